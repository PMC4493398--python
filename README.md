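# nfkb-switchscan

Dynamic pattern analysis of temporal transcription-factor binding from
promoter tiling arrays, built around the NF-κB/liver-regeneration study
design: ChIP-chip log₂ ratios measured at 0 h, 1 h and 6 h after partial
hepatectomy in three biological replicates, coupled to RNA-seq expression at
0 h, 4 h and 12 h. The package is for computational biologists who want the
whole chain — peak detection, empirical FDR, TSS annotation, temporal
binding patterns and switches, binding–expression integration, and gene-set
over-representation — as tested, reusable code, with a synthetic-data
generator that emulates the study's inputs so every stage can be validated
without array downloads.

## Method

**Peak detection.** Each array (replicate × time) is summarized by its
*hypothetical maximum signal* `M = μ + 6σ` (mean probe log₂ ratio plus six
population SDs). Scanning cutoff fractions `f = 0.90, 0.85, …, 0.15`, a
peak is seeded wherever a 500 bp window anchored at a probe with signal
`> f·M` contains ≥ 4 such probes. Regions found at the same fraction merge
when they overlap; regions found at looser fractions are absorbed into any
overlapping stricter peak, so each peak's **score** is the highest fraction
at which it is detectable and its extent is maximal across fractions.

**Empirical FDR.** Probe values are shuffled across positions 20 times and
peaks re-called; for each score level *s*,

    FDR(s) = min(1, E_perm[#{peaks ≥ s}] / #{observed peaks ≥ s}),

followed by a step-down pass making FDR non-increasing in score. Peaks with
FDR ≤ 0.05 are significant.

**Annotation.** A peak is assigned to the gene with the nearest TSS when the
signed distance from the peak center is within 5 kb, else to a gene whose
region (TSS − 5 kb to transcript end + 1.5 kb, strand-aware) contains the
center; otherwise it is unannotated.

**Patterns and switches.** A gene is *bound* at a time point when ≥ 2 of 3
replicates carry a significant peak annotated to it. Its bound/unbound bits
over (0 h, 1 h, 6 h), read MSB-first, give a pattern code 0–7 (e.g. 010 →
pattern 2). Codes pair with their bitwise complements into switches:
immediate (011/100), transient (010/101), delayed (001/110); 111 is
constitutive and 000 is excluded.

**Expression integration.** Fold change is
`log₂(RPKM_t + c) − log₂(RPKM_0 + c)` with pseudocount `c = 0.1`; a gene is
differentially expressed at ≥ 2-fold change. Binding at 1 h is evaluated
against 4 h expression and 6 h binding against 12 h. Over-representation of
the resulting gene lists uses the exact hypergeometric upper tail with
Benjamini–Hochberg correction.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic data
(200 genes, seeds fixed in the scripts) and write their tables under
`results/analysis/`:

```bash
python analysis/01_simulate.py
python analysis/02_call_peaks.py
python analysis/03_annotate_peaks.py
python analysis/04_patterns.py
python analysis/05_integrate_expression.py
python analysis/06_enrichment.py
```

`04_patterns.py` prints the per-pattern gene counts and the recovery of the
generator's ground truth:

```
 pattern_code binary  n_genes
            0    000       66
            1    001       24
            2    010       29
            3    011       10
            4    100       37
            5    101        8
            6    110       13
            7    111       13

pattern recovery vs ground truth: accuracy 1.000
```

i.e. 134 of 200 genes are bound at some time, partitioned into the seven
non-null patterns, and every gene's inferred pattern matches the simulated
truth. `05_integrate_expression.py` then reports the per-pattern
differential-expression counts in the bound-vs-DE layout (the constitutive
row counts bound-and-measured genes, footnoted), and `06_enrichment.py`
recovers a spiked demonstration gene set at p ≈ 2 × 10⁻³¹ while size-matched
random sets stay non-significant.

The same chain is available as one call — library
(`nfkb_switchscan.pipeline.run_pipeline`) or CLI:

```bash
nfkb-switchscan run --seed 1 --out results/run
```

which writes every stage table plus `manifest.json` (config snapshot, seeds,
SHA-256 digest per output). Externally supplied gene/probe/peak/expression
tables can replace any upstream stage via the `inputs:` config section.

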