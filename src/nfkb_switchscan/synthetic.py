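"""Synthetic promoter tiling-array, annotation and expression generator.

Emulates the statistical structure the analysis assumes: probes tiled around
each TSS on a NimbleGen-style promoter array, near-Gaussian background log2
ratios, rectangular enrichment plateaus over truly bound promoters, three
biological replicates at three time points (0h, 1h, 6h), and a follow-up
expression table in RPKM whose differential-expression status is coupled to
binding at the matched earlier time (1h binding -> 4h expression, 6h binding
-> 12h expression).

Each gene carries a ground-truth temporal binding pattern, a code 0-7 read
from its bound/unbound bits at (0h, 1h, 6h) with the earliest time as the
most significant bit.  The default pattern mixture keeps 30% of genes never
bound and splits the rest in proportion to the per-pattern bound-gene
composition reported for regenerating liver (patterns 1-7 roughly 21/22/8/
22/10/9/9 percent of bound genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io

TIME_LABELS = ("0h", "1h", "6h")
EXPR_TIME_LABELS = ("0h", "4h", "12h")

# fraction of bound genes per pattern 1..7, mirroring the study's composition
_BOUND_PATTERN_COUNTS = {1: 1067, 2: 1140, 3: 392, 4: 1108, 5: 502, 6: 473, 7: 435}


def default_pattern_proportions(p_never_bound: float = 0.30) -> dict[int, float]:
    total = sum(_BOUND_PATTERN_COUNTS.values())
    props = {0: p_never_bound}
    for code, n in _BOUND_PATTERN_COUNTS.items():
        props[code] = (1.0 - p_never_bound) * n / total
    return props


def tss_shift_offsets(far_bp: int = -2000, near_bp: int = -250) -> dict[str, int]:
    """Preset of per-time enrichment-center offsets emulating the observed
    1h shift of binding toward the TSS: 0h and 6h centers sit ``far_bp``
    from the TSS, 1h centers at ``near_bp`` (negative = upstream)."""
    return {"0h": far_bp, "1h": near_bp, "6h": far_bp}


@dataclass
class SimulationConfig:
    """Free parameters of the generator; defaults are the study conditions."""

    n_genes: int = 200
    n_chromosomes: int = 2
    probe_spacing_bp: int = 100
    tile_window: tuple[int, int] = (-5000, 1500)
    noise_sd: float = 0.3
    enrichment_amplitude: float = 2.0
    enrichment_width_bp: int = 600
    enrichment_center_offset_bp: dict[str, int] | int = 0
    n_replicates: int = 3
    time_labels: tuple[str, ...] = TIME_LABELS
    replicate_penetrance: float = 1.0
    pattern_proportions: dict[int, float] = field(default_factory=default_pattern_proportions)
    expression_baseline_log_mean: float = 2.0
    expression_baseline_log_sd: float = 1.0
    de_log2fc_range: tuple[float, float] = (1.0, 3.0)
    p_de_given_bound: float = 0.15
    p_de_given_unbound: float = 0.05
    expression_time_labels: tuple[str, ...] = EXPR_TIME_LABELS
    chromosome_length_bp: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be positive")
        if self.probe_spacing_bp < 1 or self.enrichment_width_bp < 1:
            raise ValueError("spacings and widths must be positive")
        if not (self.tile_window[0] < 0 < self.tile_window[1]):
            raise ValueError("tile_window must straddle the TSS (start < 0 < end)")
        if self.probe_spacing_bp >= self.enrichment_width_bp:
            raise ValueError("probe_spacing_bp must be smaller than enrichment_width_bp")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for p in (self.replicate_penetrance, self.p_de_given_bound, self.p_de_given_unbound):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        n_times = len(self.time_labels)
        codes = set(range(2 ** n_times))
        if set(self.pattern_proportions) - codes:
            raise ValueError("pattern_proportions keys must be codes 0..2^T-1")
        total = sum(self.pattern_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_proportions must sum to 1 (got {total})")
        if not (0 < self.de_log2fc_range[0] <= self.de_log2fc_range[1]):
            raise ValueError("de_log2fc_range must be positive and ordered")
        if len(self.expression_time_labels) != n_times:
            raise ValueError("need one expression time label per binding time")

    def center_offset(self, time_label: str) -> int:
        if isinstance(self.enrichment_center_offset_bp, dict):
            return int(self.enrichment_center_offset_bp.get(time_label, 0))
        return int(self.enrichment_center_offset_bp)

    def time_map(self) -> dict[str, str]:
        """Binding time -> follow-up expression time (1h->4h, 6h->12h)."""
        return dict(zip(self.time_labels[1:], self.expression_time_labels[1:]))


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    if "pattern_proportions" in raw:
        raw["pattern_proportions"] = {int(k): float(v)
                                      for k, v in raw["pattern_proportions"].items()}
    for key in ("tile_window", "time_labels", "expression_time_labels", "de_log2fc_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def save_config(config: SimulationConfig, path) -> None:
    raw = asdict(config)
    for key, val in raw.items():
        if isinstance(val, tuple):
            raw[key] = list(val)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Truth tables for parameter-recovery tests.

    genes: per-gene table (gene_id, true_pattern, de_<t> and true_log2fc_<t>
        for each follow-up time).
    arrays: long table (gene_id, replicate, time_label, enriched) — the
        per-array enrichment indicator after penetrance thinning; always
        false where the pattern bit is 0.
    """

    genes: pd.DataFrame
    arrays: pd.DataFrame

    def pattern_of(self) -> pd.Series:
        return self.genes.set_index("gene_id")["true_pattern"]


def pattern_bits(code: int, n_times: int = 3) -> tuple[int, ...]:
    """MSB-first bits of a pattern code: bit for the earliest time first."""
    return tuple((code >> (n_times - 1 - t)) & 1 for t in range(n_times))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> pd.DataFrame:
    """Lay out n_genes non-overlapping promoters across chromosomes.

    Genes are placed in disjoint slots sized to keep both tile windows and
    gene regions pairwise disjoint; strands drawn ~50/50 from the seed.
    """
    rng = np.random.default_rng(config.seed)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    tlens = rng.integers(2000, 20001, size=config.n_genes)
    tw0, tw1 = config.tile_window
    margin = 2000
    cursors = {c: 1 for c in range(config.n_chromosomes)}
    rows = []
    for i in range(config.n_genes):
        c = i % config.n_chromosomes
        chrom = f"chr{c + 1}"
        a = cursors[c]
        tlen = int(tlens[i])
        # slot wide enough for tile window and gene region on either strand
        width = (tw1 - tw0) + abs(tw0) + tlen + margin
        if strands[i] == "+":
            tss = a + abs(tw0)
            tend = tss + tlen
        else:
            tss = a + abs(tw0) + tlen
            tend = tss - tlen
        cursors[c] = a + width
        if config.chromosome_length_bp is not None and cursors[c] > config.chromosome_length_bp:
            raise ValueError(
                f"cannot place {config.n_genes} genes on {config.n_chromosomes} "
                f"chromosomes of {config.chromosome_length_bp} bp"
            )
        rows.append({
            "gene_id": f"G{i + 1:05d}",
            "refseq_id": f"NM_{900000 + i + 1}",
            "chrom": chrom,
            "strand": strands[i],
            "tss": int(tss),
            "transcript_end": int(tend),
        })
    return pd.DataFrame(rows, columns=_io.GENE_COLUMNS)


def generate_truth(config: SimulationConfig, genes: pd.DataFrame) -> GroundTruth:
    """Assign a true binding pattern per gene (multinomial over
    pattern_proportions), thin per-array enrichment by replicate_penetrance,
    and draw coupled differential-expression status per follow-up time."""
    rng = np.random.default_rng(config.seed + 1)
    codes = sorted(config.pattern_proportions)
    probs = np.array([config.pattern_proportions[c] for c in codes])
    n_times = len(config.time_labels)
    patterns = rng.choice(codes, size=len(genes), p=probs / probs.sum())

    array_rows = []
    for gid, code in zip(genes["gene_id"], patterns):
        bits = pattern_bits(int(code), n_times)
        for t, tl in enumerate(config.time_labels):
            for rep in range(1, config.n_replicates + 1):
                enriched = bool(bits[t]) and (rng.random() < config.replicate_penetrance)
                array_rows.append((gid, rep, tl, enriched))
    arrays = pd.DataFrame(array_rows,
                          columns=["gene_id", "replicate", "time_label", "enriched"])

    time_map = config.time_map()
    gene_rows = {"gene_id": genes["gene_id"].to_numpy(), "true_pattern": patterns}
    lo, hi = config.de_log2fc_range
    for t_idx, (bind_t, expr_t) in enumerate(time_map.items(), start=1):
        bits = np.array([pattern_bits(int(c), n_times)[t_idx] for c in patterns])
        p = np.where(bits == 1, config.p_de_given_bound, config.p_de_given_unbound)
        de = rng.random(len(genes)) < p
        mag = rng.uniform(lo, hi, size=len(genes))
        sign = rng.choice([-1.0, 1.0], size=len(genes))
        lfc = np.where(de, sign * mag, 0.0)
        gene_rows[f"de_{expr_t}"] = de
        gene_rows[f"true_log2fc_{expr_t}"] = lfc
    return GroundTruth(genes=pd.DataFrame(gene_rows), arrays=arrays)


def _probe_positions(gene_row, config: SimulationConfig) -> np.ndarray:
    tw0, tw1 = config.tile_window
    rel = np.arange(tw0, tw1 + 1, config.probe_spacing_bp)
    if gene_row.strand == "+":
        return gene_row.tss + rel
    return gene_row.tss - rel


def generate_probe_arrays(config: SimulationConfig, genes: pd.DataFrame,
                          truth: GroundTruth) -> dict[tuple[int, str], pd.DataFrame]:
    """One probe-signal table per (replicate, time_label) array.

    Probe coordinates are identical across arrays.  Background is i.i.d.
    Normal(0, noise_sd); probes within enrichment_width_bp/2 of the (possibly
    time-shifted) enrichment center of a truly enriched (gene, replicate,
    time) get +enrichment_amplitude.
    """
    rng = np.random.default_rng(config.seed + 2)

    probe_meta = []
    for row in genes.itertuples(index=False):
        pos = _probe_positions(row, config)
        for k, p in enumerate(np.sort(pos)):
            probe_meta.append((f"{row.gene_id}_p{k:03d}", row.chrom, int(p),
                               row.gene_id, int(row.tss), row.strand))
    meta = pd.DataFrame(probe_meta,
                        columns=["probe_id", "chrom", "position", "gene_id", "tss", "strand"])
    meta = meta.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)

    enriched_lookup = truth.arrays.set_index(["gene_id", "replicate", "time_label"])["enriched"]
    half_w = config.enrichment_width_bp / 2.0
    arrays = {}
    for rep in range(1, config.n_replicates + 1):
        for tl in config.time_labels:
            sig = rng.normal(0.0, config.noise_sd, size=len(meta)) if config.noise_sd > 0 \
                else np.zeros(len(meta))
            off = config.center_offset(tl)
            centers = np.where(meta["strand"] == "+", meta["tss"] + off, meta["tss"] - off)
            gene_enriched = enriched_lookup.loc[
                list(zip(meta["gene_id"], [rep] * len(meta), [tl] * len(meta)))
            ].to_numpy()
            hit = gene_enriched & (np.abs(meta["position"] - centers) <= half_w)
            sig = sig + np.where(hit, config.enrichment_amplitude, 0.0)
            df = meta[["probe_id", "chrom", "position"]].copy()
            df["log2_ratio"] = sig
            df["replicate"] = rep
            df["time_label"] = tl
            arrays[(rep, tl)] = df
    return arrays


def generate_expression(config: SimulationConfig, genes: pd.DataFrame,
                        truth: GroundTruth) -> pd.DataFrame:
    """Per-gene RPKM at baseline and the follow-up times.

    Baseline is log-normal; a gene flagged DE at a follow-up time has its
    baseline RPKM multiplied by 2**true_log2fc, with no further count-level
    noise (the analysis consumes already-normalized averages).
    """
    rng = np.random.default_rng(config.seed + 3)
    base = np.exp(rng.normal(config.expression_baseline_log_mean,
                             config.expression_baseline_log_sd, size=len(genes)))
    expr = genes[["gene_id", "refseq_id"]].copy()
    expr[f"rpkm_{config.expression_time_labels[0]}"] = base
    for expr_t in config.expression_time_labels[1:]:
        lfc = truth.genes[f"true_log2fc_{expr_t}"].to_numpy()
        expr[f"rpkm_{expr_t}"] = base * np.power(2.0, lfc)
    return expr


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: pd.DataFrame
    truth: GroundTruth
    arrays: dict
    expression: pd.DataFrame


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    genes = generate_genome(config)
    truth = generate_truth(config, genes)
    arrays = generate_probe_arrays(config, genes, truth)
    expression = generate_expression(config, genes, truth)
    return SyntheticDataset(config=config, genes=genes, truth=truth,
                            arrays=arrays, expression=expression)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every table of a synthetic dataset; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    _io.write_gene_table(ds.genes, outdir / "genes.tsv")
    paths["genes"] = str(outdir / "genes.tsv")
    _io.write_genes_bed(ds.genes, outdir / "genes.bed")
    paths["genes_bed"] = str(outdir / "genes.bed")
    for (rep, tl), df in sorted(ds.arrays.items()):
        p = outdir / f"array_rep{rep}_{tl}.tsv"
        _io.write_probe_array(df, p)
        paths[f"array_rep{rep}_{tl}"] = str(p)
    _io.write_expression_table(ds.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    ds.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    paths["truth_genes"] = str(outdir / "truth_genes.tsv")
    ds.truth.arrays.to_csv(outdir / "truth_arrays.tsv", sep="\t", index=False)
    paths["truth_arrays"] = str(outdir / "truth_arrays.tsv")
    save_config(ds.config, outdir / "config.yaml")
    paths["config"] = str(outdir / "config.yaml")
    return paths
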