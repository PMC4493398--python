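"""Temporal binding discretization, 2^T pattern codes, and switch pairing.

A gene is called *bound* at a time point when at least ``consensus_min``
replicates (default 2 of 3) carry a significant peak (FDR <= threshold)
annotated to it.  The per-gene bound/unbound bits across the ordered time
points, read most-significant-bit-first from the earliest time, give a
pattern code 0..2^T-1; for the three-time design the seven non-null codes
pair into binding/unbinding switches: immediate (011 / 100), transient
(010 / 101), delayed (001 / 110), with 111 constitutive and 000 excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SWITCH_CLASSES = {
    "immediate": frozenset({3, 4}),
    "transient": frozenset({2, 5}),
    "delayed": frozenset({1, 6}),
    "constitutive": frozenset({7}),
    "null": frozenset({0}),
}


@dataclass
class BindingMatrix:
    """Replicate-consensus binding calls.

    genes: ordered gene ids; times: ordered time labels; calls: gene x time
    boolean; support: gene x time count of replicates with a qualifying peak.
    """

    genes: list
    times: list
    calls: np.ndarray
    support: np.ndarray
    n_replicates: int
    consensus_min: int

    def __post_init__(self):
        if self.support.max(initial=0) > self.n_replicates:
            raise ValueError("support cannot exceed n_replicates")
        if not np.array_equal(self.calls, self.support >= self.consensus_min):
            raise ValueError("calls must equal support >= consensus_min")


def binarize(annotated_peaks: pd.DataFrame, genes: pd.DataFrame, times,
             replicates=None, fdr_threshold: float = 0.05,
             consensus_min: int = 2) -> BindingMatrix:
    """Consensus bound/unbound calls per (gene, time).

    A replicate supports (gene, time) iff at least one peak annotated to the
    gene on that array has fdr <= fdr_threshold.  Genes never supported
    anywhere keep all-false rows (pattern 0).
    """
    times = list(times)
    if replicates is None:
        replicates = sorted(annotated_peaks["replicate"].dropna().unique().astype(int)) \
            if len(annotated_peaks) else [1, 2, 3]
    replicates = list(replicates)
    seen_times = set(annotated_peaks["time_label"].unique()) if len(annotated_peaks) else set()
    if seen_times - set(times):
        raise ValueError(f"peak times {sorted(seen_times - set(times))} not in {times}")
    # every replicate must be restricted to the same declared time grid
    for rep, sub in annotated_peaks.groupby("replicate"):
        extra = set(sub["time_label"].unique()) - set(times)
        if extra:
            raise ValueError(f"replicate {rep} carries unknown times {sorted(extra)}")

    gene_ids = list(genes["gene_id"])
    gidx = {g: i for i, g in enumerate(gene_ids)}
    tidx = {t: j for j, t in enumerate(times)}
    support = np.zeros((len(gene_ids), len(times)), dtype=int)

    sig = annotated_peaks[annotated_peaks["fdr"] <= fdr_threshold]
    trip = sig[["gene_id", "time_label", "replicate"]].drop_duplicates()
    for g, t, _ in trip.itertuples(index=False):
        if g in gidx:
            support[gidx[g], tidx[t]] += 1
    calls = support >= consensus_min
    return BindingMatrix(genes=gene_ids, times=times, calls=calls, support=support,
                         n_replicates=len(replicates), consensus_min=consensus_min)


def code_from_bits(bits) -> int:
    """Pattern code: bits ordered earliest->latest, earliest = MSB."""
    code = 0
    for b in bits:
        code = (code << 1) | int(bool(b))
    return code


def binary_string(code: int, n_times: int) -> str:
    return format(code, f"0{n_times}b")


def assign_patterns(matrix: BindingMatrix):
    """Per-gene pattern assignment plus a per-pattern counts table.

    Returns (assignments DataFrame with gene_id/binary/pattern_code,
    counts DataFrame over all codes 0..2^T-1).  Each gene lands in exactly
    one pattern; counts over all codes sum to the number of genes.
    """
    n_times = len(matrix.times)
    codes = [code_from_bits(row) for row in matrix.calls]
    assignments = pd.DataFrame({
        "gene_id": matrix.genes,
        "binary": [binary_string(c, n_times) for c in codes],
        "pattern_code": codes,
    })
    all_codes = range(2 ** n_times)
    counts = pd.DataFrame({
        "pattern_code": list(all_codes),
        "binary": [binary_string(c, n_times) for c in all_codes],
        "n_genes": [int(sum(1 for c in codes if c == ac)) for ac in all_codes],
    })
    return assignments, counts


def switch_class_of(code: int, n_times: int = 3) -> tuple[str, str]:
    """(switch class, arm) of a pattern code.

    Arm rule: *binding* iff unbound at the earliest time and bound at some
    later time; *unbinding* iff bound at the earliest time and unbound at
    some later time; all-ones is constitutive, zero is null.
    """
    if code == 0:
        return "null", "none"
    full = 2 ** n_times - 1
    if code == full:
        return "constitutive", "constitutive"
    bits = [int(b) for b in binary_string(code, n_times)]
    arm = "binding" if bits[0] == 0 else "unbinding"
    if n_times == 3:
        for name, members in SWITCH_CLASSES.items():
            if code in members:
                return name, arm
    # general T: class named by the complement pair it belongs to
    return f"pair_{min(code, full - code)}_{max(code, full - code)}", arm


def classify_switches(assignments: pd.DataFrame, n_times: int = 3) -> pd.DataFrame:
    """Attach switch class and arm per gene; null-pattern genes are excluded."""
    out = assignments[assignments["pattern_code"] != 0].copy()
    cls = [switch_class_of(c, n_times) for c in out["pattern_code"]]
    out["switch_class"] = [c for c, _ in cls]
    out["arm"] = [a for _, a in cls]
    return out.reset_index(drop=True)


def pattern_recovery_report(assignments: pd.DataFrame, truth_genes: pd.DataFrame,
                            n_times: int = 3):
    """Confusion matrix (true x inferred code) and overall accuracy against
    the generator's ground truth; gene sets must match exactly."""
    if set(assignments["gene_id"]) != set(truth_genes["gene_id"]):
        raise ValueError("assignment and truth gene sets differ")
    merged = truth_genes[["gene_id", "true_pattern"]].merge(
        assignments[["gene_id", "pattern_code"]], on="gene_id")
    k = 2 ** n_times
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(merged["true_pattern"], merged["pattern_code"]):
        confusion[int(t), int(p)] += 1
    accuracy = float(np.trace(confusion)) / len(merged)
    return confusion, accuracy
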