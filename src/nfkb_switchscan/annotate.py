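"""Peak-to-gene annotation by TSS proximity and interval-overlap utilities.

A peak is assigned to the gene whose TSS is nearest to the peak center
(floor of the interval midpoint) when that distance is within the TSS cutoff
(default 5000 bp); failing that, to a gene whose *gene region* (5 kb upstream
of the TSS to 1.5 kb downstream of the transcript end, strand-aware) contains
the center.  Distances are signed strand-aware: negative = peak center
upstream of the TSS, positive = downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import gene_region

LOCATION_CLASSES = ("upstream", "downstream-in-gene", "downstream-of-gene")

ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "score", "n_probes", "mean_log2", "fdr",
    "replicate", "time_label", "peak_center", "gene_id", "refseq_id",
    "signed_distance_bp", "location_class", "entrez_id", "phastcons",
]


def _signed_distance(center: np.ndarray, tss0: np.ndarray, plus: np.ndarray) -> np.ndarray:
    return np.where(plus, center - tss0, tss0 - center)


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                   tss_cutoff_bp: int = 5000,
                   region_upstream_bp: int = 5000,
                   region_downstream_bp: int = 1500):
    """Assign each peak to at most one gene; returns (annotated, unannotated).

    Nearest-TSS ties break deterministically toward the gene earliest in
    (chrom, tss, gene_id) order.  Entrez/phastcons columns are emitted empty
    (no mapping table is bundled).
    """
    if len(genes) == 0:
        raise ValueError("gene table is empty")
    genes_sorted = genes.sort_values(["chrom", "tss", "gene_id"],
                                     kind="mergesort").reset_index(drop=True)
    regions = gene_region(genes_sorted, region_upstream_bp, region_downstream_bp)

    by_chrom = {}
    for chrom, sub in genes_sorted.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        tree = IntervalTree()
        for j in idx:
            tree.addi(int(regions.loc[j, "region_start"]),
                      int(regions.loc[j, "region_end"]), j)
        by_chrom[chrom] = (
            idx,
            sub["tss"].to_numpy() - 1,                # 0-based TSS
            (sub["strand"] == "+").to_numpy(),
            tree,
        )

    ann_rows, un_rows = [], []
    for _, peak in peaks.iterrows():
        center = (int(peak["start"]) + int(peak["end"])) // 2
        chrom = peak["chrom"]
        chosen = None
        if chrom in by_chrom:
            idx, tss0, plus, tree = by_chrom[chrom]
            dists = _signed_distance(center, tss0, plus)
            j = int(np.argmin(np.abs(dists)))         # first minimum = tie-break
            if abs(int(dists[j])) <= tss_cutoff_bp:
                chosen = (idx[j], int(dists[j]))
            else:
                hits = sorted(iv.data for iv in tree.at(center))
                if hits:
                    # nearest TSS among containing gene regions, same tie-break
                    local = [int(np.where(idx == h)[0][0]) for h in hits]
                    k = min(local, key=lambda m: (abs(int(dists[m])), m))
                    chosen = (idx[k], int(dists[k]))
        if chosen is None:
            un_rows.append(peak)
            continue
        gi, dist = chosen
        grow = genes_sorted.loc[gi]
        if dist < 0:
            loc = "upstream"
        else:
            span = abs(int(grow["transcript_end"]) - int(grow["tss"]))
            loc = "downstream-in-gene" if dist <= span else "downstream-of-gene"
        rec = peak.to_dict()
        rec.update({
            "peak_center": center,
            "gene_id": grow["gene_id"],
            "refseq_id": grow["refseq_id"],
            "signed_distance_bp": dist,
            "location_class": loc,
            "entrez_id": "",
            "phastcons": "",
        })
        ann_rows.append(rec)

    annotated = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    unannotated = pd.DataFrame(un_rows, columns=peaks.columns)
    return annotated.reset_index(drop=True), unannotated.reset_index(drop=True)


def tss_distance_profile(annotated: pd.DataFrame, bin_bp: int = 250,
                         max_bp: int = 5000):
    """Histogram of signed peak-center-to-TSS distances per time point.

    Returns (histogram DataFrame with time_label/bin_left/bin_right/count,
    dict time_label -> mode bin center).  An empty group yields an empty
    histogram with a warning.
    """
    edges = np.arange(-max_bp, max_bp + bin_bp, bin_bp)
    hist_rows = []
    modes = {}
    for tl, sub in annotated.groupby("time_label", sort=True):
        d = sub["signed_distance_bp"].to_numpy()
        if d.size == 0:
            warnings.warn(f"no annotated peaks at time {tl}")
            continue
        counts, _ = np.histogram(d, bins=edges)
        for left, right, c in zip(edges[:-1], edges[1:], counts):
            hist_rows.append({"time_label": tl, "bin_left": int(left),
                              "bin_right": int(right), "count": int(c)})
        k = int(np.argmax(counts))
        modes[tl] = float((edges[k] + edges[k + 1]) / 2.0)
    hist = pd.DataFrame(hist_rows,
                        columns=["time_label", "bin_left", "bin_right", "count"])
    return hist, modes


def region_overlap(peaks: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Per-peak overlap against a BED-style interval set (half-open).

    ``overlap_bp`` is computed against the union of the intervals so nothing
    is double-counted; ``overlaps`` is true iff overlap_bp >= 1.
    """
    trees = {}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        ivs = sorted(zip(sub["start"], sub["end"])) or []
        merged = []
        for s, e in ivs:
            if e <= s:
                continue
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        tree = IntervalTree()
        for s, e in merged:
            tree.addi(int(s), int(e))
        trees[chrom] = tree
    out = peaks.copy()
    overlaps_bp = []
    for _, pk in peaks.iterrows():
        tree = trees.get(pk["chrom"])
        total = 0
        if tree is not None:
            for iv in tree.overlap(int(pk["start"]), int(pk["end"])):
                total += min(iv.end, int(pk["end"])) - max(iv.begin, int(pk["start"]))
        overlaps_bp.append(total)
    out["overlap_bp"] = overlaps_bp
    out["overlaps"] = out["overlap_bp"] >= 1
    return out
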