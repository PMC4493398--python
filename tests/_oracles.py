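"""Independent brute-force oracles used only by the tests.

These re-derive expected results with deliberately naive enumeration so the
fast implementations are checked against code that shares none of their
machinery.
"""

import itertools
from math import comb


def brute_force_peaks(chroms, positions, values, hyp_max, window_bp=500,
                      min_probes=4, fractions=None):
    """Naive cutoff-scan peak caller.

    Enumerates, at every cutoff fraction, every window anchored at a probe
    above the cutoff; merges same-level regions that overlap or adjoin by
    repeated pairwise sweeps; absorbs lower-level regions into overlapping
    higher-level peaks.  Returns a sorted list of
    (chrom, start0, end, score) with 0-based half-open intervals.
    """
    if fractions is None:
        fractions = [x / 100.0 for x in range(90, 14, -5)]
    out = []
    for chrom in sorted(set(chroms)):
        pts = sorted((p, v) for c, p, v in zip(chroms, positions, values) if c == chrom)
        accepted = []  # dicts: lo, hi (point-inclusive), score
        for f in fractions:
            cut = f * hyp_max
            qual = [p for p, v in pts if v > cut]
            regions = []
            for a in qual:
                inwin = [p for p in qual if a <= p <= a + window_bp - 1]
                if len(inwin) >= min_probes:
                    regions.append((min(inwin), max(inwin)))
            # naive repeated merge of overlapping/adjoining regions
            changed = True
            while changed:
                changed = False
                merged = []
                for lo, hi in sorted(regions):
                    placed = False
                    for i, (mlo, mhi) in enumerate(merged):
                        if lo <= mhi + 1 and mlo <= hi + 1:
                            merged[i] = (min(mlo, lo), max(mhi, hi))
                            placed = changed = True
                            break
                    if not placed:
                        merged.append((lo, hi))
                regions = merged
            for lo, hi in sorted(regions):
                hits = [a for a in accepted if lo <= a["hi"] and a["lo"] <= hi]
                if hits:
                    keep = hits[0]
                    keep["lo"] = min([lo] + [h["lo"] for h in hits])
                    keep["hi"] = max([hi] + [h["hi"] for h in hits])
                    keep["score"] = max(h["score"] for h in hits)
                    for h in hits[1:]:
                        accepted.remove(h)
                else:
                    accepted.append({"lo": lo, "hi": hi, "score": f})
        for a in accepted:
            out.append((chrom, a["lo"] - 1, a["hi"], round(a["score"], 10)))
    return sorted(out)


def nearest_tss_brute_force(center0, genes_rows, tss_cutoff_bp=5000):
    """Exhaustive nearest-TSS search over one chromosome's genes.

    genes_rows: list of (gene_id, tss_1based, strand) on the peak's
    chromosome.  Returns (gene_id, signed_distance) or None; tie-break
    toward the gene earliest in (tss, gene_id) order.
    """
    best = None
    for gid, tss, strand in sorted(genes_rows, key=lambda r: (r[1], r[0])):
        tss0 = tss - 1
        dist = (center0 - tss0) if strand == "+" else (tss0 - center0)
        if abs(dist) <= tss_cutoff_bp and (best is None or abs(dist) < abs(best[1])):
            best = (gid, dist)
    return best


def overlap_bp_brute_force(peak, intervals):
    """Per-peak overlap bp against the union of half-open intervals,
    counted position by position."""
    covered = set()
    for c, s, e in intervals:
        if c == peak[0]:
            covered.update(range(s, e))
    return len(covered & set(range(peak[1], peak[2])))


def hypergeom_tail_enumeration(N, K, n, k):
    """P(|draw ∩ special| >= k) by enumerating all C(N, n) draws."""
    special = set(range(K))
    hits = sum(1 for draw in itertools.combinations(range(N), n)
               if len(special & set(draw)) >= k)
    return hits / comb(N, n)
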