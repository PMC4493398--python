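"""Cutoff-scan sliding-window peak detection with permutation-based FDR.

The caller works on one array (one replicate at one time point) of probe
log2 ratios.  A per-array reference level, the *hypothetical maximum signal*
(mean probe signal plus ``sd_multiplier`` standard deviations), anchors a scan
over cutoff fractions from 0.90 down to 0.15: at each fraction ``f`` the
absolute cutoff is ``f * hypothetical_max``, and any 500 bp window anchored at
a probe exceeding that cutoff which contains at least ``min_probes`` such
probes seeds an enriched region.  Regions found at the same fraction merge
when they overlap; regions found at lower fractions that overlap an existing
higher-fraction peak are absorbed into it, so each peak's score is the highest
fraction at which it is detectable and its extent is maximal over all
detecting fractions.

The empirical FDR attached to each peak compares, per score level, the number
of peaks called on value-permuted copies of the array against the number of
observed peaks at that score or higher, followed by a step-down pass that
makes the FDR non-increasing in score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PEAK_COLUMNS

DEFAULT_CUTOFF_FRACTIONS = tuple(round(x / 100.0, 2) for x in range(90, 14, -5))


@dataclass(frozen=True)
class PeakCallerParams:
    """Tunable parameters of the cutoff-scan caller.

    window_bp: width of the sliding window (a window anchored at 1-based
        position p covers positions p .. p+window_bp-1).
    min_probes: minimum probes above the cutoff inside one window.
    cutoff_fractions: strictly descending fractions of the hypothetical
        maximum signal scanned from strictest to loosest.
    n_permutations: value-shuffling permutations for the empirical FDR.
    fdr_threshold: significance threshold applied downstream.
    sd_multiplier: SDs above the mean defining the hypothetical maximum.
    per_chromosome_shuffle: permute probe values within chromosomes instead
        of across the whole array.
    """

    window_bp: int = 500
    min_probes: int = 4
    cutoff_fractions: tuple = field(default=DEFAULT_CUTOFF_FRACTIONS)
    n_permutations: int = 20
    fdr_threshold: float = 0.05
    sd_multiplier: float = 6.0
    per_chromosome_shuffle: bool = False

    def __post_init__(self):
        if self.window_bp < 1:
            raise ValueError("window_bp must be positive")
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        fr = tuple(self.cutoff_fractions)
        if not fr or any(not (0 < f <= 1) for f in fr):
            raise ValueError("cutoff_fractions must lie in (0, 1]")
        if any(a <= b for a, b in zip(fr, fr[1:])):
            raise ValueError("cutoff_fractions must be strictly descending")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ArrayStats:
    """Per-array signal summary; hypothetical_max = mean + sd_multiplier*sd."""

    mean: float
    sd: float
    hypothetical_max: float


def compute_array_stats(probes: pd.DataFrame, params: PeakCallerParams) -> ArrayStats:
    """Mean, population SD, and hypothetical maximum of one array's ratios."""
    vals = np.asarray(probes["log2_ratio"], dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 probes to compute array statistics")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    if sd == 0.0:
        warnings.warn("zero signal SD; hypothetical maximum degenerates to the mean")
    return ArrayStats(mean=mean, sd=sd, hypothetical_max=mean + params.sd_multiplier * sd)


def _merge_point_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge sorted point-inclusive intervals that overlap or adjoin (gap 0)."""
    merged = []
    cs, ce = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= ce + 1:
            ce = max(ce, e)
        else:
            merged.append((cs, ce))
            cs, ce = s, e
    merged.append((cs, ce))
    return merged


def _scan_chromosome(pos: np.ndarray, vals: np.ndarray, hyp_max: float,
                     params: PeakCallerParams):
    """Return peaks on one chromosome as (start_pos, end_pos, score) with
    point-inclusive 1-based endpoints."""
    accepted: list[list] = []  # [start, end, score]
    for f in params.cutoff_fractions:
        cutoff = f * hyp_max
        above = vals > cutoff
        q = pos[above]
        if q.size < params.min_probes:
            continue
        # window anchored at each qualifying probe: covers q[i] .. q[i]+W-1
        right = np.searchsorted(q, q + params.window_bp, side="left")
        counts = right - np.arange(q.size)
        seeds = np.nonzero(counts >= params.min_probes)[0]
        if seeds.size == 0:
            continue
        regions = _merge_point_intervals(q[seeds], q[right[seeds] - 1])
        for s, e in regions:
            hits = [k for k, pk in enumerate(accepted) if s <= pk[1] and pk[0] <= e]
            if hits:
                # absorb region (and any peaks it bridges) into the
                # highest-scoring one; extent becomes the union
                keep = accepted[hits[0]]
                keep[0] = min([s] + [accepted[k][0] for k in hits])
                keep[1] = max([e] + [accepted[k][1] for k in hits])
                keep[2] = max(accepted[k][2] for k in hits)
                for k in reversed(hits[1:]):
                    del accepted[k]
            else:
                accepted.append([s, e, f])
    return accepted


def call_peaks(probes: pd.DataFrame, stats: ArrayStats,
               params: PeakCallerParams) -> pd.DataFrame:
    """Detect peaks on one array; FDR column is NaN until permutation_fdr.

    ``probes`` must be sorted by (chrom, position).  The returned intervals
    are internal 0-based half-open, spanning the contributing probes;
    ``n_probes`` and ``mean_log2`` summarize the probes above the peak's own
    score-level cutoff inside its final extent.
    """
    rep = probes["replicate"].iloc[0] if "replicate" in probes and len(probes) else np.nan
    tl = probes["time_label"].iloc[0] if "time_label" in probes and len(probes) else ""
    rows = []
    for chrom, sub in probes.groupby("chrom", sort=True):
        pos = sub["position"].to_numpy(dtype=np.int64)
        vals = sub["log2_ratio"].to_numpy(dtype=float)
        if np.any(np.diff(pos) < 0):
            raise ValueError("probes must be sorted by (chrom, position)")
        for s, e, score in _scan_chromosome(pos, vals, stats.hypothetical_max, params):
            inside = (pos >= s) & (pos <= e)
            contrib = vals[inside] > score * stats.hypothetical_max
            rows.append({
                "chrom": chrom,
                "start": int(s) - 1,          # 1-based point -> 0-based half-open
                "end": int(e),
                "score": float(score),
                "n_probes": int(contrib.sum()),
                "mean_log2": float(vals[inside][contrib].mean()),
                "fdr": np.nan,
                "replicate": rep,
                "time_label": tl,
            })
    out = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def permutation_fdr(probes: pd.DataFrame, stats: ArrayStats,
                    observed_peaks: pd.DataFrame, params: PeakCallerParams,
                    seed: int, return_permutation_peaks: bool = False):
    """Attach an empirical FDR per peak by value-shuffling permutations.

    For each score level s:
        fdr(s) = min(1, mean_perm #(permuted peaks with score >= s)
                        / max(1, #(observed peaks with score >= s)))
    followed by a step-down pass making fdr non-increasing in s.
    Deterministic given ``seed``.
    """
    out = observed_peaks.copy()
    if len(out) == 0:
        if return_permutation_peaks:
            return out, []
        return out

    rng = np.random.default_rng(seed)
    shuffled = probes[["chrom", "position", "log2_ratio"]].copy()
    perm_score_lists = []
    perm_tables = []
    for _ in range(params.n_permutations):
        if params.per_chromosome_shuffle:
            vals = shuffled["log2_ratio"].to_numpy().copy()
            for _, idx in shuffled.groupby("chrom", sort=True).indices.items():
                vals[idx] = rng.permutation(vals[idx])
            shuffled["log2_ratio"] = vals
        else:
            shuffled["log2_ratio"] = rng.permutation(shuffled["log2_ratio"].to_numpy())
        perm_peaks = call_peaks(shuffled, stats, params)
        perm_score_lists.append(perm_peaks["score"].to_numpy())
        if return_permutation_peaks:
            perm_tables.append(perm_peaks)

    obs_scores = out["score"].to_numpy()
    levels = np.unique(obs_scores)            # ascending
    n_obs_ge = np.array([(obs_scores >= s).sum() for s in levels], dtype=float)
    mean_perm_ge = np.array([
        np.mean([(ps >= s).sum() for ps in perm_score_lists]) for s in levels
    ])
    raw = np.minimum(1.0, mean_perm_ge / np.maximum(1.0, n_obs_ge))
    mono = np.minimum.accumulate(raw)         # non-increasing in score
    fdr_by_level = dict(zip(levels, mono))
    out["fdr"] = [fdr_by_level[s] for s in obs_scores]
    if return_permutation_peaks:
        return out, perm_tables
    return out


def scree_score_cutoff(scores) -> tuple[int, float]:
    """Elbow of a descending-sorted score list for score-cutoff selection.

    The elbow is the point of maximal perpendicular distance from (rank,
    score) to the chord joining the first and last points; ties break toward
    the smaller rank (stricter cutoff).  Returns (index, scores[index]).
    """
    s = np.asarray(list(scores), dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 scores for a scree cutoff")
    if np.any(np.diff(s) > 0):
        raise ValueError("scores must be sorted in descending order")
    n = s.size
    x0, y0 = 0.0, s[0]
    x1, y1 = float(n - 1), s[-1]
    dx, dy = x1 - x0, y1 - y0
    ranks = np.arange(n, dtype=float)
    # |cross product| of chord direction with point offset = unscaled distance
    dist = np.abs(dx * (s - y0) - dy * (ranks - x0))
    idx = int(np.argmax(dist))                # argmax takes the first maximum
    return idx, float(s[idx])
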