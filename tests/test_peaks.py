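"""Cutoff-scan peak caller, permutation FDR, and scree cutoff selection."""

import numpy as np
import pandas as pd
import pytest

from nfkb_switchscan.peaks import (
    DEFAULT_CUTOFF_FRACTIONS,
    ArrayStats,
    PeakCallerParams,
    call_peaks,
    compute_array_stats,
    permutation_fdr,
    scree_score_cutoff,
)

from _oracles import brute_force_peaks
from conftest import make_probe_frame


def random_instance(rng, n=None, n_chroms=1):
    n = n or int(rng.integers(10, 501))
    chroms = rng.choice([f"chr{i + 1}" for i in range(n_chroms)], size=n)
    frames = []
    for c in sorted(set(chroms)):
        m = int((chroms == c).sum())
        pos = np.sort(rng.choice(np.arange(1, 20001), size=m, replace=False))
        frames.append(pd.DataFrame({
            "probe_id": [f"{c}p{i}" for i in range(m)], "chrom": c,
            "position": pos, "log2_ratio": rng.normal(0, 1, size=m),
        }))
    df = pd.concat(frames, ignore_index=True)
    df["replicate"] = 1
    df["time_label"] = "0h"
    return df


class TestArrayStats:
    def test_hand_computed_population_sd(self):
        probes = make_probe_frame([100, 200], [-1.0, 1.0])
        st = compute_array_stats(probes, PeakCallerParams())
        assert st.mean == 0.0
        assert st.sd == 1.0  # population convention
        assert st.hypothetical_max == 6.0

    def test_degenerate_zero_sd_warns(self):
        probes = make_probe_frame([100, 200, 300, 400], [0.0] * 4)
        with pytest.warns(UserWarning):
            st = compute_array_stats(probes, PeakCallerParams())
        assert st == ArrayStats(mean=0.0, sd=0.0, hypothetical_max=0.0)

    def test_translation_shifts_mean_not_sd(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.5, size=50)
        a = compute_array_stats(make_probe_frame(np.arange(1, 51) * 100, vals),
                                PeakCallerParams())
        b = compute_array_stats(make_probe_frame(np.arange(1, 51) * 100, vals + 2.5),
                                PeakCallerParams())
        assert b.mean == pytest.approx(a.mean + 2.5)
        assert b.sd == pytest.approx(a.sd)
        assert b.hypothetical_max == pytest.approx(a.hypothetical_max + 2.5)

    def test_single_probe_rejected(self):
        with pytest.raises(ValueError):
            compute_array_stats(make_probe_frame([100], [1.0]), PeakCallerParams())


class TestCallPeaks:
    def test_minimal_qualifying_configuration(self):
        # 4 clustered hot probes among quiet background: one peak at the
        # strictest fraction spanning exactly the contributing probes
        pos = [100, 200, 300, 400] + [50000 + 1000 * i for i in range(196)]
        vals = [1.0] * 4 + [0.0] * 196
        probes = make_probe_frame(pos, vals)
        params = PeakCallerParams()
        st = compute_array_stats(probes, params)
        assert 0.90 * st.hypothetical_max < 1.0
        peaks = call_peaks(probes, st, params)
        assert len(peaks) == 1
        pk = peaks.iloc[0]
        assert pk["score"] == 0.90
        assert pk["n_probes"] >= 4
        assert (pk["start"], pk["end"]) == (99, 400)
        assert pk["mean_log2"] == pytest.approx(1.0)

    def test_three_probes_never_enough(self):
        # the detection rule demands at least four probes above the cutoff
        pos = [100, 200, 300] + [50000 + 1000 * i for i in range(197)]
        vals = [1.0] * 3 + [0.0] * 197
        probes = make_probe_frame(pos, vals)
        params = PeakCallerParams()
        st = compute_array_stats(probes, params)
        assert len(call_peaks(probes, st, params)) == 0

    def test_probes_spread_past_window_not_called(self):
        # 4 hot probes 600 bp apart never fit one 500 bp window together
        pos = [100, 700, 1300, 1900] + [50000 + 1000 * i for i in range(196)]
        vals = [1.0] * 4 + [0.0] * 196
        probes = make_probe_frame(pos, vals)
        st = compute_array_stats(probes, PeakCallerParams())
        assert len(call_peaks(probes, st, PeakCallerParams())) == 0

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        probes = random_instance(rng, n_chroms=1 + seed % 2)
        params = PeakCallerParams()
        st = compute_array_stats(probes, params)
        got = call_peaks(probes, st, params)
        got_tuples = sorted(
            (r.chrom, int(r.start), int(r.end), round(float(r.score), 10))
            for r in got.itertuples())
        expected = brute_force_peaks(
            probes["chrom"].tolist(), probes["position"].tolist(),
            probes["log2_ratio"].tolist(), st.hypothetical_max)
        assert got_tuples == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_loosening_params_keeps_peaks(self, seed):
        """Lowering min_probes never removes a detected peak region."""
        rng = np.random.default_rng(100 + seed)
        probes = random_instance(rng)
        strict = PeakCallerParams(min_probes=4)
        loose = PeakCallerParams(min_probes=3)
        st = compute_array_stats(probes, strict)
        pk_strict = call_peaks(probes, st, strict)
        pk_loose = call_peaks(probes, st, loose)
        for r in pk_strict.itertuples():
            cover = pk_loose[(pk_loose["chrom"] == r.chrom)
                             & (pk_loose["start"] < r.end)
                             & (pk_loose["end"] > r.start)]
            assert len(cover) >= 1
            assert cover["score"].max() >= r.score

    def test_unsorted_probes_rejected(self):
        probes = make_probe_frame([100, 200, 300], [0, 0, 0])
        probes.loc[0, "position"] = 400  # break sortedness post-construction
        st = ArrayStats(mean=0.0, sd=1.0, hypothetical_max=6.0)
        with pytest.raises(ValueError):
            call_peaks(probes, st, PeakCallerParams())


class TestPermutationFdr:
    def _spike_array(self):
        # noiseless separable signal: flat zero background, one +2 plateau
        pos = list(range(100, 100 + 100 * 200, 100))
        vals = [0.0] * 200
        for i in range(50, 57):
            vals[i] = 2.0
        return make_probe_frame(pos, vals)

    def test_noiseless_spike_gets_near_zero_fdr(self):
        probes = self._spike_array()
        params = PeakCallerParams()
        st = compute_array_stats(probes, params)
        peaks = permutation_fdr(probes, st, call_peaks(probes, st, params),
                                params, seed=3)
        assert len(peaks) == 1
        assert peaks["fdr"].iloc[0] <= 0.05

    def test_null_noise_peaks_get_high_fdr(self):
        rng = np.random.default_rng(42)
        pos = list(range(100, 100 + 100 * 500, 100))
        probes = make_probe_frame(pos, rng.normal(0, 0.3, size=500))
        params = PeakCallerParams()
        st = compute_array_stats(probes, params)
        peaks = permutation_fdr(probes, st, call_peaks(probes, st, params),
                                params, seed=4)
        if len(peaks):
            assert (peaks["fdr"] > 0.05).all()

    def test_deterministic_and_recomputable_from_logged_permutations(self):
        probes = self._spike_array()
        rng = np.random.default_rng(9)
        probes["log2_ratio"] += rng.normal(0, 0.3, size=len(probes))
        params = PeakCallerParams()
        st = compute_array_stats(probes, params)
        called = call_peaks(probes, st, params)
        a = permutation_fdr(probes, st, called, params, seed=11)
        b, perm_tables = permutation_fdr(probes, st, called, params, seed=11,
                                         return_permutation_peaks=True)
        pd.testing.assert_frame_equal(a, b)
        assert len(perm_tables) == params.n_permutations
        # recompute the tail ratio with step-down directly from the logs
        obs = called["score"].to_numpy()
        for s in np.unique(obs):
            candidates = [t for t in np.unique(obs) if t >= s]
            raws = []
            for t in candidates:
                perm_mean = np.mean([(pt["score"] >= t).sum() for pt in perm_tables])
                raws.append(min(1.0, perm_mean / max(1, (obs >= t).sum())))
            expected = min(raws)
            got = a.loc[a["score"] == s, "fdr"].iloc[0]
            assert got == pytest.approx(expected)

    def test_fdr_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(17)
        probes = random_instance(rng, n=400)
        params = PeakCallerParams()
        st = compute_array_stats(probes, params)
        peaks = permutation_fdr(probes, st, call_peaks(probes, st, params),
                                params, seed=17)
        by_score = peaks.sort_values("score")
        fdrs = by_score.drop_duplicates("score")["fdr"].to_numpy()
        assert (np.diff(fdrs) <= 1e-12).all()

    def test_zero_observed_peaks_passthrough(self):
        probes = make_probe_frame([100, 1200, 2300, 3400], [0.1, -0.1, 0.1, -0.1])
        params = PeakCallerParams()
        st = compute_array_stats(probes, params)
        empty = call_peaks(probes, st, params)
        out = permutation_fdr(probes, st, empty, params, seed=1)
        assert len(out) == 0


class TestScreeCutoff:
    def test_linear_scores_degenerate_to_first_index(self):
        idx, thr = scree_score_cutoff([10, 8, 6, 4, 2])
        assert idx == 0 and thr == 10.0

    def test_sharp_elbow_found(self):
        idx, thr = scree_score_cutoff([10, 9, 8, 1, 0.9, 0.8])
        assert idx == 3 and thr == 1.0

    def test_matches_brute_force_distance_maximization(self):
        scores = [9.5, 7.0, 6.5, 6.4, 3.0, 1.0, 0.5, 0.4]
        n = len(scores)
        x0, y0, x1, y1 = 0, scores[0], n - 1, scores[-1]
        dists = [abs((x1 - x0) * (s - y0) - (y1 - y0) * (i - x0))
                 for i, s in enumerate(scores)]
        expected = dists.index(max(dists))
        assert scree_score_cutoff(scores)[0] == expected

    def test_collinear_tail_extension_preserves_threshold(self):
        # a decisive elbow survives extending the tail along its own slope
        base = [10.0, 9.0, 8.0, 1.0, 0.9, 0.8]
        _, thr = scree_score_cutoff(base)
        for extra in ([0.7, 0.6], [0.7, 0.6, 0.5, 0.4]):
            _, thr2 = scree_score_cutoff(base + extra)
            assert thr2 == thr

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            scree_score_cutoff([2.0, 1.0])


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"min_probes": 1},
        {"cutoff_fractions": (0.5, 0.5)},
        {"cutoff_fractions": (0.15, 0.90)},
        {"cutoff_fractions": (1.5,)},
        {"fdr_threshold": 0.0},
        {"window_bp": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PeakCallerParams(**kwargs)

    def test_default_cutoff_scan_covers_90_down_to_15(self):
        fr = DEFAULT_CUTOFF_FRACTIONS
        assert fr[0] == 0.90 and fr[-1] == 0.15 and len(fr) == 16
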