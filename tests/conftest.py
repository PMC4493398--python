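import numpy as np
import pandas as pd
import pytest

from nfkb_switchscan.annotate import annotate_peaks
from nfkb_switchscan.peaks import (
    PeakCallerParams,
    call_peaks,
    compute_array_stats,
    permutation_fdr,
)
from nfkb_switchscan.synthetic import SimulationConfig, generate_dataset


def make_probe_frame(positions, values, chrom="chr1", replicate=1, time_label="0h"):
    """Hand-built single-array probe table sorted by position."""
    order = np.argsort(positions, kind="stable")
    pos = np.asarray(positions)[order]
    vals = np.asarray(values, dtype=float)[order]
    return pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(len(pos))],
        "chrom": chrom,
        "position": pos.astype(np.int64),
        "log2_ratio": vals,
        "replicate": replicate,
        "time_label": time_label,
    })


def call_all_arrays(dataset, params=None, seed=100):
    """Peak-call every array of a synthetic dataset, FDR attached."""
    params = params or PeakCallerParams()
    frames = []
    for i, ((rep, tl), probes) in enumerate(sorted(dataset.arrays.items())):
        stats = compute_array_stats(probes, params)
        called = call_peaks(probes, stats, params)
        called = permutation_fdr(probes, stats, called, params, seed=seed + i)
        frames.append(called)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_dataset():
    """40-gene synthetic dataset at the default study conditions."""
    return generate_dataset(SimulationConfig(n_genes=40, seed=5))


@pytest.fixture(scope="session")
def small_annotated(small_dataset):
    """All arrays of the small dataset called, FDR'd and annotated."""
    peaks = call_all_arrays(small_dataset)
    annotated, _ = annotate_peaks(peaks, small_dataset.genes)
    return annotated
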