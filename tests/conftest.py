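"""Shared fixtures: one small simulated experiment plus hand-built tracks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from driftmap import PARENTS, TIMES, window_frequencies
from driftmap.frequency import FrequencyTrack
from driftmap.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    # infinite-census neutral pool: frequencies stay balanced, so the
    # downstream estimates are dominated by sequencing noise only
    return SimConfig(n_chromosomes=2, chrom_length=400_000, marker_spacing=500,
                     pop_size=1500, coverage=80, replicates=3, seed=42,
                     apply_drift=False, n_de_down=12, n_de_up=8,
                     n_de_down_strict=4, n_de_up_strict=3, n_background_genes=30)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    return simulate_experiment(tiny_config)


@pytest.fixture(scope="session")
def tiny_track(tiny_bundle) -> FrequencyTrack:
    return window_frequencies(tiny_bundle.counts, tiny_bundle.founders.table,
                              chrom_lengths=tiny_bundle.founders.chrom_lengths)


def build_track(freqs: dict, chrom: str = "chr1", window: int = 10_000,
                step: int = 2_000) -> FrequencyTrack:
    """FrequencyTrack from {(condition, rep, time): (W, 4) array} by hand.

    Windows are laid consecutively (book-ended) on one chromosome so merge
    behaviour is predictable; NaN rows mark masked windows.
    """
    n_w = next(iter(freqs.values())).shape[0]
    windows = pd.DataFrame({"chrom": chrom,
                            "start": np.arange(n_w) * step,
                            "end": np.arange(n_w) * step + window})
    keys = sorted(freqs, key=lambda k: (k[0], k[1], TIMES.index(k[2])))
    samples = pd.DataFrame(
        [(f"{c}_R{r}_{t}", r, c, t) for (c, r, t) in keys],
        columns=["sample_id", "replicate", "condition", "time"])
    cube = np.stack([np.asarray(freqs[k], dtype=float) for k in keys], axis=2)
    mask = np.isnan(cube).any(axis=1)
    nmk = np.ones_like(cube, dtype=np.int64)
    return FrequencyTrack(windows=windows, samples=samples, freq=cube,
                          n_markers=nmk, mask=mask)


def balanced(n_w: int, jitter: float = 0.0, seed: int = 0) -> np.ndarray:
    """(W, 4) matrix near 0.25 each; optional deterministic jitter keeps σ>0."""
    f = np.full((n_w, 4), 0.25)
    if jitter:
        rng = np.random.default_rng(seed)
        f = f + rng.uniform(-jitter, jitter, size=f.shape)
    return f / f.sum(axis=1, keepdims=True)


assert list(PARENTS) == ["NA", "SA", "WA", "WE"]
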