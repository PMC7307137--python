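"""Small shared helpers: quantiles, windows, RNG plumbing."""

from __future__ import annotations

import numpy as np

#: Canonical founder order used everywhere (arrays index parents in this order).
PARENTS: tuple[str, ...] = ("NA", "SA", "WA", "WE")

#: Time-point labels of the selection design.
TIMES: tuple[str, ...] = ("T0", "T1", "T2")


def empirical_quantile(values: np.ndarray, q: float) -> float:
    """Linear-interpolation empirical quantile over finite entries."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("quantile of empty/all-NaN data")
    return float(np.quantile(v, q, method="linear"))


def window_starts(length: int, window: int, step: int) -> np.ndarray:
    """Start coordinates (0-based) of sliding windows on [0, length).

    Yields ceil((L - window)/step) + 1 windows for length >= window: every
    multiple of `step` up to length - window, plus a final flush window when
    the remainder does not divide evenly.
    """
    if window < step:
        raise ValueError(f"window ({window}) must be >= step ({step})")
    if length < window:
        return np.array([0], dtype=np.int64)
    starts = list(range(0, length - window + 1, step))
    if (length - window) % step != 0:
        starts.append(length - window)
    return np.asarray(starts, dtype=np.int64)


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
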