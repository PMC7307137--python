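"""Growth-curve phenotyping from OD600 microculture time series.

The modified Gompertz model (Zwietering et al. 1990 parameterization)

    y(t) = A · exp(−exp(μ·e/A · (λ − t) + 1))

describes a sigmoidal growth curve directly in terms of the three
biologically meaningful quantities reported for microculture fermentations:
efficiency A (asymptotic OD gain), rate μ (tangent slope at the inflection,
OD units per hour) and lag time λ (hours).  Curves are baseline-corrected
by subtracting the first reading before fitting.  Group comparisons use
Welch two-sample t-tests; the batch-phase maximum specific growth rate
μmax is the steepest sliding-window slope of ln(OD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import gompertz


@dataclass
class GrowthResults:
    """Fitted Gompertz parameters with asymptotic standard errors."""

    efficiency: float  # A, asymptotic OD above baseline
    rate: float  # mu, h^-1 (OD-scale tangent slope at inflection)
    lag: float  # lambda, h
    residual: float  # root-mean-square residual of the fit
    bse: tuple[float, float, float]  # standard errors of (A, mu, lag)
    baseline: float
    n_points: int

    @property
    def params(self) -> tuple[float, float, float]:
        return (self.efficiency, self.rate, self.lag)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.baseline + gompertz(np.asarray(t, dtype=float), *self.params)

    def summary(self) -> str:
        rows = [("efficiency A", self.efficiency, self.bse[0]),
                ("rate mu (h^-1)", self.rate, self.bse[1]),
                ("lag lambda (h)", self.lag, self.bse[2])]
        lines = ["Gompertz growth fit", "-" * 40]
        for name, val, se in rows:
            lines.append(f"{name:<18} {val:10.4f}  +/- {se:.4f}")
        lines.append(f"{'rms residual':<18} {self.residual:10.5f}  (n={self.n_points})")
        return "\n".join(lines)


class GompertzModel:
    """Nonlinear least-squares Gompertz fit of one growth curve.

    Uses a deterministic grid of starting points (no random restarts):
    A from the maximum baseline-corrected OD, μ from the steepest finite
    difference, λ from the tangent-line intercept at the steepest point.
    """

    def __init__(self, time_h, od600):
        t = np.asarray(time_h, dtype=float)
        y = np.asarray(od600, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and OD must be 1-D arrays of equal length")
        if len(t) < 8:
            raise ValueError("growth curve needs >= 8 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("OD600 must be non-negative")
        self.t = t
        self.baseline = float(y[0])
        self.y = y - self.baseline

    def _starts(self):
        ymax = float(self.y.max())
        if ymax <= 0:
            raise ValueError("flat or non-growing curve: no Gompertz fit")
        slopes = np.diff(self.y) / np.diff(self.t)
        i = int(np.argmax(slopes))
        mu0 = max(float(slopes[i]), 1e-6)
        t_m = (self.t[i] + self.t[i + 1]) / 2
        lam0 = max(t_m - self.y[i] / mu0, 0.0)
        for fa in (1.0, 1.2):
            for fm in (1.0, 0.5, 2.0):
                for lam in (lam0, 0.5 * lam0, 1.5 * lam0 + 0.5, 0.0):
                    yield (ymax * fa, mu0 * fm, lam)

    def fit(self) -> GrowthResults:
        best = None
        for p0 in self._starts():
            try:
                popt, pcov = optimize.curve_fit(
                    gompertz, self.t, self.y, p0=p0,
                    bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=20_000, xtol=1e-8, ftol=1e-8)
            except (RuntimeError, ValueError):
                continue
            resid = gompertz(self.t, *popt) - self.y
            rms = float(np.sqrt(np.mean(resid ** 2)))
            if best is None or rms < best[0]:
                best = (rms, popt, pcov)
        if best is None:
            raise RuntimeError("Gompertz fit failed to converge from every start")
        rms, popt, pcov = best
        with np.errstate(invalid="ignore"):
            bse = tuple(float(x) for x in np.sqrt(np.diag(pcov)))
        return GrowthResults(efficiency=float(popt[0]), rate=float(popt[1]),
                             lag=float(popt[2]), residual=rms, bse=bse,
                             baseline=self.baseline, n_points=len(self.t))


def fit_gompertz(time_h, od600) -> GrowthResults:
    """Functional wrapper around :class:`GompertzModel`."""
    return GompertzModel(time_h, od600).fit()


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fit_mumax(time_h, od600, window: int = 5) -> tuple[float, tuple[int, int]]:
    """Batch-phase μmax: maximum sliding-window slope of ln(OD).

    Windows containing non-positive OD readings are skipped.  Returns
    (μmax in h^-1, (start, stop) index of the winning window).  A constant
    curve gives μmax = 0.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(od600, dtype=float)
    if len(t) < max(window, 4):
        raise ValueError(f"need >= {max(window, 4)} points")
    best, best_win = None, None
    for i in range(len(t) - window + 1):
        seg = y[i:i + window]
        if np.any(seg <= 0):
            continue
        slope = float(np.polyfit(t[i:i + window], np.log(seg), 1)[0])
        if best is None or slope > best:
            best, best_win = slope, (i, i + window)
    if best is None:
        raise ValueError("no window with strictly positive OD in exponential phase")
    if best < 1e-12:  # flat within numerical noise
        best = 0.0
    return best, best_win


def compare_groups(params_a: pd.DataFrame, params_b: pd.DataFrame,
                   columns=("lag", "rate", "efficiency")) -> pd.DataFrame:
    """Welch t-tests between two groups of fitted growth parameters."""
    rows = []
    for col in columns:
        t, df, p = welch_t(params_a[col], params_b[col])
        rows.append((col, float(params_a[col].mean()), float(params_b[col].mean()),
                     t, df, p))
    return pd.DataFrame(rows, columns=["parameter", "mean_a", "mean_b",
                                       "t", "df", "p"])


def fit_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Fit every well of a long plate table (well, time_h, od600)."""
    rows = []
    for well, sub in plate.groupby("well", sort=True):
        res = fit_gompertz(sub["time_h"].to_numpy(), sub["od600"].to_numpy())
        rows.append((well, res.lag, res.rate, res.efficiency, res.residual))
    return pd.DataFrame(rows, columns=["well", "lag", "rate", "efficiency",
                                       "residual"])
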