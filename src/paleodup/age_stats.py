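"""Ks age-distribution statistics.

Histograms over (0, 2], a goodness-of-fit test against a constant
birth-death null (truncated-exponential age density, rate fitted by
maximum likelihood, Lilliefors-style parametric bootstrap for the
p-value), and significance maps of the smoothed histogram's slope across
a bandwidth grid (local-linear Gaussian-kernel regression on bin centers
and counts, states increasing / decreasing / flat / sparse).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KsHistogram",
    "GoodnessOfFitResult",
    "SiZerMap",
    "build_histogram",
    "fit_truncated_exponential",
    "ks_gof_test",
    "sizer_map",
    "INCREASING",
    "DECREASING",
    "FLAT",
    "SPARSE",
]

INCREASING = "increasing"
DECREASING = "decreasing"
FLAT = "flat"
SPARSE = "sparse"

KS_MAX = 2.0


@dataclass(frozen=True)
class KsHistogram:
    bin_edges: np.ndarray  # increasing, starting at 0
    counts: np.ndarray
    subset: str = "all"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class GoodnessOfFitResult:
    d: float
    p_value: float
    rate: float  # fitted truncated-exponential rate (birth-death decay)
    n: int


@dataclass(frozen=True)
class SiZerMap:
    x: np.ndarray  # Ks grid
    h: np.ndarray  # bandwidth grid
    states: np.ndarray  # (len(h), len(x)) of state strings
    slopes: np.ndarray
    ci_half_widths: np.ndarray


def build_histogram(
    values, bin_width: float = 0.05, subset: str = "all", upper: float = KS_MAX
) -> KsHistogram:
    """Right-closed bins (a, a + w] over (0, upper]; the upper bound falls
    in the last bin.  Values outside (0, upper] are rejected."""
    values = np.asarray(list(values), dtype=float)
    if values.size and (values.min() <= 0 or values.max() > upper):
        bad = values[(values <= 0) | (values > upper)]
        raise ValueError(f"{bad.size} values outside (0, {upper}]: e.g. {bad[0]}")
    n_bins = int(math.ceil(upper / bin_width - 1e-9))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    # right-closed: shift values down a hair relative to numpy's half-open bins
    counts = np.zeros(n_bins, dtype=int)
    if values.size:
        idx = np.ceil(values / bin_width - 1e-9).astype(int) - 1
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(counts, idx, 1)
    return KsHistogram(edges, counts, subset)


# ---------------------------------------------------------------------------
# constant birth-death null: truncated exponential on (0, T]

def _trunc_exp_mean(rate: float, T: float) -> float:
    """Mean of Exp(rate) truncated to (0, T]; linear in the rate->0 limit."""
    if abs(rate) < 1e-12:
        return T / 2.0
    if rate * T > 700:  # truncation negligible
        return 1.0 / rate
    if rate * T < -700:  # mass piles up at T
        return T + 1.0 / rate
    em = math.expm1(-rate * T)  # e^{-rT} - 1
    return 1.0 / rate + T * math.exp(-rate * T) / em


def trunc_exp_cdf(x: np.ndarray, rate: float, T: float = KS_MAX) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), 0.0, T)
    if abs(rate) < 1e-12:
        return x / T
    return np.expm1(-rate * x) / math.expm1(-rate * T)


def trunc_exp_rvs(rate: float, size: int, rng: np.random.Generator, T: float = KS_MAX) -> np.ndarray:
    u = rng.random(size)
    if abs(rate) < 1e-12:
        return u * T
    return -np.log1p(u * math.expm1(-rate * T)) / rate


def fit_truncated_exponential(values: np.ndarray, T: float = KS_MAX) -> float:
    """ML rate of an exponential truncated to (0, T]; negative rates
    (increasing density) are allowed so the fit is defined for any sample."""
    m = float(np.mean(values))
    m = min(max(m, 1e-9), T - 1e-9)

    def gap(rate: float) -> float:
        return _trunc_exp_mean(rate, T) - m

    lo, hi = -690.0 / T, 690.0 / T  # keeps exp() in range downstream
    if abs(gap(0.0)) < 1e-12:
        return 0.0
    try:
        return float(optimize.brentq(gap, lo, hi, xtol=1e-10))
    except ValueError:
        return lo if gap(lo) > 0 else hi


def _ks_statistic(sorted_values: np.ndarray, rate: float, T: float = KS_MAX) -> float:
    n = sorted_values.size
    cdf = trunc_exp_cdf(sorted_values, rate, T)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - cdf, cdf - (i - 1) / n)))


def ks_gof_test(
    values,
    n_boot: int = 200,
    seed: int | np.random.Generator | None = 0,
    T: float = KS_MAX,
) -> GoodnessOfFitResult:
    """Kolmogorov-Smirnov test of the Ks sample against a fitted constant
    birth-death null, p-value by parametric bootstrap with per-replicate
    refitting (the rate is estimated, so the naive K-S p would be biased).
    """
    values = np.sort(np.asarray(list(values), dtype=float))
    n = values.size
    if n < 30:
        raise ValueError(f"need at least 30 values, got {n}")
    if values[0] == values[-1]:
        raise ValueError("degenerate sample: all values identical")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = fit_truncated_exponential(values, T)
    d_obs = _ks_statistic(values, rate, T)
    exceed = 0
    for _ in range(n_boot):
        sim = np.sort(trunc_exp_rvs(rate, n, rng, T))
        rate_b = fit_truncated_exponential(sim, T)
        if _ks_statistic(sim, rate_b, T) >= d_obs:
            exceed += 1
    p = (1 + exceed) / (n_boot + 1)
    return GoodnessOfFitResult(d=d_obs, p_value=p, rate=rate, n=n)


# ---------------------------------------------------------------------------
# slope-significance map

def sizer_map(
    values,
    h_range: tuple[float, float] = (0.05, 5.0),
    n_h: int = 21,
    n_x: int = 41,
    bin_width: float = 0.05,
    ess_threshold: float = 5.0,
    bonferroni: bool = False,
    histogram: KsHistogram | None = None,
) -> SiZerMap:
    """Classify the slope of the smoothed Ks histogram over a log-spaced
    bandwidth grid and a linear location grid.

    The smoother is degree-1 local polynomial regression of bin counts on
    bin centers with a Gaussian kernel; a cell is significantly
    increasing/decreasing when the pointwise t-based CI of the local slope
    excludes zero, and sparse when the effective sample size
    (sum of kernel weights relative to the peak weight) is below threshold.
    """
    h_lo, h_hi = h_range
    if h_lo >= h_hi:
        raise ValueError(f"inverted bandwidth range ({h_lo}, {h_hi})")
    if histogram is None:
        histogram = build_histogram(values, bin_width=bin_width)
    xs = histogram.bin_centers
    ys = histogram.counts.astype(float)
    x_grid = np.linspace(xs[0], xs[-1], n_x)
    h_grid = np.geomspace(h_lo, h_hi, n_h)
    states = np.full((n_h, n_x), SPARSE, dtype="<U10")
    slopes = np.zeros((n_h, n_x))
    ci = np.zeros((n_h, n_x))
    # guards against calling a numerically-zero slope significant when the
    # local fit is exact (zero residual variance)
    eps = 1e-9 * (np.abs(ys).max() + 1.0)
    for hi_, h in enumerate(h_grid):
        for xi, x0 in enumerate(x_grid):
            w = np.exp(-0.5 * ((xs - x0) / h) ** 2)
            ess = float(w.sum())  # K(0) = 1
            if ess < ess_threshold:
                continue
            d = xs - x0
            sw = w.sum()
            swx = (w * d).sum()
            swx2 = (w * d * d).sum()
            det = sw * swx2 - swx * swx
            if det <= 1e-12:
                continue
            swy = (w * ys).sum()
            swxy = (w * d * ys).sum()
            beta0 = (swx2 * swy - swx * swxy) / det
            beta1 = (sw * swxy - swx * swy) / det
            resid = ys - (beta0 + beta1 * d)
            dof = max(ess - 2.0, 1.0)
            sigma2 = float((w * resid * resid).sum()) / dof
            # Var(beta1) = sigma^2 [ (X'WX)^-1 X'W^2X (X'WX)^-1 ]_11
            s2w = (w * w).sum()
            s2wx = (w * w * d).sum()
            s2wx2 = (w * w * d * d).sum()
            # row of (X'WX)^-1 for beta1: (-swx, sw)/det
            var1 = (
                sigma2
                * (swx * swx * s2w - 2 * swx * sw * s2wx + sw * sw * s2wx2)
                / (det * det)
            )
            if bonferroni:
                alpha = 0.05 / n_x
            else:
                alpha = 0.05
            tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
            half = tcrit * math.sqrt(max(var1, 0.0))
            slopes[hi_, xi] = beta1
            ci[hi_, xi] = half
            if beta1 - half > eps:
                states[hi_, xi] = INCREASING
            elif beta1 + half < -eps:
                states[hi_, xi] = DECREASING
            else:
                states[hi_, xi] = FLAT
    return SiZerMap(x=x_grid, h=h_grid, states=states, slopes=slopes, ci_half_widths=ci)
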