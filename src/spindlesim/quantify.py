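"""Model-data comparison statistics and curve fits.

These operate on event tables (rescue/catastrophe positions, growth
speeds and durations) and on time series (spindle length, polymer
mass), whether simulated, synthetic or measured:

* 1-µm binning of any quantity against spindle length, and the
  closed-form scaling factor that matches simulated polymer mass to
  fluorescence intensity;
* the Kolmogorov–Smirnov distance between empirical CDFs;
* the multi-step catastrophe-time fit ``F(t) = (1 - exp(-theta*t))**n``;
* the three-phase piecewise-linear spindle-elongation fit whose second
  breakpoint defines anaphase B onset;
* the error-function fit of growth speed against distance to the
  closest pole, capturing the fast -> slow two-state transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "BinnedSeries", "ScalingResult", "PiecewiseFitResult", "ErfFitResult",
    "CatFitResult", "bin_by_spindle_length", "fit_intensity_scaling",
    "ecdf", "ks_distance", "fit_catastrophe_cdf", "fit_piecewise_elongation",
    "piecewise_elongation", "erf_transition", "fit_erf_transition",
    "rescue_position_histogram", "catastrophe_cdf",
]


@dataclass
class BinnedSeries:
    edges: np.ndarray      # length n_bins + 1, strictly increasing
    means: np.ndarray      # NaN where the bin is empty
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0


@dataclass
class ScalingResult:
    f: float
    sse: float


@dataclass
class PiecewiseFitResult:
    L0: float
    t1: float
    t2: float
    s1: float
    s2: float
    s3: float
    residual_norm: float
    reliable: bool

    @property
    def anaphase_onset(self) -> float:
        return self.t2


@dataclass
class ErfFitResult:
    v_fast: float
    v_slow: float
    d0: float
    w: float
    r_squared: float


@dataclass
class CatFitResult:
    theta_hat: float
    n_hat: float
    gof: float  # root-mean-square ECDF residual


def bin_by_spindle_length(pairs, width: float = 1.0) -> BinnedSeries:
    """Average a paired quantity in spindle-length bins.

    ``pairs`` is a sequence of (spindle length, value); bins have the
    given width (1 µm by default) starting at ``floor(min length /
    width) * width``. Empty bins carry NaN means and zero counts.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    arr = np.asarray(pairs, dtype=float)
    lengths, values = arr[:, 0], arr[:, 1]
    lo = math.floor(lengths.min() / width) * width
    n_bins = int(math.floor((lengths.max() - lo) / width)) + 1
    edges = lo + width * np.arange(n_bins + 1)
    idx = np.clip(((lengths - lo) / width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedSeries(edges=edges, means=means, counts=counts)


def fit_intensity_scaling(sim_bins: BinnedSeries,
                          exp_bins: BinnedSeries) -> ScalingResult:
    """Scaling factor matching binned intensity to binned polymer mass.

    Minimises ``sum_i (s_i - f*e_i)**2`` over the bins that are
    non-empty in both series; the minimiser is the closed form
    ``f = sum(s*e) / sum(e**2)``.
    """
    if not np.allclose(sim_bins.edges, exp_bins.edges):
        raise ValueError("series must share the same binning")
    common = sim_bins.nonempty & exp_bins.nonempty
    if not common.any():
        raise ValueError("no common non-empty bin")
    s = sim_bins.means[common]
    e = exp_bins.means[common]
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise ValueError("all experimental bin means are zero")
    f = float(np.sum(s * e)) / denom
    sse = float(np.sum((s - f * e) ** 2))
    return ScalingResult(f=f, sse=sse)


def ecdf(sample) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and F evaluated just after each."""
    x = np.sort(np.asarray(sample, dtype=float))
    return x, np.arange(1, x.size + 1) / x.size


def ks_distance(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov distance.

    The supremum over the real line of the absolute difference between
    the two empirical CDFs; it suffices to evaluate both ECDFs at every
    observed point.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    pts = np.concatenate([a, b])
    Fa = np.searchsorted(a, pts, side="right") / a.size
    Fb = np.searchsorted(b, pts, side="right") / b.size
    return float(np.max(np.abs(Fa - Fb)))


def catastrophe_cdf(t, theta: float, n: float):
    """CDF of growth duration: ``(1 - exp(-theta*t))**n``."""
    return (1.0 - np.exp(-theta * np.asarray(t, dtype=float))) ** n


def _moment_init(durations: np.ndarray) -> tuple[float, float]:
    # mean = (psi(n+1)+gamma)/theta, var = (pi^2/6 - psi'(n+1))/theta^2:
    # the mean^2/variance ratio depends on n only, so solve for n first
    mean = durations.mean()
    var = durations.var()
    if var <= 0:
        return 1.0 / mean, 1.0
    target = mean * mean / var

    def ratio(log_n: float) -> float:
        nn = math.exp(log_n)
        m = special.digamma(nn + 1.0) + np.euler_gamma
        v = math.pi ** 2 / 6.0 - special.polygamma(1, nn + 1.0)
        return m * m / v - target

    try:
        log_n = optimize.brentq(ratio, math.log(1e-3), math.log(1e4))
    except ValueError:
        return 1.0 / mean, 1.0
    n0 = math.exp(log_n)
    theta0 = (special.digamma(n0 + 1.0) + np.euler_gamma) / mean
    return theta0, n0


def fit_catastrophe_cdf(durations) -> CatFitResult:
    """Least-squares fit of the empirical CDF of growth durations to
    ``(1 - exp(-theta*t))**n``, initialised from matched moments."""
    d = np.asarray(durations, dtype=float)
    if d.size < 50:
        raise ValueError("need at least 50 durations")
    if np.ptp(d) == 0:
        raise ValueError("degenerate (all-equal) durations")
    x, F = ecdf(d)
    F_mid = F - 0.5 / d.size  # midpoint plotting positions
    theta0, n0 = _moment_init(d)
    popt, _ = optimize.curve_fit(catastrophe_cdf, x, F_mid,
                                 p0=(theta0, n0),
                                 bounds=([1e-8, 1e-8], [np.inf, np.inf]),
                                 maxfev=20000)
    resid = catastrophe_cdf(x, *popt) - F_mid
    return CatFitResult(theta_hat=float(popt[0]), n_hat=float(popt[1]),
                        gof=float(np.sqrt(np.mean(resid ** 2))))


def piecewise_elongation(t, L0: float, t1: float, t2: float,
                         s1: float, s2: float, s3: float):
    """Three-phase continuous piecewise-linear spindle length G(t):
    slope s1 up to t1 (prophase), s2 on (t1, t2] (metaphase/anaphase A)
    and s3 after t2 (anaphase B); anaphase B onset is t2."""
    t = np.asarray(t, dtype=float)
    seg1 = np.minimum(t, t1)
    seg2 = np.clip(t - t1, 0.0, t2 - t1)
    seg3 = np.maximum(t - t2, 0.0)
    return L0 + s1 * seg1 + s2 * seg2 + s3 * seg3


def _breakpoint_rss(t: np.ndarray, y: np.ndarray, t1: float,
                    t2: float) -> tuple[float, np.ndarray]:
    X = np.column_stack([
        np.ones_like(t),
        np.minimum(t, t1),
        np.clip(t - t1, 0.0, t2 - t1),
        np.maximum(t - t2, 0.0),
    ])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def fit_piecewise_elongation(series) -> PiecewiseFitResult:
    """Fit the three-phase elongation curve to a (t, length) series.

    The model is linear in (L0, s1, s2, s3) once the breakpoints are
    fixed, so the fit profiles those out and optimises (t1, t2) by
    multi-start Nelder-Mead over a grid of breakpoint initialisations.
    The result is flagged unreliable when the breakpoints collapse
    (t1 >= t2, or a breakpoint escapes the sampled range) or when
    adjacent slopes are indistinguishable (the breakpoint between them
    is then unidentifiable) — cases the original analysis fixed by hand.
    """
    arr = np.asarray(series, dtype=float)
    t, y = arr[:, 0], arr[:, 1]
    order = np.argsort(t)
    t, y = t[order], y[order]
    if t.size < 6:
        raise ValueError("need at least 6 points to fit 6 parameters")
    lo, hi = t[0], t[-1]
    span = hi - lo

    qs = np.linspace(0.1, 0.9, 7)
    starts = [(lo + a * span, lo + b * span)
              for a in qs for b in qs if b - a > 0.05]

    def objective(p):
        t1, t2 = p
        if not (lo < t1 < t2 < hi):
            return 1e18 * (1.0 + abs(t1) + abs(t2))
        return _breakpoint_rss(t, y, t1, t2)[0]

    best = None
    for start in starts:
        res = optimize.minimize(objective, start, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-18,
                                         "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    t1, t2 = best.x
    rss, coef = _breakpoint_rss(t, y, t1, t2)
    L0, s1, s2, s3 = coef
    scale = max(np.abs([s1, s2, s3]).max(), 1e-12)
    reliable = (lo < t1 < t2 < hi
                and abs(s1 - s2) > 1e-4 * scale
                and abs(s2 - s3) > 1e-4 * scale)
    return PiecewiseFitResult(L0=float(L0), t1=float(t1), t2=float(t2),
                              s1=float(s1), s2=float(s2), s3=float(s3),
                              residual_norm=float(np.sqrt(rss)),
                              reliable=bool(reliable))


def erf_transition(d, v_fast: float, v_slow: float, d0: float, w: float):
    """Two-state growth-speed curve: v_fast plateau for tips close to
    the pole, v_slow far from it, with an error-function transition of
    midpoint d0 and width w."""
    d = np.asarray(d, dtype=float)
    return v_fast - (v_fast - v_slow) * 0.5 * (1.0 + special.erf((d - d0) / w))


def fit_erf_transition(events) -> ErfFitResult:
    """Fit growth speed versus distance-to-closest-pole to the
    error-function transition between a fast and a slow state."""
    arr = np.asarray(events, dtype=float)
    d, v = arr[:, 0], arr[:, 1]
    if d.size < 20:
        raise ValueError("need at least 20 events")
    if np.ptp(v) == 0:
        raise ValueError("all speeds equal: transition width unidentifiable")
    order = np.argsort(d)
    d, v = d[order], v[order]
    k = max(d.size // 4, 1)
    p0 = (float(v[:k].mean()), float(v[-k:].mean()),
          float(np.median(d)), float(max(np.ptp(d) / 4.0, 1e-3)))
    popt, _ = optimize.curve_fit(erf_transition, d, v, p0=p0,
                                 maxfev=20000)
    pred = erf_transition(d, *popt)
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    return ErfFitResult(v_fast=float(popt[0]), v_slow=float(popt[1]),
                        d0=float(popt[2]), w=float(abs(popt[3])),
                        r_squared=1.0 - ss_res / ss_tot)


def rescue_position_histogram(events, bin_width: float = 0.2
                              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of signed rescue positions and the fraction positive.

    ``events`` may be EventRecord objects or raw positions; only
    ``kind == "rescue"`` records are used. Positions are signed positive
    in the growth direction, so the positive side is past the spindle
    centre (the distal midzone edge).
    """
    pos = []
    for e in events:
        kind = getattr(e, "kind", "rescue")
        if kind == "rescue":
            pos.append(getattr(e, "pos_signed", e))
    if not pos:
        raise ValueError("no rescue events")
    pos = np.asarray(pos, dtype=float)
    lo = math.floor(pos.min() / bin_width) * bin_width
    hi = math.ceil(pos.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(pos, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    return counts, edges, float(np.mean(pos > 0))
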