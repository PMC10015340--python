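"""Drought-response modelling: the 4PL Tr_m,VPD-VWC curve and the midday
phase shift.

The response of midday normalized transpiration to soil water content is

    Tr_m,VPD(vwc) = A2 + (A1 - A2) / (1 + (theta_c / vwc)**p)

with A1 the well-watered (high-VWC) asymptote, A2 the severe-drought
asymptote, theta_c the critical VWC at the inflection (where the decline
is fastest) and p > 0 the steepness.  Note the exponent convention: with
(theta_c/vwc)**p and p > 0 the curve increases in vwc, so A1 is the
high-VWC asymptote as its physiological meaning requires; this is
algebraically the textbook (vwc/theta_c)**p form with a negative exponent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .water import MomentaryTr


@dataclass
class LogisticFit:
    A1: float
    A2: float
    p: float
    theta_c: float
    se: dict
    rss: float
    converged: bool
    degenerate: bool
    n_points: int

    def predict(self, vwc):
        return logistic_value(self.A1, self.A2, self.p, self.theta_c, vwc)


@dataclass
class PhaseShiftResult:
    day: int
    ww_peak_h: float
    treated_peak_h: float
    shift_h: float  # WW - treated; positive = advance under drought
    method: str = "quadratic-vertex"


@dataclass
class DailyTrComparison:
    day: int
    mean_ww: float
    mean_treated: float
    t_statistic: float
    p_value: float
    significant: bool


def logistic_value(A1, A2, p, theta_c, vwc):
    """Evaluate the 4PL response at ``vwc`` (scalar or array, must be > 0)."""
    vwc = np.asarray(vwc, dtype=float)
    if np.any(vwc <= 0):
        raise ValueError("vwc must be positive")
    out = A2 + (A1 - A2) / (1.0 + (theta_c / vwc) ** p)
    return float(out) if out.ndim == 0 else out


def max_decline_rate(fit: LogisticFit) -> float:
    """|dTr/dVWC| at the inflection vwc = theta_c: (A1-A2) * p / (4 theta_c)."""
    return abs(fit.A1 - fit.A2) * fit.p / (4.0 * fit.theta_c)


def fit_logistic_response(
    vwc: np.ndarray,
    tr_m_vpd: np.ndarray,
    init: tuple | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> LogisticFit:
    """Nonlinear least-squares fit of the 4PL response.

    Multi-start: the default initialization (A1 = max y, A2 = min y,
    theta_c = median x, p = 5) plus ``n_starts - 1`` jittered copies; the
    best-RSS converged solution wins.  Bounds keep A2 >= 0 and theta_c
    within the observed VWC range.  A near-flat response (max y - min y
    below 5% of max y) is returned with ``degenerate=True``.
    """
    x = np.asarray(vwc, dtype=float)
    y = np.asarray(tr_m_vpd, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0)
    x, y = x[ok], y[ok]
    if x.size < 6:
        raise ValueError("need >= 6 points to fit the 4PL response")

    span = y.max() - y.min()
    if span < 0.05 * max(y.max(), 1e-12):
        return LogisticFit(A1=float(y.max()), A2=float(y.min()), p=np.nan,
                           theta_c=np.nan, se={}, rss=float(np.sum((y - y.mean()) ** 2)),
                           converged=False, degenerate=True, n_points=int(x.size))

    if init is None:
        init = (y.max(), max(y.min(), 1e-6), 5.0, float(np.median(x)))
    rng = np.random.default_rng(seed)
    lo = [0.0, 0.0, 0.5, x.min() * 0.5]
    hi = [np.inf, np.inf, 60.0, x.max() * 1.5]

    def model(v, A1, A2, p, thc):
        return A2 + (A1 - A2) / (1.0 + (thc / v) ** p)

    best = None
    for s in range(n_starts):
        p0 = np.array(init, dtype=float)
        if s > 0:
            p0 = p0 * rng.lognormal(0.0, 0.2, 4)
        p0 = np.clip(p0, np.array(lo) + 1e-9, [1e6, 1e6, hi[2], hi[3]])
        try:
            popt, pcov = optimize.curve_fit(model, x, y, p0=p0,
                                            bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - model(x, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        return LogisticFit(A1=np.nan, A2=np.nan, p=np.nan, theta_c=np.nan,
                           se={}, rss=np.nan, converged=False, degenerate=False,
                           n_points=int(x.size))
    popt, pcov, rss = best
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    names = ("A1", "A2", "p", "theta_c")
    return LogisticFit(A1=float(popt[0]), A2=float(popt[1]), p=float(popt[2]),
                       theta_c=float(popt[3]),
                       se=dict(zip(names, (float(e) for e in perr))),
                       rss=rss, converged=True, degenerate=False,
                       n_points=int(x.size))


def midday_peak_time(
    tr: MomentaryTr,
    day: int,
    window: tuple = (10.0, 16.0),
    plant_weight: np.ndarray | None = None,
    smoothing_min: float = 45.0,
    vertex_half_width_h: float = 1.5,
) -> float:
    """Clock time (decimal hours) of the midday transpiration peak.

    The momentary Tr course (optionally normalized by plant weight to
    remove the within-day growth trend) is smoothed, the argmax inside the
    window located, and a quadratic fitted over +-``vertex_half_width_h``
    around it; the vertex gives sub-sample resolution.  Falls back to the
    argmax when the vertex leaves the window.  Returns NaN when the window
    holds no usable signal.
    """
    per_day_min = tr.hours[1] - tr.hours[0]
    dt_min = per_day_min * 60.0
    per_day = int(round(24 * 60 / dt_min))
    sl = slice(day * per_day, (day + 1) * per_day)
    tod = tr.hours[sl] % 24.0
    y = tr.tr_g_per_min[sl].astype(float).copy()
    if plant_weight is not None:
        w = plant_weight[sl]
        y = np.where(w > 0, y / w, np.nan)
    in_win = (tod >= window[0]) & (tod < window[1])
    if not np.any(in_win & np.isfinite(y)):
        return np.nan
    width = max(1, int(round(smoothing_min / dt_min)))
    y_filled = np.where(np.isfinite(y), y, 0.0)
    kernel = np.ones(width) / width
    sm = np.convolve(y_filled, kernel, mode="same")
    wsum = np.convolve(np.isfinite(y).astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(wsum > 0, sm / wsum, np.nan)

    cand = np.where(in_win & np.isfinite(sm))[0]
    if cand.size < 5 or np.nanmax(sm[cand]) <= 0:
        return np.nan
    i_max = cand[np.nanargmax(sm[cand])]
    t_max = tod[i_max]
    near = np.isfinite(sm) & (np.abs(tod - t_max) <= vertex_half_width_h)
    tt, yy = tod[near], sm[near]
    if tt.size >= 5:
        c = np.polyfit(tt - t_max, yy, 2)
        if c[0] < 0:
            vertex = t_max - c[1] / (2 * c[0])
            if window[0] <= vertex < window[1]:
                return float(vertex)
    return float(t_max)


def phase_shift(
    tr_ww: MomentaryTr,
    tr_treated: MomentaryTr,
    day: int,
    window: tuple = (10.0, 16.0),
    weight_ww: np.ndarray | None = None,
    weight_treated: np.ndarray | None = None,
    **kwargs,
) -> PhaseShiftResult:
    """Midday-peak phase shift on one day: WW peak time minus treated peak
    time (hours, positive = drought-induced advance)."""
    p_ww = midday_peak_time(tr_ww, day, window, plant_weight=weight_ww, **kwargs)
    p_tr = midday_peak_time(tr_treated, day, window, plant_weight=weight_treated, **kwargs)
    return PhaseShiftResult(day=day, ww_peak_h=p_ww, treated_peak_h=p_tr,
                            shift_h=p_ww - p_tr)


def compare_daily_tr(
    ww_values: np.ndarray,
    treated_values: np.ndarray,
    day: int = 0,
    alpha: float = 0.05,
) -> DailyTrComparison:
    """Welch two-sample t-test on per-pot daily transpiration (one day)."""
    a = np.asarray(ww_values, dtype=float)
    b = np.asarray(treated_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 pots per group for the daily t-test")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return DailyTrComparison(day=day, mean_ww=float(a.mean()),
                             mean_treated=float(b.mean()),
                             t_statistic=float(t), p_value=float(p),
                             significant=bool(p <= alpha))
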