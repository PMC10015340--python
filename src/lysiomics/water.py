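"""Gravimetric whole-plant water-relations estimation.

Everything here works from the recorded lysimeter series alone (system
weight, VWC, VPD, irrigation events) plus the pot bookkeeping constants:

* daily transpiration from predawn/evening weight anchors,
* WUE as the OLS slope of cumulative biomass gain on cumulative
  transpiration over a well-irrigated window,
* plant-weight reconstruction W(t) = W0 + WUE x cumulative transpiration,
* momentary transpiration as -dW/dt on the smoothed weight series, and
* midday VPD- and weight-normalized transpiration (Tr_m,VPD) paired with
  midday mean VWC, the input to the 4PL drought-response fit.

All rates carry explicit units in the returned column names.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate.lysimeter import LysimeterSeries, SoilPotSpec


@dataclass
class WueEstimate:
    slope: float        # g FW per g water
    intercept: float
    r_squared: float
    n_points: int
    window_days: tuple

    def __post_init__(self):
        if self.n_points < 2:
            raise ValueError("WUE fit needs >= 2 points")


@dataclass
class MomentaryTr:
    hours: np.ndarray
    tr_g_per_min: np.ndarray
    smoothing_min: float
    masked: np.ndarray          # bool, True where irrigation-window masked
    n_clamped_negative: int


def initial_plant_weight(total_system_weight: float, pot: SoilPotSpec) -> float:
    """Plant fresh weight = total system weight minus tare, soil-at-capacity
    and drainage-water components.  Raises if the bookkeeping goes negative."""
    w = total_system_weight - (pot.tare_weight + pot.soil_weight_at_capacity
                               + pot.drainage_water_weight)
    if w < 0:
        raise ValueError("initial plant weight came out negative; "
                         "check the pot bookkeeping components")
    return w


def daily_transpiration(
    series: LysimeterSeries,
    predawn_hour: float = 5.0,
    evening_hour: float = 19.0,
    noise_floor: float = 5.0,
) -> pd.DataFrame:
    """Per-day transpiration from weight anchors.

    daily T = weight(predawn) - weight(evening) + irrigation inside the
    window.  Values in [-noise_floor, 0) are clamped to 0; larger negative
    values are kept and flagged.  Days missing an anchor sample yield NaN
    with a warning.
    """
    per_day = int(round(24 * 60 / series.resolution_min))
    n_days = len(series.hours) // per_day
    rows = []
    for day in range(n_days):
        sl = series.day_slice(day)
        tod = series.hours[sl] % 24.0
        w = series.weight_g[sl]
        i_pre = np.argmin(np.abs(tod - predawn_hour))
        i_eve = np.argmin(np.abs(tod - evening_hour))
        if (abs(tod[i_pre] - predawn_hour) > 0.5 or abs(tod[i_eve] - evening_hour) > 0.5):
            warnings.warn(f"day {day}: missing anchor samples")
            rows.append({"day": day, "transpiration_g_per_day": np.nan})
            continue
        irr_in_window = sum(v for (h, v) in series.irrigation_events
                            if day * 24 + predawn_hour <= h < day * 24 + evening_hour)
        t = w[i_pre] - w[i_eve] + irr_in_window
        if -noise_floor <= t < 0:
            t = 0.0
        rows.append({"day": day, "transpiration_g_per_day": t})
    df = pd.DataFrame(rows)
    df["cumulative_transpiration_g"] = df["transpiration_g_per_day"].fillna(0).cumsum()
    return df


def daily_biomass_gain(
    series: LysimeterSeries,
    predawn_hour: float = 5.0,
) -> pd.DataFrame:
    """Gravimetric daily biomass gain from predawn system-weight drift.

    When nightly irrigation refills the pot to capacity (the well-irrigated
    regime), the predawn soil water pool is constant, so the
    predawn-to-predawn change in system weight equals plant biomass gain.
    During deficit irrigation the pool drifts and this reading is not
    meaningful; WUE estimation therefore uses a well-irrigated window only.
    The returned table aligns day d with the predawn(d) -> predawn(d+1)
    interval.
    """
    per_day = int(round(24 * 60 / series.resolution_min))
    n_days = len(series.hours) // per_day
    i_pre = int(round(predawn_hour * 60 / series.resolution_min))
    rows = []
    for day in range(n_days - 1):
        w0 = series.weight_g[day * per_day + i_pre]
        w1 = series.weight_g[(day + 1) * per_day + i_pre]
        rows.append({"day": day, "biomass_gain_g_per_day": w1 - w0})
    df = pd.DataFrame(rows)
    df["cumulative_biomass_g"] = df["biomass_gain_g_per_day"].cumsum()
    return df


def estimate_wue(
    cumulative_biomass: np.ndarray,
    cumulative_transpiration: np.ndarray,
    window_days: tuple = (0, 7),
) -> WueEstimate:
    """OLS slope of cumulative biomass gain on cumulative transpiration.

    ``window_days`` selects rows [start, stop) of the aligned daily arrays.
    The slope is invariant to intercept shifts of either series.
    """
    lo, hi = window_days
    x = np.asarray(cumulative_transpiration, dtype=float)[lo:hi]
    y = np.asarray(cumulative_biomass, dtype=float)[lo:hi]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise ValueError("WUE window needs >= 2 paired days")
    if np.ptp(x) == 0:
        raise ValueError("degenerate WUE fit: zero variance in transpiration")
    res = stats.linregress(x, y)
    return WueEstimate(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2), n_points=int(x.size),
                       window_days=window_days)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width) / width
    sm = np.convolve(x, kernel, mode="same")
    # fix edge normalization
    counts = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return sm / counts


def momentary_tr(
    series: LysimeterSeries,
    smoothing_min: float = 15.0,
    mask_pad_min: float = 15.0,
) -> MomentaryTr:
    """Momentary transpiration: -dW/dt (g min^-1) on the smoothed weights.

    Weight is smoothed with a centered moving average of ``smoothing_min``
    before central differencing.  Windows of ``mask_pad_min`` around each
    irrigation event are masked.  Negative values outside the mask are
    clamped to 0 and counted (noise artifact).
    """
    dt = series.resolution_min
    width = max(1, int(round(smoothing_min / dt)))
    if width >= len(series.weight_g):
        raise ValueError("smoothing window exceeds series length")
    w = _moving_average(series.weight_g, width)
    tr = np.empty_like(w)
    tr[1:-1] = -(w[2:] - w[:-2]) / (2 * dt)
    tr[0] = tr[1]
    tr[-1] = tr[-2]

    masked = np.zeros(len(w), dtype=bool)
    pad_h = (mask_pad_min + smoothing_min) / 60.0
    for (h, v) in series.irrigation_events:
        masked |= (series.hours >= h - pad_h) & (series.hours <= h + pad_h)
    neg = (tr < 0) & ~masked
    tr = np.where(neg, 0.0, tr)
    tr[masked] = np.nan
    return MomentaryTr(hours=series.hours.copy(), tr_g_per_min=tr,
                       smoothing_min=smoothing_min, masked=masked,
                       n_clamped_negative=int(neg.sum()))


def plant_weight_series(
    series: LysimeterSeries,
    wue: float,
    smoothing_min: float = 15.0,
) -> np.ndarray:
    """Reconstruct plant fresh weight at full resolution.

    Cumulative transpiration is recovered from the weight balance
    cumT(t) = W(0) - W(t) + cumulative irrigation(t) on the smoothed
    weights, then W_plant(t) = W_plant(0) + WUE x cumT(t).  The initial
    plant weight comes from the pot bookkeeping; the initial system weight
    is averaged over the first 30 min to suppress measurement noise.
    """
    if wue <= 0:
        raise ValueError("wue must be positive")
    dt = series.resolution_min
    width = max(1, int(round(smoothing_min / dt)))
    w = _moving_average(series.weight_g, width)
    n0 = max(1, int(round(30.0 / dt)))
    w_start = float(np.mean(series.weight_g[:n0]))
    cum_irr = np.zeros(len(w))
    for (h, v) in series.irrigation_events:
        cum_irr[series.hours >= h] += v
    cum_t = np.maximum(w_start - w + cum_irr, 0.0)
    w0_plant = initial_plant_weight(w_start, series.pot)
    return w0_plant + wue * cum_t


def midday_normalized_tr(
    tr: MomentaryTr,
    series: LysimeterSeries,
    plant_weight: np.ndarray,
    window: tuple = (12.0, 16.0),
    vpd_floor: float = 0.1,
) -> pd.DataFrame:
    """Per-day midday Tr_m,VPD and midday mean VWC.

    Tr_m,VPD = mean over the window of Tr(t) * 1000 / (VPD(t) * W_plant(t)),
    in mg H2O min^-1 kPa^-1 g^-1 FW; samples with VPD below ``vpd_floor``
    or masked by irrigation are excluded.  Returns NaN for a day whose
    window is empty after exclusions.
    """
    per_day = int(round(24 * 60 / series.resolution_min))
    n_days = len(series.hours) // per_day
    rows = []
    for day in range(n_days):
        sl = series.day_slice(day)
        tod = series.hours[sl] % 24.0
        in_win = (tod >= window[0]) & (tod < window[1])
        vpd = series.vpd[sl]
        t = tr.tr_g_per_min[sl]
        w = plant_weight[sl]
        ok = in_win & (vpd >= vpd_floor) & np.isfinite(t) & (w > 0)
        if not np.any(ok):
            rows.append({"day": day, "tr_m_vpd_mg_min_kpa_gfw": np.nan,
                         "midday_vwc_m3_m3": np.nan})
            continue
        norm = t[ok] * 1000.0 / (vpd[ok] * w[ok])
        rows.append({
            "day": day,
            "tr_m_vpd_mg_min_kpa_gfw": float(np.mean(norm)),
            "midday_vwc_m3_m3": float(np.mean(series.vwc[sl][in_win])),
        })
    return pd.DataFrame(rows)
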