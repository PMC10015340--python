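"""End-to-end water-relations analysis of a simulated (or loaded) pot pair.

Chains the gravimetric estimators: daily transpiration and biomass gain,
WUE over a well-irrigated window, plant-weight reconstruction, momentary
transpiration, midday normalized transpiration, the 4PL drought-response
fit (pre-treatment + drought days only; recovery days are excluded because
rewatered stomata reopen below the drought curve), per-day phase shifts
and WW-vs-treated daily contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import water
from .response import LogisticFit, fit_logistic_response, phase_shift
from .simulate.lysimeter import LysimeterSeries


@dataclass
class WaterRelationsResult:
    daily: pd.DataFrame
    wue: water.WueEstimate
    midday: pd.DataFrame
    fit: LogisticFit | None
    phase_shifts: pd.DataFrame | None


def analyze_pot(
    series: LysimeterSeries,
    wue_window: tuple = (1, 8),
    midday_window: tuple = (12.0, 16.0),
    fit_response: bool = True,
) -> WaterRelationsResult:
    """Run the full single-pot water-relations pipeline."""
    daily = water.daily_transpiration(series)
    biomass = water.daily_biomass_gain(series)
    merged = daily.merge(biomass, on="day", how="inner")
    wue = water.estimate_wue(merged["cumulative_biomass_g"].to_numpy(),
                             merged["cumulative_transpiration_g"].to_numpy(),
                             window_days=wue_window)
    tr = water.momentary_tr(series)
    weights = water.plant_weight_series(series, wue.slope)
    midday = water.midday_normalized_tr(tr, series, weights, window=midday_window)

    fit = None
    if fit_response:
        n_fit_days = series.policy.pre_days + series.policy.drought_days
        # days whose recorded VWC collapsed to ~0 ran dry intra-day; their
        # midday transpiration is supply- not stomata-limited
        per_day = int(round(24 * 60 / series.resolution_min))
        day_min_vwc = series.vwc[: (len(series.vwc) // per_day) * per_day] \
            .reshape(-1, per_day).min(axis=1)
        usable = midday["day"].map(lambda d: day_min_vwc[int(d)] > 0.02)
        pts = midday[(midday["day"] < n_fit_days) & usable].dropna()
        if len(pts) >= 6:
            fit = fit_logistic_response(pts["midday_vwc_m3_m3"].to_numpy(),
                                        pts["tr_m_vpd_mg_min_kpa_gfw"].to_numpy())
    return WaterRelationsResult(daily=merged, wue=wue, midday=midday,
                                fit=fit, phase_shifts=None)


def analyze_pair(
    ww: LysimeterSeries,
    treated: LysimeterSeries,
    **kwargs,
) -> tuple[WaterRelationsResult, WaterRelationsResult, pd.DataFrame]:
    """Analyze a WW/treated pair and the per-drought-day phase shifts."""
    res_ww = analyze_pot(ww, **kwargs)
    res_tr = analyze_pot(treated, **kwargs)
    tr_ww = water.momentary_tr(ww)
    tr_tr = water.momentary_tr(treated)
    w_ww = water.plant_weight_series(ww, res_ww.wue.slope)
    w_tr = water.plant_weight_series(treated, res_tr.wue.slope)

    policy = treated.policy
    rows = []
    for day in range(policy.pre_days, policy.pre_days + policy.drought_days):
        ps = phase_shift(tr_ww, tr_tr, day,
                         weight_ww=w_ww, weight_treated=w_tr)
        rows.append({"day": day, "ww_peak_h": ps.ww_peak_h,
                     "treated_peak_h": ps.treated_peak_h,
                     "shift_h": ps.shift_h})
    shifts = pd.DataFrame(rows)
    res_tr.phase_shifts = shifts
    return res_ww, res_tr, shifts


def preset_recovery_study(preset, seeds, days: int = 28) -> pd.DataFrame:
    """Simulate paired pots and rerun the estimation pipeline per seed.

    For each seed: generate an environment and a WW/treated pair under
    ``preset`` (default noise), run the full water-relations pipeline and
    collect the fitted WUE, 4PL parameters and the maximum daily
    midday-peak phase shift across drought days.
    """
    from .simulate import simulate_environment, simulate_pair
    rows = []
    for seed in seeds:
        env = simulate_environment(days, seed=seed)
        ww, treated = simulate_pair(preset, env, seed=seed)
        _, res_tr, shifts = analyze_pair(ww, treated)
        f = res_tr.fit
        rows.append({
            "seed": seed,
            "wue": res_tr.wue.slope,
            "A1": f.A1 if f else np.nan,
            "A2": f.A2 if f else np.nan,
            "p": f.p if f else np.nan,
            "theta_c": f.theta_c if f else np.nan,
            "max_shift_h": float(np.nanmax(shifts["shift_h"].to_numpy())),
        })
    return pd.DataFrame(rows)


def condition_trait_vector(treated: LysimeterSeries,
                           sampling_days: dict | None = None) -> np.ndarray:
    """Mean transpiration trait aligned to the 12 stage x TOD cells.

    For each stage's sampling day, momentary transpiration is averaged in a
    one-hour window at each sampling hour (6, 12, 16); the resulting
    12-vector (stage-major order WW, MD, SD, RC) anchors gene-significance
    and module-trait analyses.
    """
    policy = treated.policy
    if sampling_days is None:
        sampling_days = {
            "WW": policy.pre_days - 2,
            "MD": policy.pre_days + policy.drought_days // 3,
            "SD": policy.pre_days + policy.drought_days - 2,
            "RC": policy.pre_days + policy.drought_days + 1,
        }
    tr = water.momentary_tr(treated)
    out = []
    for stage in ("WW", "MD", "SD", "RC"):
        day = sampling_days[stage]
        sl = treated.day_slice(day)
        tod = treated.hours[sl] % 24.0
        vals = tr.tr_g_per_min[sl]
        for hour in (6, 12, 16):
            win = (tod >= hour) & (tod < hour + 1)
            v = vals[win]
            out.append(float(np.nanmean(v)) if np.any(np.isfinite(v)) else 0.0)
    return np.array(out)
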