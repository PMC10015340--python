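"""Synthetic greenhouse environment series (VPD, PAR) at lysimeter resolution."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EnvironmentSeries:
    """Greenhouse atmosphere sampled on a fixed grid.

    ``hours`` are decimal hours since midnight of day 0, strictly increasing.
    ``vpd`` is vapor pressure deficit (kPa), ``par`` photosynthetically
    active radiation (umol m^-2 s^-1, zero at night), ``light`` the
    day/night flag (PAR > 0).
    """

    hours: np.ndarray
    vpd: np.ndarray
    par: np.ndarray
    light: np.ndarray
    resolution_min: float

    @property
    def n_days(self) -> int:
        return int(np.ceil(self.hours[-1] / 24.0))

    def day_slice(self, day: int) -> slice:
        per_day = int(round(24 * 60 / self.resolution_min))
        return slice(day * per_day, (day + 1) * per_day)

    def vpd_at(self, hours: np.ndarray) -> np.ndarray:
        """VPD at arbitrary decimal hours (linear interpolation)."""
        return np.interp(hours, self.hours, self.vpd)


# Diurnal shape parameters: half-sine day courses.  PAR is nonzero over
# 06:00-18:00; the VPD bump spans 07:00-19:00 so that it peaks at 13:00,
# matching the typical afternoon-lagged atmospheric demand.
PAR_ON, PAR_OFF = 6.0, 18.0
VPD_ON, VPD_OFF = 7.0, 19.0
VPD_NIGHT = 0.4
PAR_PEAK = 1200.0


def simulate_environment(
    days: int,
    resolution_min: float = 3.0,
    vpd_peak: float = 3.0,
    seed: int | None = 0,
    jitter: float = 0.05,
) -> EnvironmentSeries:
    """Generate a diurnal VPD/PAR series.

    VPD follows a night baseline with a half-sine midday bump peaking
    ``vpd_peak`` kPa at 13:00; PAR is a half-sine between 06:00 and 18:00.
    ``jitter`` is the lognormal s.d. of a per-day multiplicative factor on
    the VPD peak (0 disables day-to-day variation).  Deterministic for a
    fixed seed.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if resolution_min <= 0:
        raise ValueError("resolution_min must be positive")
    per_day = 24 * 60 / resolution_min
    if abs(per_day - round(per_day)) > 1e-9:
        raise ValueError("resolution must divide 24 h")
    per_day = int(round(per_day))

    rng = np.random.default_rng(seed)
    hours = np.arange(days * per_day) * (resolution_min / 60.0)
    tod = hours % 24.0

    par = np.where(
        (tod > PAR_ON) & (tod < PAR_OFF),
        PAR_PEAK * np.sin(np.pi * (tod - PAR_ON) / (PAR_OFF - PAR_ON)),
        0.0,
    )
    day_factor = np.ones(days)
    if jitter > 0:
        day_factor = rng.lognormal(mean=0.0, sigma=jitter, size=days)
    peak = np.repeat(day_factor * vpd_peak, per_day)
    # cubed half-sine: atmospheric demand concentrated around early afternoon
    vpd = VPD_NIGHT + np.where(
        (tod > VPD_ON) & (tod < VPD_OFF),
        (peak - VPD_NIGHT) * np.sin(np.pi * (tod - VPD_ON) / (VPD_OFF - VPD_ON)) ** 3,
        0.0,
    )
    return EnvironmentSeries(
        hours=hours,
        vpd=vpd,
        par=par,
        light=par > 0,
        resolution_min=resolution_min,
    )
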