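"""Forward simulation of a gravimetric (lysimeter) pot experiment.

The simulated system is a pot of soil plus plants standing on a load cell:
recorded system weight = tare + soil water pool + plant fresh weight
(+ Gaussian measurement noise).  Transpiration is driven by a species'
four-parameter logistic (4PL) stomatal response to soil water content,
multiplied by atmospheric demand (VPD), the day/night light gate, and
plant fresh weight.  Nightly feedback irrigation replaces a fraction f of
the previous day's water loss (f = 1 keeps the pot at capacity; f < 1
imposes progressive deficit).

Modelling conventions (see docs/methods.md for rationale):

* The stomatal response factor is constant within a day and evaluated at
  the day's midday mean VWC, obtained by fixed-point iteration of the
  within-day water balance.  The diurnal transpiration course is therefore
  separable, response(VWC) x VPD(t) x W(t), so the midday normalized
  transpiration paired with midday VWC sits exactly on the generating 4PL.
* Under drought, the profligate habit's midday peak is advanced by warping
  the VPD course in time: Tr uses VPD(t + a_d) where a_d ramps linearly in
  predawn VWC between ``phase_onset_vwc`` (advance 0) and
  ``phase_full_vwc`` (advance = ``phase_advance_max``).
* Plant growth is WUE x transpired water, drawn from the soil pool, so
  system weight obeys exact water conservation:
  weight(t2) - weight(t1) = sum(irrigation) - sum(transpiration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ..presets import SpeciesPreset
from .environment import PAR_OFF, PAR_ON, EnvironmentSeries


@dataclass(frozen=True)
class SoilPotSpec:
    """Pot, soil and drainage bookkeeping (grams / litres)."""

    soil_volume_l: float = 3.9
    capacity_vwc: float = 0.45
    tare_weight: float = 800.0
    soil_weight_at_capacity: float = 4000.0
    drainage_water_weight: float = 150.0

    def __post_init__(self):
        if not (0 < self.capacity_vwc <= 1):
            raise ValueError("capacity_vwc must be in (0, 1]")
        for f in (self.soil_volume_l, self.tare_weight,
                  self.soil_weight_at_capacity, self.drainage_water_weight):
            if f < 0:
                raise ValueError("pot spec weights/volumes must be >= 0")

    @property
    def soil_ml(self) -> float:
        return self.soil_volume_l * 1000.0

    @property
    def capacity_water_g(self) -> float:
        """Grams of plant-available water at pot capacity (1 g = 1 mL)."""
        return self.capacity_vwc * self.soil_ml

    @property
    def base_weight(self) -> float:
        """Non-plant, non-water constant part of system weight.

        ``soil_weight_at_capacity`` includes the water held at capacity, so
        the dry contribution is that weight minus the capacity water.
        """
        return (self.tare_weight + self.drainage_water_weight
                + self.soil_weight_at_capacity - self.capacity_water_g)


@dataclass(frozen=True)
class IrrigationPolicy:
    """Phase schedule and nightly feedback-irrigation rule.

    Defaults follow a 28-day experiment: 12 pre-treatment days, 14 drought
    days, 2 recovery days.  During drought the treated pot receives
    ``feedback_fraction`` x (previous-day water loss); all other phases
    (and well-watered pots throughout) receive full replacement.
    """

    pre_days: int = 12
    drought_days: int = 14
    recovery_days: int = 2
    feedback_fraction: float = 0.8
    irrigation_hour: float = 21.5
    drought_floor_vwc: float = 0.10

    def __post_init__(self):
        if not (0 <= self.feedback_fraction <= 1):
            raise ValueError("feedback_fraction must be in [0, 1]")
        if not (19.0 <= self.irrigation_hour < 24.0 or 0.0 <= self.irrigation_hour < 5.0):
            raise ValueError("irrigation window must fall in dark hours")
        if min(self.pre_days, self.drought_days, self.recovery_days) < 0:
            raise ValueError("phase lengths must be >= 0")

    @property
    def total_days(self) -> int:
        return self.pre_days + self.drought_days + self.recovery_days

    def phase_of(self, day: int) -> str:
        if day < self.pre_days:
            return "pre"
        if day < self.pre_days + self.drought_days:
            return "drought"
        return "recovery"


@dataclass
class LysimeterSeries:
    """Recorded output of one simulated pot."""

    pot_id: str
    species: str
    group: str  # "WW" | "treated"
    hours: np.ndarray
    weight_g: np.ndarray
    vwc: np.ndarray
    vpd: np.ndarray
    par: np.ndarray
    light: np.ndarray
    irrigation_events: list  # (hour, volume g)
    resolution_min: float
    policy: IrrigationPolicy
    pot: SoilPotSpec
    flags: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    @property
    def n_days(self) -> int:
        return int(round(self.hours[-1] + self.resolution_min / 60.0)) // 24

    def day_slice(self, day: int) -> slice:
        per_day = int(round(24 * 60 / self.resolution_min))
        return slice(day * per_day, (day + 1) * per_day)


def fourpl(vwc, A1, A2, p, theta_c):
    """4PL response: A2 + (A1 - A2) / (1 + (theta_c / vwc)**p)."""
    vwc = np.asarray(vwc, dtype=float)
    if np.any(vwc <= 0):
        raise ValueError("vwc must be positive")
    return A2 + (A1 - A2) / (1.0 + (theta_c / vwc) ** p)


def _phase_advance(preset: SpeciesPreset, predawn_vwc: float) -> float:
    if preset.phase_advance_max == 0:
        return 0.0
    ramp = (preset.phase_onset_vwc - predawn_vwc) / (
        preset.phase_onset_vwc - preset.phase_full_vwc)
    return preset.phase_advance_max * float(np.clip(ramp, 0.0, 1.0))


def simulate_lysimeter(
    preset: SpeciesPreset,
    env: EnvironmentSeries,
    policy: IrrigationPolicy | None = None,
    pot: SoilPotSpec | None = None,
    seed: int | None = 0,
    group: str = "treated",
    pot_id: str | None = None,
) -> LysimeterSeries:
    """Simulate one pot for the policy's full schedule.

    ``group="WW"`` forces full nightly replacement (f = 1), no recovery
    throttle and (because predawn VWC stays at capacity) no phase warp.
    Measurement noise is Gaussian on recorded weight with the preset's
    ``noise_sd_weight``; soil-moisture probe readings are returned clean.
    """
    policy = policy or IrrigationPolicy()
    pot = pot or SoilPotSpec()
    preset.validate(pot_capacity_vwc=pot.capacity_vwc)
    if group not in ("WW", "treated"):
        raise ValueError("group must be 'WW' or 'treated'")
    if env.n_days < policy.total_days:
        raise ValueError("environment series does not cover the policy schedule")

    rng = np.random.default_rng(seed)
    per_day = int(round(24 * 60 / env.resolution_min))
    dt = env.resolution_min  # minutes
    n = policy.total_days * per_day

    pool = pot.capacity_water_g
    plant = preset.initial_plant_weight
    removed_since_irr = 0.0

    pool_path = np.empty(n)
    plant_path = np.empty(n)
    events: list[tuple[float, float]] = []
    flags: list[str] = []
    gate_by_day = np.empty(policy.total_days)
    advance_by_day = np.empty(policy.total_days)
    tr_path = np.empty(n)

    irr_idx = int(round(policy.irrigation_hour * 60 / dt))  # sample index within day

    for day in range(policy.total_days):
        sl = env.day_slice(day)
        hours_day = env.hours[sl]
        tod = hours_day % 24.0
        light = env.light[sl]

        phase = policy.phase_of(day)
        mult = 1.0
        f = 1.0
        if group == "treated":
            if phase == "drought":
                f = policy.feedback_fraction
            elif phase == "recovery":
                mult = preset.recovery_fraction

        predawn_vwc = pool / pot.soil_ml
        advance = _phase_advance(preset, predawn_vwc) if group == "treated" else 0.0
        # midpoint rule: each step's flow uses VPD at the step centre, so a
        # centered finite difference of the weight series is flow-unbiased
        half = dt / 60.0 / 2.0
        mid_h = hours_day + half
        tod_mid = mid_h % 24.0
        light_mid = (tod_mid > PAR_ON) & (tod_mid < PAR_OFF)
        drive = np.where(light_mid, env.vpd_at(mid_h + advance), 0.0)

        midday = (tod >= 12.0) & (tod < 16.0)
        uptake_per_g = drive * dt / 1000.0  # (mg->g) per unit response per g FW

        # State is recorded at sample times (start of step): sample i holds
        # the state before the flow of step [t_i, t_i + dt).
        def day_pass(gate: float, k_override=None):
            k = gate * uptake_per_g if k_override is None else k_override
            # exact exponential within-step growth: the step's transpiration
            # (W_next - W)/wue equals k x midpoint weight to second order,
            # which a centered difference of the weight series recovers
            # without bias
            growth_factor = np.cumprod(np.exp(preset.wue * k))
            w_steps = plant * np.concatenate(([1.0], growth_factor[:-1]))
            tr_steps = w_steps * np.expm1(preset.wue * k) / preset.wue
            removal = tr_steps * (1.0 + preset.wue)  # transpiration + growth uptake
            pool_steps = pool - np.concatenate(([0.0], np.cumsum(removal)[:-1]))
            v_mid = float(np.mean(pool_steps[midday])) / pot.soil_ml
            return v_mid, growth_factor, w_steps, tr_steps, removal, pool_steps

        def response(v: float) -> float:
            return mult * float(fourpl(max(v, 1e-4), preset.A1, preset.A2,
                                       preset.steepness, preset.theta_c))

        # The response factor is evaluated at the midday mean VWC produced
        # under that same factor.  g - response(v_mid(g)) is monotone
        # increasing in g (more draw -> lower midday VWC -> lower response),
        # so the self-consistent factor is the unique bracketed root.
        g_hi = response(predawn_vwc)
        g_lo = mult * preset.A2
        def _resid(g):
            return g - response(day_pass(g)[0])
        if g_hi <= g_lo + 1e-12 or _resid(g_hi) <= 0:
            gate = g_hi
        else:
            gate = float(optimize.brentq(_resid, g_lo, g_hi, xtol=1e-13))
        v_mid, growth_factor, w_steps, tr_steps, removal, pool_steps = day_pass(gate)

        # Physical shutoff: once the pool is exhausted, transpiration stops.
        pool_after = pool - np.cumsum(removal)
        if pool_after[-1] <= 0:
            idx0 = int(np.argmax(pool_after <= 0))
            k = gate * uptake_per_g
            k[idx0:] = 0.0
            _, growth_factor, w_steps, tr_steps, removal, pool_steps = \
                day_pass(gate, k_override=k)
            flags.append(f"day {day}: soil water pool exhausted")

        gate_by_day[day] = gate
        advance_by_day[day] = advance

        pool_day = pool_steps.copy()
        plant_day = w_steps
        pool_end = pool - float(np.sum(removal))

        # Nightly irrigation event (transpiration is zero then, so it does
        # not interact with the daytime root solve).  The event's volume
        # appears in the recorded series from the following sample on.
        # Under severe deficit the feedback system keeps predawn VWC at or
        # above the policy floor (pots are droughted, not killed).
        removed_today = float(np.sum(removal))
        removed_by_event = float(np.sum(removal[: irr_idx + 1]))
        pool_at_event = pool - removed_by_event
        deficit_at_event = pot.capacity_water_g - pool_at_event
        if phase == "drought" and group == "treated":
            irr = f * (removed_since_irr + removed_by_event)
            floor_pool = policy.drought_floor_vwc * pot.soil_ml
            if pool_at_event + irr < floor_pool:
                irr = floor_pool - pool_at_event
        else:
            # full replacement: refill to pot capacity (rewatering after
            # drought must also recover the accumulated deficit)
            irr = deficit_at_event
        irr = float(np.clip(irr, 0.0, max(deficit_at_event, 0.0)))
        pool_day[irr_idx + 1:] += irr
        pool_end += irr
        events.append((hours_day[irr_idx], irr))
        removed_since_irr = (removed_today - removed_by_event if irr > 0
                             else removed_since_irr + removed_today)

        pool_path[sl] = pool_day
        plant_path[sl] = plant_day
        tr_path[sl] = tr_steps
        pool = pool_end
        plant = plant * float(growth_factor[-1])

    weight = pot.base_weight + pool_path + plant_path
    if preset.noise_sd_weight > 0:
        weight = weight + rng.normal(0.0, preset.noise_sd_weight, size=n)

    return LysimeterSeries(
        pot_id=pot_id or f"{preset.name}-{group}",
        species=preset.name,
        group=group,
        hours=env.hours[:n].copy(),
        weight_g=weight,
        vwc=pool_path / pot.soil_ml,
        vpd=env.vpd[:n].copy(),
        par=env.par[:n].copy(),
        light=env.light[:n].copy(),
        irrigation_events=events,
        resolution_min=env.resolution_min,
        policy=policy,
        pot=pot,
        flags=flags,
        truth={
            "plant_weight": plant_path,
            "gate_by_day": gate_by_day,
            "advance_by_day": advance_by_day,
            "transpiration": tr_path,
        },
    )


def simulate_pair(
    preset: SpeciesPreset,
    env: EnvironmentSeries,
    policy: IrrigationPolicy | None = None,
    pot: SoilPotSpec | None = None,
    seed: int | None = 0,
) -> tuple[LysimeterSeries, LysimeterSeries]:
    """Simulate a matched WW / treated pot pair sharing one environment."""
    ss = np.random.SeedSequence(seed)
    s_ww, s_tr = ss.spawn(2)
    ww = simulate_lysimeter(preset, env, policy, pot, seed=s_ww, group="WW")
    treated = simulate_lysimeter(preset, env, policy, pot, seed=s_tr, group="treated")
    return ww, treated
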