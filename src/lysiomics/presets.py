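"""Species presets for the whole-plant drought-response simulator.

A preset bundles the parameters of the four-parameter logistic (4PL)
stomatal response of midday VPD- and weight-normalized transpiration
(Tr_m,VPD) to volumetric soil water content (VWC), together with the
water-use efficiency, the diurnal phase-advance behaviour under drought,
and measurement-noise settings.

Two defaults are provided:

``conservative``
    A cowpea-like water saver: lower maximal normalized transpiration,
    high critical VWC (stomata begin closing while soil is still moist),
    higher WUE, and no drought-induced phase shift of the midday peak.

``profligate``
    A soybean-like water spender: higher maximal normalized transpiration,
    low critical VWC, lower WUE, and a midday transpiration peak that
    advances by up to 1.9 h as drought becomes severe.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class SpeciesPreset:
    """Parameterization of one species' water-use behaviour.

    Attributes
    ----------
    name : str
        Label used in outputs.
    A1 : float
        Upper asymptote of the 4PL response: midday normalized transpiration
        under ample soil water (mg H2O min^-1 kPa^-1 g^-1 FW).
    A2 : float
        Lower asymptote under severe drought (same units; 0 < A2 < A1).
    theta_c : float
        Critical VWC (m^3/m^3): the inflection point at which normalized
        transpiration declines fastest.
    steepness : float
        Dimensionless sharpness p > 0 of the logistic transition.
    wue : float
        Water-use efficiency, g fresh biomass gained per g water transpired.
    initial_plant_weight : float
        Fresh weight (g) of the plants in a pot at the experiment start.
    phase_advance_max : float
        Maximum advance (hours >= 0) of the diurnal transpiration peak,
        reached when predawn VWC falls to ``phase_full_vwc``.
    phase_onset_vwc : float
        Predawn VWC below which the phase advance starts ramping in.
    phase_full_vwc : float
        Predawn VWC at (and below) which the advance equals
        ``phase_advance_max``.
    noise_sd_weight : float
        Gaussian measurement noise s.d. (g) added to recorded system weight.
    recovery_fraction : float
        Multiplier in (0, 1] applied to the stomatal response during the
        recovery phase (transpiration typically resumes at ~80% of the
        well-watered level within two days of rewatering).
    """

    name: str
    A1: float
    A2: float
    theta_c: float
    steepness: float
    wue: float
    initial_plant_weight: float
    phase_advance_max: float
    phase_onset_vwc: float
    phase_full_vwc: float
    noise_sd_weight: float
    recovery_fraction: float

    def validate(self, pot_capacity_vwc: float | None = None) -> None:
        if not (self.A1 > self.A2 > 0):
            raise ValueError("preset requires A1 > A2 > 0")
        if self.theta_c <= 0:
            raise ValueError("theta_c must be positive")
        if pot_capacity_vwc is not None and self.theta_c >= pot_capacity_vwc:
            raise ValueError("theta_c must lie below pot-capacity VWC")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if not (0 < self.wue < 1):
            raise ValueError("wue must be in (0, 1)")
        if self.phase_advance_max < 0:
            raise ValueError("phase_advance_max must be >= 0")
        if self.phase_onset_vwc <= self.phase_full_vwc:
            raise ValueError("phase_onset_vwc must exceed phase_full_vwc")
        if not (0 < self.recovery_fraction <= 1):
            raise ValueError("recovery_fraction must be in (0, 1]")
        if self.noise_sd_weight < 0:
            raise ValueError("noise_sd_weight must be >= 0")
        if self.initial_plant_weight <= 0:
            raise ValueError("initial_plant_weight must be positive")

    def with_(self, **kwargs) -> "SpeciesPreset":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)


def species_presets() -> dict[str, SpeciesPreset]:
    """Default conservative (cowpea-like) and profligate (soybean-like) presets."""
    conservative = SpeciesPreset(
        name="conservative",
        A1=3.747,
        A2=0.913,
        theta_c=0.350,
        steepness=10.0,
        wue=0.065,
        initial_plant_weight=12.0,
        phase_advance_max=0.0,
        phase_onset_vwc=0.35,
        phase_full_vwc=0.18,
        noise_sd_weight=1.0,
        recovery_fraction=0.8,
    )
    profligate = SpeciesPreset(
        name="profligate",
        A1=5.247,
        A2=0.451,
        theta_c=0.263,
        steepness=6.0,
        wue=0.054,
        initial_plant_weight=12.0,
        phase_advance_max=1.9,
        phase_onset_vwc=0.35,
        phase_full_vwc=0.18,
        noise_sd_weight=1.0,
        recovery_fraction=0.8,
    )
    return {"conservative": conservative, "profligate": profligate}
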