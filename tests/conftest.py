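import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def presets():
    from lysiomics.presets import species_presets
    return species_presets()


@pytest.fixture(scope="session")
def short_env():
    from lysiomics.simulate import simulate_environment
    return simulate_environment(5, seed=11, jitter=0.0)


@pytest.fixture(scope="session")
def full_env():
    from lysiomics.simulate import simulate_environment
    return simulate_environment(28, seed=11)


@pytest.fixture(scope="session")
def clean_pair(presets, full_env):
    """Noise-free conservative WW/treated pair over the full schedule."""
    from lysiomics.simulate import simulate_pair
    p = presets["conservative"].with_(noise_sd_weight=0.0)
    return simulate_pair(p, full_env, seed=11)


@pytest.fixture(scope="session")
def small_counts():
    """Default-structure count simulation at reduced size."""
    from lysiomics.simulate import ExpressionSimSpec, simulate_counts
    spec = ExpressionSimSpec(n_genes=400, seed=7)
    return simulate_counts(spec)


def make_series(hours, weight, vpd=None, events=(), resolution_min=3.0,
                policy=None, pot=None, vwc=None):
    """Assemble a LysimeterSeries directly from arrays (for estimator tests)."""
    from lysiomics.simulate import IrrigationPolicy, LysimeterSeries, SoilPotSpec
    hours = np.asarray(hours, dtype=float)
    n = len(hours)
    vpd = np.full(n, 2.0) if vpd is None else np.asarray(vpd, dtype=float)
    par = np.where((hours % 24 > 6) & (hours % 24 < 18), 1000.0, 0.0)
    return LysimeterSeries(
        pot_id="test", species="test", group="treated",
        hours=hours, weight_g=np.asarray(weight, dtype=float),
        vwc=np.full(n, 0.4) if vwc is None else np.asarray(vwc, dtype=float),
        vpd=vpd, par=par, light=par > 0,
        irrigation_events=list(events), resolution_min=resolution_min,
        policy=policy or IrrigationPolicy(), pot=pot or SoilPotSpec())
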