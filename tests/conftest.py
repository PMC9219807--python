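import math

import numpy as np
import pytest

from allopred import ConcProfile, SimScenario


@pytest.fixture
def make_profile():
    """Factory for valid profiles with overridable fields."""

    def _make(times=(1.0, 7.0, 14.0), concs=(100.0, 50.0, 10.0), **kw):
        defaults = dict(
            species_label="monkey",
            body_weight=3.5,
            dose_per_kg=1.0,
            analyte="total",
        )
        defaults.update(kw)
        return ConcProfile(times=tuple(times), concentrations=tuple(concs), **defaults)

    return _make


@pytest.fixture
def mono_profile(make_profile):
    """Noiseless mono-exponential decay C(t) = 100 e^(-0.1 t), dense 0-60 d."""
    times = np.linspace(0.0, 60.0, 241)
    concs = 100.0 * np.exp(-0.1 * times)
    # dose 10 mg, V = 0.1 L, k = 0.1/day -> CL = 0.01 L/day, AUC_inf = 1000
    return make_profile(times=times, concs=concs, species_label="human",
                        body_weight=70.0, dose_per_kg=10.0 / 70.0)


@pytest.fixture
def base_scenario():
    """Monkey-like two-compartment scenario with well-separated phases."""

    def _make(**kw):
        defaults = dict(
            ref_weight=3.5,
            cl_ref=0.02,
            v1_ref=0.15,
            q_ref=0.03,
            v2_ref=0.10,
            dose_animal_per_kg=1.0,
            dose_human_per_kg=5.0,
            e_cl=0.85,
            e_v=1.0,
            noise_cv=0.0,
            seed=0,
        )
        defaults.update(kw)
        return SimScenario(**defaults)

    return _make
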