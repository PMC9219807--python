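import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from allopred import (
    METHOD_PRESETS,
    PKScalingSpec,
    SimScenario,
    SimulationError,
    ValidationError,
    evaluate,
    load_scenario,
    macro_constants,
    nca_summary,
    predict_human_clearance,
    predict_human_half_life,
    predict_profile,
    simulate_pair,
)
from allopred.synthetic_pk import concentrations


def ode_concentrations(cl, v1, q, v2, dose_total, times):
    """Independent oracle: integrate the two-compartment ODE system."""
    k10, k12, k21 = cl / v1, q / v1, q / v2

    def rhs(_t, y):
        a1, a2 = y
        return [-(k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2]

    sol = solve_ivp(rhs, (0.0, max(times)), [dose_total, 0.0], t_eval=times,
                    rtol=1e-10, atol=1e-12, method="LSODA")
    return sol.y[0] / v1


class TestMacroConstants:
    def test_one_compartment_limit(self):
        mc = macro_constants(cl=0.01, v1=0.1, q=0.0, v2=1.0, dose_total=10.0)
        assert mc.A == pytest.approx(100.0, rel=1e-12)
        assert mc.B == 0.0
        assert mc.alpha == pytest.approx(0.1, rel=1e-12)
        assert mc.beta == 0.0

    def test_initial_concentration_identity(self):
        mc = macro_constants(cl=0.4, v1=3.0, q=0.6, v2=2.0, dose_total=350.0)
        assert mc.c0 == pytest.approx(350.0 / 3.0, rel=1e-9)
        assert mc.alpha > mc.beta > 0

    def test_matches_ode_oracle(self):
        cl, v1, q, v2, dose = 0.4, 3.0, 0.6, 2.0, 350.0
        mc = macro_constants(cl, v1, q, v2, dose)
        times = np.linspace(0.1, 40.0, 20)
        closed = concentrations(mc, times)
        oracle = ode_concentrations(cl, v1, q, v2, dose, times)
        np.testing.assert_allclose(closed, oracle, rtol=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            macro_constants(cl=0.0, v1=1.0, q=0.1, v2=1.0, dose_total=1.0)


pk_values = st.floats(min_value=1e-3, max_value=1e2, allow_nan=False)


@given(cl=pk_values, v1=pk_values, q=pk_values, v2=pk_values, dose=pk_values)
@settings(max_examples=200, deadline=None)
def test_vieta_root_identities(cl, v1, q, v2, dose):
    mc = macro_constants(cl, v1, q, v2, dose)
    k10, k12, k21 = cl / v1, q / v1, q / v2
    assert mc.alpha + mc.beta == pytest.approx(k10 + k12 + k21, rel=1e-10)
    assert mc.alpha * mc.beta == pytest.approx(k10 * k21, rel=1e-10)
    assert mc.A + mc.B == pytest.approx(dose / v1, rel=1e-9)


class TestScenario:
    def test_strictly_increasing_times_required(self, base_scenario):
        with pytest.raises(ValidationError):
            base_scenario(sampling_times=(1.0, 1.0, 2.0))

    def test_exponent_range(self, base_scenario):
        with pytest.raises(ValidationError):
            base_scenario(e_v=1.6)

    def test_negative_noise_rejected(self, base_scenario):
        with pytest.raises(ValidationError):
            base_scenario(noise_cv=-0.1)

    def test_load_scenario_yaml(self, tmp_path, base_scenario):
        path = tmp_path / "scen.yaml"
        path.write_text(
            "ref_weight: 3.5\ncl_ref: 0.02\nv1_ref: 0.15\nq_ref: 0.03\n"
            "v2_ref: 0.1\ndose_animal_per_kg: 1.0\ndose_human_per_kg: 5.0\n"
            "e_cl: 0.85\ne_v: 1.0\nseed: 3\n"
        )
        assert load_scenario(path) == base_scenario(seed=3)

    def test_load_scenario_unknown_key(self, tmp_path):
        path = tmp_path / "scen.yaml"
        path.write_text("ref_weight: 3.5\nbogus: 1\n")
        with pytest.raises(ValidationError, match="bogus"):
            load_scenario(path)


class TestSimulatePair:
    def test_truth_record_power_laws(self, base_scenario):
        sc = base_scenario(e_cl=0.85, e_v=0.9)
        _, _, truth = simulate_pair(sc)
        r = 70.0 / 3.5
        assert truth["cl_human"] == pytest.approx(sc.cl_ref * r**0.85, rel=1e-12)
        assert truth["q_human"] == pytest.approx(sc.q_ref * r**0.85, rel=1e-12)
        assert truth["v1_human"] == pytest.approx(sc.v1_ref * r**0.9, rel=1e-12)
        assert truth["v2_human"] == pytest.approx(sc.v2_ref * r**0.9, rel=1e-12)
        assert truth["thalf_terminal_human"] == pytest.approx(
            math.log(2) / truth["beta_human"], rel=1e-12
        )

    def test_determinism_same_seed(self, base_scenario):
        sc = base_scenario(noise_cv=0.2, seed=42)
        a1, h1, t1 = simulate_pair(sc)
        a2, h2, t2 = simulate_pair(sc)
        assert a1 == a2 and h1 == h2 and t1 == t2

    def test_different_seed_differs(self, base_scenario):
        sc = base_scenario(noise_cv=0.2, seed=1)
        a1, _, _ = simulate_pair(sc)
        a2, _, _ = simulate_pair(replace(sc, seed=2))
        assert a1.concentrations != a2.concentrations

    def test_noiseless_matches_closed_form(self, base_scenario):
        sc = base_scenario()
        animal, _, _ = simulate_pair(sc)
        mc = macro_constants(sc.cl_ref, sc.v1_ref, sc.q_ref, sc.v2_ref,
                             sc.dose_animal_per_kg * sc.ref_weight)
        np.testing.assert_allclose(
            animal.concentrations, concentrations(mc, animal.times), rtol=1e-12
        )

    def test_lloq_censors_points(self, base_scenario):
        free = simulate_pair(base_scenario())[0]
        censored = simulate_pair(base_scenario(lloq=min(free.concentrations) * 1.01))[0]
        assert censored.n < free.n
        assert min(censored.concentrations) >= min(free.concentrations)

    def test_all_censored_raises(self, base_scenario):
        with pytest.raises(SimulationError):
            simulate_pair(base_scenario(lloq=1e9))

    @pytest.mark.parametrize("b,method_id", [(0.8, "III"), (0.9, "II"), (1.0, "I")])
    def test_matching_exponent_reproduces_human_exactly(self, base_scenario, b, method_id):
        sc = base_scenario(e_cl=b, e_v=b)
        animal, human, _ = simulate_pair(sc)
        pred = predict_profile(animal, sc.dose_human_per_kg, METHOD_PRESETS[method_id])
        report = evaluate(pred, human)
        assert report.afe == pytest.approx(1.0, abs=1e-9)
        assert report.bin_counts["within_0.7_1.3"] == report.n

    def test_method_i_underprediction_grows_with_time(self, base_scenario):
        # e_v = 1.0, e_cl = 0.85: human kinetics are slower, so the
        # unity-exponent projection falls further below truth over time
        sc = base_scenario(e_v=1.0, e_cl=0.85)
        animal, human, _ = simulate_pair(sc)
        pred = predict_profile(animal, sc.dose_human_per_kg, METHOD_PRESETS["I"])
        ratios = [r for _, r in evaluate(pred, human).ratios]
        assert all(b < a for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] < 1.0


class TestCrossModuleRecovery:
    def test_nca_recovers_truth_parameters(self, base_scenario):
        # early first sample (no t=0 back-extrapolation) and >= 5 terminal
        # half-lives of coverage
        times = tuple(np.geomspace(0.01, 120.0, 60))
        sc = base_scenario(sampling_times=times)
        _, human, truth = simulate_pair(sc)
        res = nca_summary(human)
        assert res.clearance == pytest.approx(truth["cl_human"], rel=0.02)
        assert res.thalf == pytest.approx(truth["thalf_terminal_human"], rel=0.02)

    def test_fixed_exponent_scaling_consistency(self, base_scenario):
        # Eq-style fixed exponents (CL 0.85, t1/2 0.15) assume e_cl = 0.85,
        # e_v = 1.0; under that simulation they must match human NCA within 5%
        times = tuple(np.geomspace(0.25, 150.0, 80))
        sc = base_scenario(e_cl=0.85, e_v=1.0, sampling_times=times)
        animal, human, _ = simulate_pair(sc)
        nca_a = nca_summary(animal)
        nca_h = nca_summary(human)
        spec = PKScalingSpec()
        cl_pred = predict_human_clearance(nca_a.clearance, sc.ref_weight, spec)
        thalf_pred = predict_human_half_life(nca_a.thalf, sc.ref_weight, spec)
        assert cl_pred == pytest.approx(nca_h.clearance, rel=0.05)
        assert thalf_pred == pytest.approx(nca_h.thalf, rel=0.05)
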