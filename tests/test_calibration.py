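"""Calibration tests: condition maps, the ATP objective and bounded fit,
and the Ca²⁺→insulin scaling fit."""

import numpy as np
import pytest

from betacell.calibration import (
    CalibrationScales,
    Condition,
    FluxMap,
    ObservationTable,
    atp_objective,
    condition_to_fluxes,
    condition_to_inputs,
    fit_atp,
    fit_calcium_scaling,
    insulin_objective,
)
from betacell.metabolic import MetabolicParameters
from betacell.synthetic import (
    NoiseModel,
    atp_fit_conditions,
    insulin_fit_conditions,
    simulate_observations,
)


class TestCondition:
    def test_alanine_and_aib_mutually_exclusive(self):
        with pytest.raises(ValueError):
            Condition(alanine=10.0, aib=10.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            Condition(glucose=-1.0)

    def test_basal_maps_to_basal_inputs(self):
        s = CalibrationScales()
        k_atp, g = condition_to_inputs(Condition(), s)
        assert k_atp == s.k_atp_basal
        assert g == 0.0

    def test_alanine_vs_aib_same_conductance_different_katp(self):
        s = CalibrationScales()
        k_ala, g_ala = condition_to_inputs(Condition(alanine=10.0), s)
        k_aib, g_aib = condition_to_inputs(Condition(aib=10.0), s)
        assert g_ala == g_aib
        assert k_ala > k_aib
        assert k_aib == s.k_atp_basal

    def test_equipotency_anchor(self):
        # k_ATP(10 mmol/l alanine) == k_ATP(16.7 mmol/l glucose)
        s = CalibrationScales()
        k_ala, _ = condition_to_inputs(Condition(alanine=10.0), s)
        k_glc, _ = condition_to_inputs(Condition(glucose=16.7), s)
        assert k_ala == pytest.approx(k_glc, rel=1e-12)

    def test_oligomycin_clamps_katp_to_basal(self):
        s = CalibrationScales()
        k, g = condition_to_inputs(
            Condition(glucose=16.7, alanine=10.0, oligomycin=True), s)
        assert k == s.k_atp_basal
        assert g == s.ala_to_gnaala * 10.0

    def test_aib_carries_no_metabolic_flux(self):
        j_glc, j_ala = condition_to_fluxes(Condition(aib=10.0), FluxMap())
        assert j_glc == 0.0 and j_ala == 0.0


class TestAtpObjective:
    def _table(self, values, conds=None):
        conds = conds or [Condition(glucose=g) for g in (5.0, 16.7)]
        v = np.asarray(values, dtype=float)
        return ObservationTable(conds, v, 0.1 * v, kind="ATP")

    def test_perfect_fit_is_zero(self):
        conds = [Condition(), Condition(glucose=5.0), Condition(glucose=16.7)]
        obs = simulate_observations(conds, NoiseModel(cv=0.0, seed=0), kind="ATP")
        assert atp_objective({}, obs) == pytest.approx(0.0, abs=1e-16)

    def test_single_observation_double_value(self):
        # observation set to half the simulated value: ((2−1)/1)² = 1
        from betacell.calibration import _steady_atp
        true_sim = _steady_atp(MetabolicParameters(), Condition(glucose=5.0), FluxMap())
        obs = self._table([true_sim / 2.0], [Condition(glucose=5.0)])
        assert atp_objective({}, obs) == pytest.approx(1.0, rel=1e-6)

    def test_matches_vectorised_spreadsheet_oracle(self):
        conds = [Condition(glucose=g) for g in (1.1, 5.0, 16.7)]
        from betacell.calibration import _steady_atp
        sims = np.array([_steady_atp(MetabolicParameters(), c, FluxMap())
                         for c in conds])
        rng = np.random.default_rng(7)
        ys = sims * rng.uniform(0.8, 1.2, size=sims.size)
        obs = ObservationTable(conds, ys, 0.1 * ys, kind="ATP")
        expected = float(np.sum(((sims - ys) / ys) ** 2))
        assert atp_objective({}, obs) == pytest.approx(expected, abs=1e-12)

    def test_basal_observation_excluded(self):
        conds = [Condition(), Condition(glucose=5.0)]
        # absurd basal value: must not contribute
        obs = ObservationTable(conds, np.array([99.0, 1.0]),
                               np.array([1.0, 0.1]), kind="ATP")
        with_basal = atp_objective({}, obs, include_basal=True)
        without = atp_objective({}, obs)
        assert without < with_basal

    def test_wrong_kind_rejected(self):
        obs = ObservationTable([Condition(glucose=5.0)], np.array([1.0]),
                               np.array([0.1]), kind="insulin")
        with pytest.raises(ValueError):
            atp_objective({}, obs)


@pytest.fixture(scope="module")
def small_obs():
    # mid-to-high influx conditions keep every optimiser iterate away
    # from the low-glucose glycolytic-oscillation region
    conds = [Condition(glucose=g) for g in (5.0, 16.7, 30.0)] + [
        Condition(alanine=10.0)]
    return simulate_observations(conds, NoiseModel(cv=0.0, seed=0), kind="ATP")


class TestFitAtp:

    def test_fixed_point_at_truth(self, small_obs):
        p = MetabolicParameters()
        theta0 = {"k8": p["k8"], "k23": p["k23"]}
        fit = fit_atp(small_obs, theta0, maxiter=5)
        assert fit.objective == pytest.approx(0.0, abs=1e-10)
        for k, v in theta0.items():
            assert fit.params[k] == pytest.approx(v, rel=1e-6)

    def test_perturbed_start_recovers_parameters(self, small_obs):
        p = MetabolicParameters()
        truth = {"k8": p["k8"], "k21": p["k21"]}
        theta0 = {k: 1.5 * v for k, v in truth.items()}
        bounds = {k: (0.2 * v, 5.0 * v) for k, v in truth.items()}
        fit = fit_atp(small_obs, theta0, bounds=bounds, maxiter=40)
        assert fit.objective < 1e-5
        for k, v in truth.items():
            assert fit.params[k] == pytest.approx(v, rel=0.10), k

    def test_excluding_truth_pins_solution_at_bound(self, small_obs):
        p = MetabolicParameters()
        # bounds strictly above the generating k21: optimum hits the bound
        bounds = {"k21": (1.5 * p["k21"], 3.0 * p["k21"])}
        fit = fit_atp(small_obs, {"k21": 2.0 * p["k21"]}, bounds=bounds, maxiter=30)
        assert "k21" in fit.at_bounds
        assert fit.objective > 0.01

    def test_trace_never_increases(self, small_obs):
        p = MetabolicParameters()
        fit = fit_atp(small_obs, {"k8": 1.3 * p["k8"]}, maxiter=15)
        assert all(b <= a + 1e-12 for a, b in zip(fit.trace, fit.trace[1:]))
        assert fit.objective <= fit.trace[0] + 1e-12


class TestScalingFit:
    def test_zero_noise_exact_recovery(self, mean_ca_surrogate):
        truth = CalibrationScales()
        obs = simulate_observations(
            insulin_fit_conditions(), NoiseModel(cv=0.0, seed=0),
            kind="insulin", scales=truth, mean_ca=mean_ca_surrogate)
        fit = fit_calcium_scaling(obs, mean_ca_surrogate, scales0=truth)
        assert fit.objective < 1e-20
        assert fit.params["insulin_per_ca"] == pytest.approx(truth.insulin_per_ca, rel=1e-6)
        assert fit.params["glc_to_katp"] == pytest.approx(truth.glc_to_katp, rel=1e-6)
        assert fit.params["ala_to_gnaala"] == pytest.approx(truth.ala_to_gnaala, rel=1e-6)

    def test_objective_zero_at_truth(self, mean_ca_surrogate):
        truth = CalibrationScales()
        obs = simulate_observations(
            insulin_fit_conditions(), NoiseModel(cv=0.0, seed=0),
            kind="insulin", scales=truth, mean_ca=mean_ca_surrogate)
        assert insulin_objective(truth, obs, mean_ca_surrogate) == pytest.approx(0.0, abs=1e-18)

    def test_wrong_design_shape_rejected(self, mean_ca_surrogate):
        conds = [Condition()] + [Condition(glucose=g) for g in (1.1, 5.0, 16.7)]
        obs = ObservationTable(conds, np.ones(4), 0.1 * np.ones(4), kind="insulin")
        with pytest.raises(ValueError, match="glucose-only"):
            fit_calcium_scaling(obs, mean_ca_surrogate)

    def test_fitted_glucose_series_monotone_in_glucose(self, mean_ca_surrogate):
        truth = CalibrationScales()
        obs = simulate_observations(
            insulin_fit_conditions(), NoiseModel(cv=0.0, seed=0),
            kind="insulin", scales=truth, mean_ca=mean_ca_surrogate)
        fit = fit_calcium_scaling(obs, mean_ca_surrogate, scales0=truth)
        s = CalibrationScales(
            insulin_per_ca=fit.params["insulin_per_ca"],
            glc_to_katp=fit.params["glc_to_katp"],
            ala_to_gnaala=fit.params["ala_to_gnaala"])
        preds = []
        for g in (1.1, 5.0, 10.0, 16.7, 30.0):
            k_atp, gna = condition_to_inputs(Condition(glucose=g), s)
            preds.append(s.insulin_per_ca * mean_ca_surrogate(k_atp, gna))
        assert all(a < b for a, b in zip(preds, preds[1:]))
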