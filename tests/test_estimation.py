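"""Mixed-effects likelihood, fitting, EBEs, shrinkage, SEs and the LRT."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad

from fupk import (AnalysisDataset, CohortSpec, ConcentrationObservation,
                  CovariateEffect, DoseEvent, PopulationModel,
                  ResidualErrorModel, cv_to_omega, empirical_bayes,
                  final_model, fit, generate_cohort, lrt, ofv,
                  predict_concentration, shrinkage, simulate_concentrations,
                  standard_errors, typical_clearance)
from fupk.estimation import PopPKEstimator, _Workspace, _ofv_components

from conftest import make_subject

LOG2PI = math.log(2 * math.pi)


def quad_ofv(model, dataset):
    """Independent oracle: per-subject scipy.integrate.quad of the raw
    marginal-likelihood integrand, OFV on the n·log(2π)-omitted scale."""
    dose_by = {(d.subject_id, d.cycle): d for d in dataset.doses}
    obs_by = {}
    for o in dataset.observations:
        obs_by.setdefault(o.subject_id, []).append(o)
    total = 0.0
    for s in dataset.subjects:
        obs = obs_by.get(s.subject_id, [])
        clt = typical_clearance(model, s)
        om = model.omega_cl

        def integrand(eta):
            ll = 0.0
            for o in obs:
                d = dose_by[(o.subject_id, o.cycle)]
                f = predict_concentration(clt * math.exp(eta), model.v,
                                          d.rate, o.time,
                                          o.steady_state_flag)
                v = model.residual.sigma_add**2 \
                    + (model.residual.sigma_prop * f) ** 2
                ll += -0.5 * math.log(2 * math.pi * v) \
                    - (o.dv - f) ** 2 / (2 * v)
            prior = -0.5 * math.log(2 * math.pi * om**2) \
                - eta**2 / (2 * om**2)
            return math.exp(ll + prior)

        val, _ = quad(integrand, -8 * om, 8 * om, limit=200,
                      epsabs=1e-14, epsrel=1e-12)
        total += -2.0 * math.log(val) - len(obs) * LOG2PI
    return total


def one_subject_dataset(dv=900.0, dose=4800.0):
    s = make_subject("A")
    return AnalysisDataset(
        subjects=[s], doses=[DoseEvent("A", 1, dose, 24.0)],
        observations=[ConcentrationObservation("A", 1, 18.0, dv)])


class TestOfv:
    def test_closed_form_when_no_iiv(self):
        """ω = 0 collapses the OFV to the weighted least-squares −2LL,
        hand-computable for one subject with one observation."""
        m = PopulationModel(cl_pop=200.0, omega_cl=0.0,
                            residual=ResidualErrorModel(sigma_prop=0.2))
        ds = one_subject_dataset(dv=900.0, dose=4800.0)
        pred = 1000.0  # 200 mg/h / 200 L/h
        v = (0.2 * pred) ** 2
        expected = math.log(v) + (900.0 - pred) ** 2 / v
        assert ofv(m, ds) == pytest.approx(expected, abs=1e-10)

    def test_additive_over_subjects(self, small_simulated):
        sim, model = small_simulated
        base = ofv(model, sim)
        doubled = AnalysisDataset(
            subjects=sim.subjects + [replace(s, subject_id=s.subject_id + "x")
                                     for s in sim.subjects],
            doses=sim.doses + [replace(d, subject_id=d.subject_id + "x")
                               for d in sim.doses],
            observations=sim.observations
            + [replace(o, subject_id=o.subject_id + "x")
               for o in sim.observations])
        assert ofv(model, doubled) == pytest.approx(2 * base, abs=1e-6)

    def test_matches_quadrature_oracle(self, small_simulated):
        sim, model = small_simulated
        assert ofv(model, sim) == pytest.approx(quad_ofv(model, sim),
                                                abs=1e-3)

    def test_laplace_close_but_distinct(self, small_simulated):
        sim, model = small_simulated
        lap = ofv(model, sim, method="laplace")
        agq = ofv(model, sim)
        assert lap == pytest.approx(agq, abs=0.5)
        assert lap != agq

    def test_invariant_to_v_and_omega_v_at_steady_state(
            self, small_simulated):
        sim, model = small_simulated
        perturbed = replace(model, v=model.v * 3.0,
                            omega_v=model.omega_v * 2.0)
        assert ofv(perturbed, sim) == pytest.approx(ofv(model, sim),
                                                    abs=1e-9)

    def test_zero_residual_variance_raises_with_subject(self):
        m = PopulationModel(cl_pop=200.0, omega_cl=0.2,
                            residual=ResidualErrorModel(sigma_prop=0.2))
        s = make_subject("Z")
        ds = AnalysisDataset(
            subjects=[s], doses=[DoseEvent("Z", 1, 4800.0, 24.0)],
            observations=[ConcentrationObservation("Z", 1, 0.0, 100.0,
                                                   steady_state_flag=False)])
        with pytest.raises(FloatingPointError, match="Z"):
            ofv(m, ds)


class TestFit:
    def test_noiseless_recovery_is_exact(self):
        """With σ→0 and ω=0 the optimizer must hit CL_pop to tolerance."""
        truth = PopulationModel(cl_pop=223.0, omega_cl=0.0,
                                residual=ResidualErrorModel(sigma_prop=1e-10))
        ds = generate_cohort(CohortSpec(n_subjects=8), seed=1)
        sim = simulate_concentrations(ds, truth, seed=2)
        init = replace(truth, cl_pop=180.0,
                       fixed=frozenset({"v", "omega_v", "omega_cl",
                                        "sigma_prop"}))
        res = fit(init, sim, compute_rse=False)
        assert res.estimates["cl_pop"] == pytest.approx(223.0, rel=1e-4)

    def test_fit_beats_truth_ofv(self, small_simulated):
        sim, model = small_simulated
        res = fit(model, sim, compute_rse=False)
        assert res.ofv <= ofv(model, sim) + 1e-6
        assert res.converged

    def test_estimator_is_sklearn_compatible(self, small_simulated):
        sim, model = small_simulated
        est = PopPKEstimator(model, compute_rse=False)
        params = est.get_params()
        assert params["n_nodes"] == 11
        est.set_params(maxiter=300)
        est.fit(sim)
        assert est.ofv_ == pytest.approx(est.result_.ofv)
        assert est.model_.cl_pop > 0
        assert est.score(sim) == pytest.approx(-est.ofv_, abs=1e-6)

    def test_too_few_observations_rejected(self):
        m = final_model()
        with pytest.raises(ValueError, match="observations"):
            fit(m, one_subject_dataset())


class TestEmpiricalBayes:
    def test_no_observations_gives_zero(self, small_simulated):
        sim, model = small_simulated
        extra = make_subject("LONER")
        ds = AnalysisDataset(subjects=sim.subjects + [extra],
                             doses=sim.doses, observations=sim.observations)
        res = fit(model, ds, compute_rse=False)
        assert res.ebes.loc["LONER"] == 0.0

    def test_omega_to_zero_shrinks_all_ebes(self, small_simulated):
        sim, model = small_simulated
        tiny = replace(model, omega_cl=1e-6)
        res_fit = fit(replace(model, fixed=frozenset(
            {"v", "omega_v", "omega_cl", "sigma_prop", "theta_bsa",
             "theta_smi_back", "cl_pop"})), sim, compute_rse=False)
        ebes = empirical_bayes(replace(res_fit, model=tiny), sim)
        assert np.all(np.abs(ebes.to_numpy()) < 1e-4)

    def test_matches_grid_search_mode(self, small_simulated):
        """EBE = argmin of the per-subject joint density, cross-checked by
        brute-force grid refinement."""
        sim, model = small_simulated
        res = fit(model, sim, compute_rse=False)
        m = res.model
        ws = _Workspace(sim, m.covariate_effects)
        for i, sid in enumerate(ws.subject_ids):
            grid = np.linspace(-1.0, 1.0, 20001)
            mask = ws.sidx == i
            clt = ws.typical_cl(m)[i]
            f = ws.rate[mask][None, :] / (clt * np.exp(grid))[:, None] * 1000
            v = (m.residual.sigma_prop * f) ** 2
            obj = (np.log(v) + (ws.y[mask][None, :] - f) ** 2 / v).sum(axis=1) \
                + grid**2 / m.omega_cl**2
            best = grid[np.argmin(obj)]
            assert res.ebes.loc[sid] == pytest.approx(best, abs=1e-4)


class TestShrinkage:
    def test_hand_computed_eta_shrinkage(self, small_simulated):
        sim, model = small_simulated
        res = fit(model, sim, compute_rse=False)
        eta_s, eps_s = shrinkage(res, sim)
        expected = 100.0 * (1 - np.std(res.ebes.to_numpy(), ddof=1)
                            / res.model.omega_cl)
        assert eta_s == pytest.approx(expected, abs=1e-9)
        assert 0.0 <= eta_s <= 100.0

    def test_eta_v_shrinkage_is_100_with_steady_state_data(
            self, small_simulated):
        sim, model = small_simulated
        res = fit(model, sim, compute_rse=False)
        assert res.eta_v_shrinkage_percent == 100.0

    def test_rich_data_limit_low_shrinkage(self):
        """Many informative observations per subject pin down η: shrinkage
        should be near zero."""
        truth = PopulationModel(cl_pop=223.0, omega_cl=cv_to_omega(25.0),
                                residual=ResidualErrorModel(sigma_prop=0.05))
        spec = CohortSpec(n_subjects=40, cycle_probs=(0, 0, 0, 0, 1),
                          obs_per_cycle=2.0)
        sim = simulate_concentrations(generate_cohort(spec, seed=3), truth,
                                      seed=4)
        res = fit(truth, sim, compute_rse=False)
        assert res.eta_shrinkage_percent < 15.0


class TestStandardErrors:
    def test_matches_profile_curvature(self):
        """One estimated parameter: the RSE from the covariance step must
        match the curvature of the OFV/2 profile fitted by polynomial
        regression (an independent arithmetic oracle)."""
        truth = PopulationModel(cl_pop=223.0, omega_cl=cv_to_omega(20.0),
                                residual=ResidualErrorModel(sigma_prop=0.2))
        sim = simulate_concentrations(
            generate_cohort(CohortSpec(n_subjects=30), seed=5), truth, seed=6)
        frozen = replace(truth, fixed=frozenset(
            {"v", "omega_v", "omega_cl", "sigma_prop"}))
        res = fit(frozen, sim)
        cl_hat = res.estimates["cl_pop"]
        xs = np.linspace(cl_hat * 0.98, cl_hat * 1.02, 21)
        ys = [0.5 * ofv(replace(res.model, cl_pop=x), sim) for x in xs]
        curv = 2.0 * np.polyfit(xs - cl_hat, ys, 2)[0]
        se_oracle = 1.0 / math.sqrt(curv)
        assert res.rse_percent["cl_pop"] == pytest.approx(
            100 * se_oracle / cl_hat, rel=0.02)
        assert res.covariance_ok

    def test_fixed_parameters_get_no_rse(self, small_simulated):
        sim, model = small_simulated
        res = fit(model, sim)
        assert "v" not in res.rse_percent
        assert "omega_v" not in res.rse_percent
        assert set(res.rse_percent) == set(res.param_names)


class TestLrt:
    def test_published_threshold(self):
        assert lrt(3.84, 0.0, 1) == pytest.approx(0.0500, abs=5e-5)

    def test_no_improvement_p_one(self):
        assert lrt(100.0, 100.0, 1) == 1.0

    def test_chi_square_table_value(self):
        assert lrt(6.63, 0.0, 1) == pytest.approx(0.0100, abs=2e-4)

    def test_negative_df_and_negative_dofv(self):
        with pytest.raises(ValueError):
            lrt(1.0, 0.0, 0)
        with pytest.warns(UserWarning):
            p = lrt(0.0, 5.0, 1)
        assert p == 1.0


class TestResidualIivLegacyModel:
    def test_ofv_with_residual_iiv_matches_oracle(self):
        """The legacy residual-variability random effect (subject-level
        log-normal multiplier on the residual SD) against a 2-D brute-force
        integration oracle on one subject."""
        m = PopulationModel(
            cl_pop=200.0, omega_cl=0.2,
            residual=ResidualErrorModel(sigma_prop=0.2, sigma_add=50.0,
                                        iiv_on_residual=0.3))
        ds = one_subject_dataset(dv=900.0, dose=4800.0)

        def integrand(eta, etar):
            f = 1000.0 * math.exp(-eta)
            v = (50.0**2 + (0.2 * f) ** 2) * math.exp(2 * etar)
            ll = -0.5 * math.log(2 * math.pi * v) - (900 - f) ** 2 / (2 * v)
            pr = (-0.5 * math.log(2 * math.pi * 0.2**2)
                  - eta**2 / (2 * 0.2**2)
                  - 0.5 * math.log(2 * math.pi * 0.3**2)
                  - etar**2 / (2 * 0.3**2))
            return math.exp(ll + pr)

        from scipy.integrate import dblquad
        val, _ = dblquad(integrand, -2.0, 2.0, -2.0, 2.0,
                         epsabs=1e-12, epsrel=1e-10)
        expected = -2 * math.log(val) - LOG2PI
        assert ofv(m, ds) == pytest.approx(expected, abs=5e-3)
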