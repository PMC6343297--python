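"""Mixed-effects engine: likelihood approximations, fitting, post-hoc etas."""

import math

import numpy as np
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy import stats

from propofol_pkpd import (
    DoseEvent,
    Observation,
    StudyDataset,
    Subject,
    attach_individual_pk,
    individual_loglik,
    solve_pk,
)
from propofol_pkpd.nlme import (
    EstimationError,
    PopulationModel,
    bis_pd_spec,
    caai_pd_spec,
    fit_sequential_pd,
    pk_model_spec,
)
from propofol_pkpd.trial import TrialDesignConfig, default_truth, generate_trial

from conftest import FINAL_PK, make_toy_pk_dataset

REF_INIT = {"CL": 1.37, "Q": 1.15, "V1": 3.6, "V2": 76.8}


def _empty_subject(sid="E0"):
    return Subject(id=sid, weight=50.0, age=14.0, sex="F", remi_rate=0.5,
                   doses=[DoseEvent(0.0, 200.0, 1.0 / 6.0)], observations=[])


class TestIndividualLoglik:
    def test_no_observations_reduces_to_prior(self):
        spec = pk_model_spec(init=REF_INIT, omega2_cl=0.05, sigma2=0.04)
        s = _empty_subject()
        for eta in (0.0, 0.1, -0.3):
            ll = individual_loglik(spec, s, [eta])
            assert ll == pytest.approx(stats.norm.logpdf(eta, 0.0, math.sqrt(0.05)), abs=1e-10)
        # prior-only contribution is maximized at eta = 0
        grid = np.linspace(-0.5, 0.5, 41)
        vals = [individual_loglik(spec, s, [e]) for e in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(0.0, abs=1e-9)

    def test_matches_manual_gaussian_density(self):
        ds = make_toy_pk_dataset(n_subjects=1, seed=3)
        spec = pk_model_spec(init=REF_INIT, omega2_cl=0.05, sigma2=0.04)
        s = ds.subjects[0]
        eta = 0.12
        pk_i = FINAL_PK.replace(CL=FINAL_PK.CL * math.exp(eta))
        times = [o.time for o in s.obs_of_type("conc")]
        pred = solve_pk(pk_i, s.doses, times).cb
        obs = np.array([o.value for o in s.obs_of_type("conc")])
        expected = stats.norm.logpdf(np.log(obs), np.log(pred), 0.2).sum()
        expected += stats.norm.logpdf(eta, 0.0, math.sqrt(0.05))
        assert individual_loglik(spec, s, [eta]) == pytest.approx(expected, rel=1e-10)


class TestOfv:
    def test_no_random_effects_is_exact_gaussian_m2ll(self, toy_pk_dataset):
        spec = pk_model_spec(init=REF_INIT, omega2_cl=None, sigma2=0.04)
        model = PopulationModel(toy_pk_dataset, spec)
        # manual fixed-effects -2LL on the log scale
        total = 0.0
        for s in toy_pk_dataset:
            obs = s.obs_of_type("conc")
            pred = solve_pk(FINAL_PK, s.doses, [o.time for o in obs]).cb
            r = np.log([o.value for o in obs]) - np.log(pred)
            total += float(r @ r / 0.04 + len(obs) * math.log(2 * math.pi * 0.04))
        assert model.ofv() == pytest.approx(total, rel=1e-10)

    @pytest.mark.parametrize("omega2,sigma2", [(0.05, 0.0225), (0.3, 0.04)])
    def test_foce_and_laplace_match_gauss_hermite_oracle(self, toy_pk_dataset, omega2, sigma2):
        spec = pk_model_spec(init=REF_INIT, omega2_cl=omega2, sigma2=sigma2)
        eng = PopulationModel(toy_pk_dataset, spec).engine
        theta, om, s2 = eng.table.unpack(eng.table.x0(None))

        def quad_m2ll(ctx, n_nodes=81):
            eta_hat, J = eng.conditional_mode(ctx, theta, om, s2)
            om_inv, _ = eng._prior_terms(om)
            H = float((J.T @ J / s2 + om_inv)[0, 0])
            l_hat = -0.5 * eng.joint_minus2ll(ctx, theta, om, s2, eta_hat)
            z, w = hermgauss(n_nodes)
            scale = math.sqrt(2.0 / H)
            tot = 0.0
            for zk, wk in zip(z, w):
                l = -0.5 * eng.joint_minus2ll(ctx, theta, om, s2,
                                              np.array([eta_hat[0] + scale * zk]))
                tot += wk * math.exp(l - l_hat + zk * zk)
            return -2.0 * (l_hat + math.log(scale * tot))

        oracle = sum(quad_m2ll(c) for c in eng.contexts)
        foce, _ = eng.ofv_parts(theta, om, s2, method="foce")
        laplace, _ = eng.ofv_parts(theta, om, s2, method="laplace")
        assert foce == pytest.approx(oracle, abs=0.1)
        assert laplace == pytest.approx(oracle, abs=0.1)
        assert abs(foce - laplace) < 1.0

    def test_subject_order_invariance(self, toy_pk_dataset):
        spec = pk_model_spec(init=REF_INIT, omega2_cl=0.05, sigma2=0.04)
        f1 = PopulationModel(toy_pk_dataset, spec).ofv()
        reversed_ds = StudyDataset(list(reversed(toy_pk_dataset.subjects)))
        f2 = PopulationModel(reversed_ds, spec).ofv()
        assert f1 == pytest.approx(f2, abs=1e-8)


class TestFitPopulation:
    def test_noise_free_recovery(self):
        truth = FINAL_PK
        times = [1.0, 5.0, 15.0, 30.0, 60.0, 120.0, 180.0, 300.0]
        subjects = []
        for i in range(2):
            doses = [DoseEvent(0.0, 200.0, 1.0 / 6.0), DoseEvent(1.0 / 6.0, 400.0, 150.0)]
            cb = solve_pk(truth, doses, times).cb
            obs = [Observation(time=t, value=float(c), obs_type="conc")
                   for t, c in zip(times, cb)]
            subjects.append(Subject(id=f"N{i}", weight=50.0, age=14.0, sex="F",
                                    remi_rate=0.5, doses=doses, observations=obs))
        spec = pk_model_spec(omega2_cl=None, sigma2=1e-4, sigma2_fixed=True)
        fit = PopulationModel(StudyDataset(subjects), spec).fit(compute_se=False)
        for name in ("CL", "Q", "V1", "V2"):
            assert fit.params[name] == pytest.approx(getattr(truth, name), rel=1e-3)

    def test_nested_model_never_fits_worse(self):
        # extending the optimum with an unused covariate coefficient (init 0)
        ds = make_toy_pk_dataset(n_subjects=5, seed=2)
        base = PopulationModel(ds, pk_model_spec()).fit(compute_se=False)
        from propofol_pkpd.nlme import CovariateEffect
        import dataclasses

        spec_ext = dataclasses.replace(
            base.spec, covariate_effect=CovariateEffect("CL", "weight", "power")
        )
        ext = PopulationModel(ds, spec_ext).fit(init=base._init_overrides(),
                                                compute_se=False)
        assert ext.ofv <= base.ofv + 1e-6 * abs(base.ofv)

    def test_population_fit_recovers_clearance(self, study_pk_fit):
        # 14-subject trial simulated from the final estimates: CL near 1.37 L/min
        assert study_pk_fit.converged
        assert abs(study_pk_fit.params["CL"] / 1.37 - 1.0) < 0.15

    def test_standard_errors_and_ci(self):
        ds = make_toy_pk_dataset(n_subjects=6, seed=4)
        fit = PopulationModel(ds, pk_model_spec()).fit(compute_se=True)
        assert set(fit.se) >= {"CL", "Q", "V1", "V2"}
        lo, hi = fit.ci95["CL"]
        assert lo < fit.params["CL"] < hi
        # CI symmetric on the log estimation scale
        assert math.log(fit.params["CL"]) - math.log(lo) == pytest.approx(
            math.log(hi) - math.log(fit.params["CL"]), rel=1e-6
        )
        text = fit.summary()
        assert "CL" in text and "OFV" in text


class TestPosthoc:
    def test_subject_without_observations_gets_zero_eta(self, toy_pk_dataset):
        ds = StudyDataset(toy_pk_dataset.subjects + [_empty_subject("XX")])
        spec = pk_model_spec(init=REF_INIT, omega2_cl=0.05, sigma2=0.04)
        etas = PopulationModel(ds, spec).posthoc()
        assert etas.loc["XX", "CL"] == pytest.approx(0.0, abs=1e-12)

    def test_rich_low_noise_subject_recovers_true_eta(self):
        rng = np.random.default_rng(8)
        true_eta = 0.18
        pk_i = FINAL_PK.replace(CL=FINAL_PK.CL * math.exp(true_eta))
        times = np.linspace(2.0, 400.0, 60)
        doses = [DoseEvent(0.0, 200.0, 1.0 / 6.0), DoseEvent(1.0 / 6.0, 1200.0, 350.0)]
        cb = solve_pk(pk_i, doses, times).cb
        obs = [Observation(time=float(t), value=float(math.exp(math.log(c) + rng.normal(0, 0.02))),
                           obs_type="conc") for t, c in zip(times, cb)]
        s = Subject(id="R", weight=50.0, age=14.0, sex="F", remi_rate=0.5,
                    doses=doses, observations=obs)
        spec = pk_model_spec(init=REF_INIT, omega2_cl=0.1, sigma2=0.0004)
        etas = PopulationModel(StudyDataset([s]), spec).posthoc()
        assert etas.loc["R", "CL"] == pytest.approx(true_eta, rel=0.02)

    def test_population_mean_eta_near_zero(self, study_pk_fit):
        etas = study_pk_fit.etas["CL"].to_numpy()
        se = etas.std(ddof=1) / math.sqrt(etas.size)
        assert abs(etas.mean()) < 3.0 * se + 1e-9


class TestSequentialPD:
    def test_missing_posthoc_pk_raises(self, study_trial):
        spec = bis_pd_spec()
        with pytest.raises(EstimationError, match="individual PK"):
            PopulationModel(study_trial, spec).ofv()

    def test_attach_individual_pk(self, study_trial, study_pk_fit):
        ds = attach_individual_pk(study_trial, study_pk_fit)
        for s in ds:
            assert s.pk_params is not None
            assert s.pk_params.Q == pytest.approx(study_pk_fit.params["Q"])

    def test_two_compartment_biophase_preferred_on_its_own_data(self):
        # BIS data simulated from the two-compartment biophase truth
        cfg = TrialDesignConfig(n_subjects=7, pd_interval=7.0, pd_types=("BIS",))
        ds = generate_trial(cfg, seed=7)
        pk_fit = PopulationModel(ds, pk_model_spec()).fit(compute_se=False)
        fit2 = fit_sequential_pd(pk_fit, bis_pd_spec(order=2), ds, compute_se=False)
        fit1 = fit_sequential_pd(pk_fit, bis_pd_spec(order=1), ds, compute_se=False)
        assert fit1.ofv - fit2.ofv > 3.8

    def test_steep_hill_coefficient_detected(self):
        # cAAI-like on-off data: estimating gamma beats gamma fixed at 1
        import dataclasses

        truth = default_truth()
        truth = dataclasses.replace(
            truth, omega2_pd={"cAAI": {"EC50": 0.159, "gamma": 0.0, "ke0": 0.0}}
        )
        cfg = TrialDesignConfig(n_subjects=5, pd_interval=10.0, pd_types=("cAAI",))
        ds = generate_trial(cfg, truth=truth, seed=11)
        pk_fit = PopulationModel(ds, pk_model_spec()).fit(compute_se=False)

        def lean_spec(gamma_fixed):
            s = caai_pd_spec(order=1)
            s.random_effects.omega2 = {"EC50": 0.1}
            if gamma_fixed:
                fe = s.effect("gamma")
                fe.init, fe.fixed = 1.0, True
            return s

        fit_est = fit_sequential_pd(pk_fit, lean_spec(False), ds,
                                    compute_se=False, maxiter=100)
        fit_fix = fit_sequential_pd(pk_fit, lean_spec(True), ds,
                                    compute_se=False, maxiter=100)
        assert fit_fix.ofv - fit_est.ofv > 7.8
        assert fit_est.params["gamma"] > 3.0
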