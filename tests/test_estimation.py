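"""First-order estimation: objective, fitting, selection rules, EBEs."""

import math

import numpy as np
import pytest

from bpmpk.cohort import (
    Observation,
    SamplingScheme,
    SubjectRecord,
    filter_estimable,
    generate_dataset,
)
from bpmpk.estimation import (
    BACKWARD_THRESHOLD,
    FORWARD_THRESHOLD,
    CompiledDataset,
    ValidationError,
    accept_forward,
    backward_eliminate,
    compare_structures,
    ebe_estimate,
    fit_fo,
    fo_block_ofv,
    fo_objective,
    forward_select,
    keep_covariate,
    stepwise_select,
)
from bpmpk.pkmodel import CovariateRecord, DoseEvent
from bpmpk.population import CovariateEffect, PopulationModel


def _quiet_model(final):
    m = final.copy()
    m.omega = {}
    m.sigma_add = 0.0
    return m


def _noise_free_subjects(final, n=40, seed=7):
    return filter_estimable(generate_dataset(n, _quiet_model(final), seed=seed))


class TestFoObjective:
    def test_exact_marginal_for_eta_linear_toy(self):
        # one subject, y = theta + eta + eps with theta=1, omega^2=1, sigma^2=1:
        # marginally y ~ N(1, 2), so the OFV (2*pi omitted) is ln 2 + (y-1)^2/2
        ofv = fo_block_ofv(r=[1.0], F=[[1.0]], omega_diag=[1.0], resid_var=[1.0])
        expected = math.log(2.0) + 1.0 / 2.0
        assert ofv == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_normal_logpdf(self):
        from scipy import stats

        y, theta, om, sg = 2.7, 1.3, 0.8, 0.5
        ofv = fo_block_ofv([y - theta], [[1.0]], [om], [sg])
        exact = -2.0 * stats.norm.logpdf(y, theta, math.sqrt(om + sg)) - math.log(
            2.0 * math.pi
        )
        assert ofv == pytest.approx(exact, abs=1e-10)

    def test_zero_omega_additive_closed_form(self, final):
        subjects = _noise_free_subjects(final)
        model = _quiet_model(final)
        model.sigma_add = 0.25
        n = sum(len(s.usable_observations()) for s in subjects)
        # y = f exactly, so only the log-determinant terms remain
        assert fo_objective(subjects, model) == pytest.approx(n * math.log(0.25), rel=1e-10)

    def test_invariant_to_subject_order(self, final, rng):
        subjects = filter_estimable(generate_dataset(25, final, seed=3))
        shuffled = list(subjects)
        rng.shuffle(shuffled)
        assert fo_objective(subjects, final) == pytest.approx(
            fo_objective(shuffled, final), rel=1e-12
        )

    def test_blq_only_subject_rejected(self, final):
        s = SubjectRecord(
            id=1,
            covariates=CovariateRecord(clcr=80.0, bun=7.0),
            doses=(DoseEvent(0.0, 300.0, 1.0),),
            observations=(Observation(6.0, 0.1, True),),
        )
        with pytest.raises(ValidationError, match="non-BLQ"):
            CompiledDataset([s])


class TestFitFo:
    def test_noise_free_recovery(self, final):
        subjects = _noise_free_subjects(final, n=60)
        init = _quiet_model(final)
        init.theta = {"cl": 6.0, "v1": 20.0, "q": 2.5, "v2": 40.0}
        init.sigma_add = 1e-8
        fit = fit_fo(
            subjects, init, fixed={"sigma_add", "cl:clcr", "q:bun"},
            n_starts=1, compute_se=False, maxiter=500,
        )
        assert fit.converged
        for name, true in (("cl", 8.33), ("v1", 13.4), ("q", 3.75), ("v2", 60.4)):
            assert fit.model.theta[name] == pytest.approx(true, rel=1e-3)

    def test_refit_from_solution_is_fixed_point(self, final):
        scheme = SamplingScheme(
            mean_samples=2.0, extra_samples_max=1, windows=((0.17, 0.3), (0.75, 1.0))
        )
        subjects = filter_estimable(generate_dataset(60, final, scheme=scheme, seed=5))
        fit1 = fit_fo(subjects, final, n_starts=1, compute_se=False, maxiter=600)
        assert fit1.converged
        fit2 = fit_fo(subjects, fit1.model, n_starts=1, compute_se=False, maxiter=600)
        assert fit2.ofv == pytest.approx(fit1.ofv, rel=1e-6)

    def test_standard_errors_scale(self, final):
        scheme = SamplingScheme(
            mean_samples=2.0, extra_samples_max=1, windows=((0.17, 0.3), (0.75, 1.0))
        )
        subjects = filter_estimable(generate_dataset(80, final, scheme=scheme, seed=6))
        fit = fit_fo(subjects, final, n_starts=1, maxiter=600)
        assert fit.converged
        assert fit.se and all(v >= 0 or math.isnan(v) for v in fit.se.values())
        for name, se in fit.se.items():
            if not math.isnan(se) and se > 0:
                est = fit.estimates()[name]
                assert fit.rse_percent[name] == pytest.approx(100 * se / abs(est))


class TestCompareStructures:
    def test_two_compartment_data_prefers_two_compartments(self, final):
        scheme = SamplingScheme(
            mean_samples=2.0, extra_samples_max=1, windows=((0.17, 0.3), (0.8, 1.0))
        )
        subjects = filter_estimable(
            generate_dataset(120, final, scheme=scheme, seed=21)
        )
        init = final.copy()
        init.effects = []
        ranked = compare_structures(subjects, init, n_starts=1, compute_se=False)
        assert ranked[0][0] == "two_compartment"
        assert ranked[0][2] == 0.0
        assert ranked[1][2] > 0.0

    def test_identical_fits_tie(self, final):
        subjects = filter_estimable(generate_dataset(30, final, seed=2))
        f1 = fit_fo(subjects, final, n_starts=1, compute_se=False, maxiter=100)
        f2 = fit_fo(subjects, final, n_starts=1, compute_se=False, maxiter=100)
        assert f1.ofv == f2.ofv


class TestSelectionRules:
    def test_forward_boundary_is_strict(self):
        assert not accept_forward(FORWARD_THRESHOLD)
        assert accept_forward(FORWARD_THRESHOLD + 1e-9)

    def test_backward_boundary_removes_at_threshold(self):
        # a covariate is retained only when its removal cost strictly
        # exceeds the threshold, so a cost of exactly 6.63 means removal
        assert not keep_covariate(BACKWARD_THRESHOLD)
        assert keep_covariate(BACKWARD_THRESHOLD + 1e-9)

    def test_forward_no_candidates_returns_base(self, final):
        subjects = filter_estimable(generate_dataset(25, final, seed=4))
        base = final.copy()
        base.effects = []
        fit, trace = forward_select(subjects, base, [], maxiter=100)
        assert fit.model.effects == []
        assert trace.empty

    def test_backward_no_covariates_is_identity(self, final):
        subjects = filter_estimable(generate_dataset(25, final, seed=4))
        base = final.copy()
        base.effects = []
        fit, trace = backward_eliminate(subjects, base, maxiter=100)
        assert fit.model.effects == []
        assert trace.empty

    def test_stepwise_recovers_true_structure(self, final):
        scheme = SamplingScheme(
            mean_samples=2.0, extra_samples_max=1, windows=((0.17, 0.3), (0.75, 1.0))
        )
        subjects = filter_estimable(
            generate_dataset(150, final, scheme=scheme, seed=31)
        )
        base = final.copy()
        base.effects = []
        base.theta = {"cl": 7.0, "v1": 15.0, "q": 4.0, "v2": 50.0}
        base.omega = {"cl": 0.1, "q": 0.5}
        base.sigma_add = 0.3
        candidates = [
            ("cl", "clcr", "linear"),
            ("cl", "alb", "linear"),
            ("q", "bun", "linear"),
        ]
        fit, trace = stepwise_select(subjects, base, candidates, seed=31, maxiter=200)
        kept = sorted(e.key() for e in fit.model.effects)
        assert kept == [("cl", "clcr"), ("q", "bun")]
        assert (trace.action == "forward_include").sum() >= 2
        assert set(trace.columns) == {
            "step", "action", "parameter", "covariate",
            "ofv_before", "ofv_after", "delta",
        }


class TestEbe:
    def test_no_observations_rejected(self, final):
        s = SubjectRecord(
            id=9,
            covariates=CovariateRecord(clcr=80.0, bun=7.0),
            doses=(DoseEvent(0.0, 300.0, 1.0),),
            observations=(),
        )
        with pytest.raises(ValidationError):
            ebe_estimate(s, final)

    def test_prior_dominates_as_omega_vanishes(self, final):
        subjects = filter_estimable(generate_dataset(5, final, seed=14))
        tight = final.copy()
        tight.omega = {"cl": 1e-10, "q": 1e-10}
        eta, _ = ebe_estimate(subjects[0], tight)
        assert all(abs(v) < 1e-4 for v in eta.values())

    def test_small_noise_drives_prediction_through_observation(self, final):
        subjects = filter_estimable(generate_dataset(8, final, seed=15))
        subject = next(s for s in subjects if len(s.usable_observations()) == 1)
        loose = final.copy()
        loose.sigma_add = 1e-6
        loose.omega = {"cl": 10.0, "q": 10.0}
        _, ipred = ebe_estimate(subject, loose)
        obs = subject.usable_observations()[0].conc
        assert ipred[0] == pytest.approx(obs, rel=1e-2)
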