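"""Two-compartment closed-form kinetics against independent oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from bpmpk.pkmodel import (
    CovariateRecord,
    DomainError,
    DoseEvent,
    Regimen,
    StructuralParams,
    ThetaVector,
    auc,
    conc_profile,
    ft_above_mic,
    ft_above_mic_many,
    individual_params,
    interval_profile,
    macro_constants,
    typical_params,
)
from conftest import random_params

TABLE_THETA = ThetaVector(
    th1_cl=8.33, th2_v1=13.4, th3_q=3.75, th4_v2=60.4,
    th5_clcr_slope=0.0046, th6_bun_slope=0.112,
)


def ode_profile(p, doses, times, rtol=1e-10):
    """Independent oracle: numeric integration of the compartment ODEs."""
    k10, k12, k21, _, _ = macro_constants(p)

    def rhs(t, y):
        rate = sum(
            d.amount / d.duration
            for d in doses
            if d.start_time < t <= d.start_time + d.duration
        )
        return [rate - (k10 + k12) * y[0] + k21 * y[1], k12 * y[0] - k21 * y[1]]

    switch = sorted({d.start_time for d in doses} | {d.start_time + d.duration for d in doses})
    sol = solve_ivp(
        rhs, [0, max(times)], [0.0, 0.0], t_eval=sorted(times),
        rtol=rtol, atol=1e-12, max_step=0.25,
    )
    order = np.argsort(np.argsort(times))
    return (sol.y[0] / p.v1)[order]


class TestMacroConstants:
    def test_algebraic_identities(self, typical_patient):
        k10, k12, k21, alpha, beta = macro_constants(typical_patient)
        p = typical_patient
        assert k10 == pytest.approx(p.cl / p.v1)
        assert k12 == pytest.approx(p.q / p.v1)
        assert k21 == pytest.approx(p.q / p.v2)
        assert alpha + beta == pytest.approx(k10 + k12 + k21, rel=1e-12)
        assert alpha * beta == pytest.approx(k10 * k21, rel=1e-12)
        assert alpha > beta > 0

    def test_matches_eigenvalue_oracle(self, typical_patient):
        k10, k12, k21, alpha, beta = macro_constants(typical_patient)
        rate_matrix = np.array([[-(k10 + k12), k21], [k12, -k21]])
        eig = np.sort(-np.linalg.eigvals(rate_matrix))
        assert beta == pytest.approx(eig[0], rel=1e-12)
        assert alpha == pytest.approx(eig[1], rel=1e-12)

    def test_one_compartment_limit(self):
        p = StructuralParams(cl=8.33, v1=13.4, q=1e-9, v2=60.4)
        *_, alpha, beta = macro_constants(p)
        assert alpha == pytest.approx(8.33 / 13.4, rel=1e-6)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(DomainError):
            StructuralParams(cl=-1.0, v1=13.4, q=3.75, v2=60.4)


class TestConcProfile:
    def test_no_doses_no_drug(self, typical_patient):
        c = conc_profile(typical_patient, [], [0.0, 1.0, 5.0])
        assert (c == 0).all()

    def test_zero_before_first_dose(self, typical_patient):
        doses = [DoseEvent(2.0, 300.0, 1.0)]
        c = conc_profile(typical_patient, doses, [0.0, 1.0, 1.999, 2.5])
        assert (c[:3] == 0).all() and c[3] > 0

    def test_linearity_in_dose(self, typical_patient):
        doses = [DoseEvent(0.0, 300.0, 1.0), DoseEvent(8.0, 300.0, 1.0)]
        doubled = [DoseEvent(d.start_time, 2 * d.amount, d.duration) for d in doses]
        t = np.linspace(0.2, 20, 40)
        np.testing.assert_allclose(
            conc_profile(typical_patient, doubled, t),
            2 * conc_profile(typical_patient, doses, t),
            rtol=1e-12,
        )

    def test_negative_time_rejected(self, typical_patient):
        with pytest.raises(DomainError):
            conc_profile(typical_patient, [DoseEvent(0, 300, 1)], [-1.0])

    def test_matches_ode_oracle_typical(self, typical_patient):
        doses = [DoseEvent(0.0, 300.0, 1.0)]
        t = [1.0, 2.0, 6.0]
        closed = conc_profile(typical_patient, doses, t)
        numeric = ode_profile(typical_patient, doses, t)
        np.testing.assert_allclose(closed, numeric, rtol=1e-8)

    def test_matches_ode_oracle_random_params(self, rng):
        doses = [DoseEvent(0.0, 400.0, 1.0), DoseEvent(6.0, 400.0, 1.0)]
        t = [0.5, 1.0, 3.0, 6.5, 7.0, 10.0]
        for p in random_params(rng, 50):
            closed = conc_profile(p, doses, t)
            numeric = ode_profile(p, doses, t)
            np.testing.assert_allclose(closed, numeric, rtol=1e-6)

    def test_superposition(self, rng):
        t = np.linspace(0.1, 40, 300)
        for p in random_params(rng, 10):
            doses = [DoseEvent(8.0 * k, 300.0, 1.0) for k in range(4)]
            total = conc_profile(p, doses, t)
            parts = sum(conc_profile(p, [d], t) for d in doses)
            scale = np.max(total)
            np.testing.assert_allclose(total / scale, parts / scale, atol=1e-10)


class TestTypicalParams:
    def test_reference_covariates_return_point_estimates(self):
        p = typical_params(TABLE_THETA, CovariateRecord(clcr=78.2, bun=6.8))
        assert (p.cl, p.v1, p.q, p.v2) == (8.33, 13.4, 3.75, 60.4)

    def test_clcr_shift_scales_clearance(self):
        p = typical_params(TABLE_THETA, CovariateRecord(clcr=178.2, bun=6.8))
        assert p.cl == pytest.approx(8.33 * 1.46, rel=1e-12)
        assert (p.v1, p.v2) == (13.4, 60.4)

    def test_guard_violation_names_covariate(self):
        bad = ThetaVector(8.33, 13.4, 3.75, 60.4, th5_clcr_slope=0.046, th6_bun_slope=0.112)
        with pytest.raises(DomainError, match="clcr"):
            typical_params(bad, CovariateRecord(clcr=10.0, bun=6.8))
        falling_q = ThetaVector(
            8.33, 13.4, 3.75, 60.4, th5_clcr_slope=0.0046, th6_bun_slope=-0.2
        )
        with pytest.raises(DomainError, match="bun"):
            typical_params(falling_q, CovariateRecord(clcr=78.2, bun=15.0))


class TestIndividualParams:
    def test_zero_eta_is_identity(self, typical_patient):
        assert individual_params(typical_patient, 0.0, 0.0) == typical_patient

    def test_log_two_doubles_clearance_only(self, typical_patient):
        p = individual_params(typical_patient, math.log(2.0), 0.0)
        assert p.cl == pytest.approx(2 * typical_patient.cl)
        assert (p.v1, p.q, p.v2) == (
            typical_patient.v1, typical_patient.q, typical_patient.v2,
        )

    def test_median_over_draws_matches_typical(self, typical_patient, rng):
        etas = rng.normal(0.0, math.sqrt(0.0591), size=100_000)
        cls = typical_patient.cl * np.exp(etas)
        # median of a log-normal equals the typical value
        assert np.median(cls) == pytest.approx(typical_patient.cl, rel=5e-3)


class TestAUC:
    def test_dose_over_clearance(self, typical_patient):
        assert auc(typical_patient, 300.0) == pytest.approx(300.0 / 8.33, rel=1e-12)
        assert auc(typical_patient, 300.0) == pytest.approx(36.014, abs=5e-4)

    def test_steady_state_equals_single_dose(self, typical_patient):
        assert auc(typical_patient, 300.0, "steady_state_tau", 8.0) == auc(
            typical_patient, 300.0, "single_inf"
        )

    def test_quadrature_oracle(self, rng):
        for p in random_params(rng, 8):
            doses = [DoseEvent(0.0, 300.0, 1.0)]
            *_, beta = macro_constants(p)
            horizon = 40.0 / beta
            val, _ = quad(
                lambda t: float(conc_profile(p, doses, [t])[0]),
                0.0, horizon, limit=400, points=[1.0],
            )
            assert val == pytest.approx(300.0 / p.cl, rel=1e-3)


class TestFtAboveMic:
    def test_mic_below_trough_gives_100(self, typical_patient):
        reg = Regimen(300.0, 8.0, 1.0)
        trough = interval_profile(typical_patient, reg, np.array([reg.interval]))[0]
        assert ft_above_mic(typical_patient, reg, mic=0.5 * trough) == 100.0

    def test_mic_above_peak_gives_0(self, typical_patient):
        reg = Regimen(300.0, 8.0, 1.0)
        peak = interval_profile(typical_patient, reg, np.array([reg.infusion_duration]))[0]
        assert ft_above_mic(typical_patient, reg, mic=3.0 * peak) == 0.0

    def test_against_dense_grid_oracle(self, typical_patient):
        reg = Regimen(300.0, 8.0, 1.0)
        for steady in (True, False):
            t = np.arange(0.0, reg.interval, 0.001)
            css = interval_profile(typical_patient, reg, t, steady)
            oracle = 100.0 * np.mean(css > 1.0)
            got = ft_above_mic(typical_patient, reg, 1.0, steady_state=steady)
            assert got == pytest.approx(oracle, abs=0.2)

    def test_vectorized_matches_scalar(self, typical_patient, rng):
        reg = Regimen(300.0, 6.0, 1.0)
        params = random_params(rng, 6)
        for steady in (True, False):
            many = ft_above_mic_many(
                np.array([p.cl for p in params]),
                np.array([p.v1 for p in params]),
                np.array([p.q for p in params]),
                np.array([p.v2 for p in params]),
                reg, [0.5, 2.0], steady_state=steady,
            )
            for j, p in enumerate(params):
                for i, mic in enumerate((0.5, 2.0)):
                    assert many[i, j] == pytest.approx(
                        ft_above_mic(p, reg, mic, steady_state=steady), abs=0.05
                    )

    def test_monotone_in_mic_and_dose(self, typical_patient):
        mics = [0.0625, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
        fts = [ft_above_mic(typical_patient, Regimen(300, 6, 1), m) for m in mics]
        assert all(a >= b for a, b in zip(fts, fts[1:]))
        for mic in (2.0, 6.0):
            low = ft_above_mic(typical_patient, Regimen(300, 6, 1), mic)
            high = ft_above_mic(typical_patient, Regimen(600, 6, 1), mic)
            assert high >= low

    def test_invalid_inputs(self, typical_patient):
        reg = Regimen(300, 8, 1)
        with pytest.raises(DomainError):
            ft_above_mic(typical_patient, reg, mic=0.0)
        with pytest.raises(DomainError):
            ft_above_mic(typical_patient, reg, mic=1.0, fu=1.5)


class TestRegimen:
    def test_interval_must_exceed_infusion(self):
        with pytest.raises(DomainError):
            Regimen(300.0, 1.0, 2.0)

    def test_daily_dose(self):
        assert Regimen(300.0, 6.0, 1.0).daily_dose == 1200.0
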