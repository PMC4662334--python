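import math

import numpy as np
import pytest

import ctsecr as ct
from ctsecr.multicatch import occasion_outcome_logprobs


def naive_loglik(model, params, omega, L, traps, mask):
    """Loop-based reference for the full multicatch likelihood; independent
    of the vectorized implementation."""
    lam = 0.0
    cell = mask.cell_area_ha
    M = mask.n_points
    n, K = omega.shape
    contrib = [0.0] * n
    for m in range(M):
        x = mask.points[m]
        D = float(model.intensity(np.array([x]))[0])
        h = [
            -math.log(1 - float(ct.halfnormal_g(
                math.hypot(x[0] - traps.x[k], x[1] - traps.y[k]), params
            )))
            for k in range(K)
        ]
        hdot = sum(h)
        p_escape = math.exp(-hdot)
        lam += D * (1 - p_escape**L) * cell
        for i in range(n):
            P = 1.0
            for k in range(K):
                pk = (h[k] / hdot) * (1 - p_escape)
                P *= pk ** omega[i, k]
            P *= p_escape ** (L - omega[i].sum())
            contrib[i] += D * P * cell
    return -lam - math.lgamma(n + 1) + sum(math.log(c) for c in contrib)


@pytest.fixture(scope="module")
def two_trap_setup():
    traps = ct.build_grid_array(2, 1, 100.0)
    design = ct.SurveyDesign(traps, duration_T=1.0, num_occasions_L=1)
    mask = ct.build_mask(traps, 100.0, 100.0, "full_integration")  # 9 points
    return traps, design, mask


class TestDiscretize:
    def test_empty(self, study_design):
        data = ct.CaptureData(events=(), design=study_design)
        hist = ct.discretize(data, study_design)
        assert hist.n == 0

    def test_occasion_assignment(self, study_design):
        data = ct.CaptureData(
            events=(ct.CaptureEvent(0, 4, 2.3, 3.0),), design=study_design
        )
        hist = ct.discretize(data, study_design)
        assert hist.omega[0, 4] == 1  # third occasion holds t = 2.3

    def test_round_trip_preserves_counts(self, exp1_survey, study_design):
        _, data = exp1_survey
        hist = ct.discretize(data, study_design)
        assert hist.n == data.n
        assert hist.omega.sum() == data.n_events
        assert np.all(hist.omega.sum(axis=1) <= study_design.num_occasions_L)


class TestOutcomeProbabilities:
    def test_per_occasion_normalization(
        self, integration_mask, study_design, study_params
    ):
        log_pk, log_esc = occasion_outcome_logprobs(
            integration_mask.points, study_design.traps, study_params
        )
        total = np.exp(log_pk).sum(axis=1) + np.exp(log_esc)
        np.testing.assert_allclose(total, 1.0, rtol=1e-12)

    def test_single_trap_reduces_to_g(self, lone_trap_design):
        """K = 1: per-occasion capture probability is exactly g(d)."""
        params = ct.DetectionParams(0.3, 80.0)
        pts = np.array([[0.0, 0.0], [50.0, 20.0], [200.0, 0.0]])
        log_pk, _ = occasion_outcome_logprobs(
            pts, lone_trap_design.traps, params
        )
        d = lone_trap_design.traps.distances_to(pts)[:, 0]
        np.testing.assert_allclose(
            np.exp(log_pk[:, 0]), ct.halfnormal_g(d, params), rtol=1e-12
        )


class TestLoglik:
    def test_no_captures_gives_minus_lambda(self, two_trap_setup):
        traps, design, mask = two_trap_setup
        params = ct.DetectionParams(0.2, 100.0)
        hist = ct.DiscreteHistory(np.zeros((0, 2)), 1)
        ll = ct.multicatch_loglik(
            np.array([np.log(2.0)]), params, hist, design, mask
        )
        h = ct.hazard_matrix(mask.points, traps, params)
        lam = float(np.sum(2.0 * (1 - np.exp(-h.sum(axis=1))) * mask.cell_area_ha))
        assert ll == pytest.approx(-lam, rel=1e-12)

    def test_matches_enumeration_oracle(self, two_trap_setup):
        """2 traps, 1 occasion, 9-point mask: likelihood of a one-capture
        history equals the directly enumerated expression."""
        traps, design, mask = two_trap_setup
        params = ct.DetectionParams(0.25, 90.0)
        D0 = 1.7
        omega = np.array([[0.0, 1.0]])
        hist = ct.DiscreteHistory(omega, 1)
        got = ct.multicatch_loglik(np.array([np.log(D0)]), params, hist, design, mask)
        model = ct.DensityModel("constant", [np.log(D0)])
        want = naive_loglik(model, params, omega, 1, traps, mask)
        assert got == pytest.approx(want, rel=1e-10)

    def test_matches_loop_reference_on_study_data(
        self, exp1_survey, study_design, study_params
    ):
        _, data = exp1_survey
        hist = ct.discretize(data, study_design)
        # coarse mask keeps the O(M n K) pure-python reference affordable
        mask = ct.build_mask(study_design.traps, 400.0, 150.0, "full_integration")
        model = ct.get_scenario("exp1").density_model()
        got = ct.multicatch_loglik(
            model.phi, study_params, hist, study_design, mask
        )
        want = naive_loglik(
            model, study_params, hist.omega, 5, study_design.traps, mask
        )
        assert got == pytest.approx(want, rel=1e-9)

    def test_likelihood_prefers_generating_pattern(
        self, exp1_survey, study_design, study_params
    ):
        """Reassigning captures to the far corner trap lowers the likelihood
        at the true parameters, on average."""
        _, data = exp1_survey
        hist = ct.discretize(data, study_design)
        mask = ct.build_mask(study_design.traps, 400.0, 50.0, "full_integration")
        model = ct.get_scenario("exp1").density_model()
        base = ct.multicatch_loglik(model.phi, study_params, hist, study_design, mask)
        rng = np.random.default_rng(0)
        perturbed = []
        for _ in range(5):
            om = hist.omega.copy()
            i = rng.integers(om.shape[0])
            k_from = np.argmax(om[i])
            d = study_design.traps.distances_to(
                np.array([[study_design.traps.x[k_from], study_design.traps.y[k_from]]])
            )[0]
            k_to = int(np.argmax(d))
            om[i, k_from] -= 1
            om[i, k_to] += 1
            hp = ct.DiscreteHistory(om, 5)
            perturbed.append(
                ct.multicatch_loglik(model.phi, study_params, hp, study_design, mask)
            )
        assert base > np.mean(perturbed)


class TestFitMulticatch:
    def test_self_consistency_on_multicatch_data(self, study_design, integration_mask):
        """On data generated by the multicatch model itself, the fit recovers
        (D, g0, sigma) within its own Wald intervals."""
        params = ct.DetectionParams(0.2, 100.0)
        model = ct.DensityModel("constant", [np.log(3.0)])
        pop = ct.simulate_population(model, integration_mask, 31)
        hist = ct.simulate_multicatch_history(pop, study_design, params, 32)
        fit = ct.fit_multicatch(
            hist, study_design, integration_mask, "constant"
        )
        assert fit.converged and fit.usable()
        lo, hi = fit.ci_g0(0.997)
        assert lo <= 0.2 <= hi
        lo, hi = fit.ci_sigma(0.997)
        assert lo <= 100.0 <= hi
        dd = ct.derived_density(fit, integration_mask, level=0.997)
        assert dd["lo"] <= 3.0 <= dd["hi"]

    def test_requires_captures(self, study_design, integration_mask):
        hist = ct.DiscreteHistory(np.zeros((0, 20)), 5)
        with pytest.raises(ValueError):
            ct.fit_multicatch(hist, study_design, integration_mask)
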