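import numpy as np
import pytest

import ctsecr as ct
from ctsecr.availability import build_availability
from ctsecr.fitting import pack, unpack
from ctsecr.singlecatch import _loglik as sc_loglik_inner


def discretized_availability(data, design, dt=1e-3):
    """Brute-force oracle: integrate the availability indicators on a time
    grid instead of by interval arithmetic."""
    T = design.duration_T
    K = design.traps.n_traps
    ids = data.individual_ids
    ts = np.arange(dt / 2, T, dt)
    a = np.ones((K, ts.size), dtype=bool)
    v = np.ones((len(ids), ts.size), dtype=bool)
    for ev in data.events:
        inside = (ts >= ev.capture_time) & (ts < ev.release_time)
        a[ev.trap_id, inside] = False
        v[ids.index(ev.individual_id), inside] = False
    A = a.sum(axis=1) * dt
    U = (v[:, None, :] & a[None, :, :]).sum(axis=2) * dt
    return A, U


@pytest.fixture(scope="module")
def exp4_fit_setup():
    """Scenario-4 survey plus a coarse mask for fast fitting."""
    traps = ct.build_grid_array(5, 4, 100.0)
    design = ct.SurveyDesign(traps, duration_T=5.0, num_occasions_L=5)
    mask = ct.build_mask(traps, 400.0, 50.0, "full_integration")
    model = ct.get_scenario("exp4").density_model()
    params = ct.DetectionParams(0.2, 100.0)
    rng = np.random.default_rng(77)
    pop = ct.simulate_population(model, mask, rng)
    data = ct.simulate_survey(pop, design, params, rng)
    return design, mask, data


class TestLoglik:
    def test_no_captures_reduces_to_minus_lambda(self, study_design, study_params):
        """With no captures the likelihood is exp(-lambda) with full
        availability, i.e. the plug-in equals the standard lambda."""
        mask = ct.build_mask(study_design.traps, 400.0, 100.0, "full_integration")
        data = ct.CaptureData(events=(), design=study_design)
        sched = build_availability(data, study_design)
        D0 = 2.3
        ll = ct.singlecatch_loglik(
            np.array([np.log(D0)]), study_params, data, sched, study_design, mask
        )
        p = ct.p_overall(mask.points, study_design, study_params)
        lam = float(np.sum(D0 * p) * mask.cell_area_ha)
        assert ll == pytest.approx(-lam, rel=1e-12)

    def test_full_availability_survivor_reduction(self, study_design, study_params):
        """With U = T and no captures in the product term, the survivor factor
        is exp(-T h.(x)) — the continuous-time no-competition survivor."""
        mask = ct.build_mask(study_design.traps, 400.0, 100.0, "full_integration")
        K = study_design.traps.n_traps
        T = study_design.duration_T
        sched = ct.AvailabilitySchedule(
            individual_ids=(0,),
            A=np.full(K, T),
            U=np.full((1, K), T),
            omega=np.zeros((1, K)),
        )
        model = ct.DensityModel("constant", [0.0])
        ll = sc_loglik_inner(model, study_params, sched, study_design, mask)
        h = ct.hazard_matrix(mask.points, study_design.traps, study_params)
        hdot = h.sum(axis=1)
        cell = mask.cell_area_ha
        lam = float(np.sum(1.0 * (1 - np.exp(-T * hdot)) * cell))
        want = -lam + np.log(np.sum(np.exp(-T * hdot) * cell))
        assert ll == pytest.approx(want, rel=1e-12)

    def test_matches_time_discretized_oracle(self):
        """2 traps, 2 animals, T = 1: the likelihood computed from exact
        interval arithmetic matches brute-force time discretization of the
        availability indicators to < 1e-3 relative error."""
        traps = ct.build_grid_array(2, 1, 100.0)
        design = ct.SurveyDesign(traps, duration_T=1.0, num_occasions_L=1)
        mask = ct.build_mask(traps, 100.0, 50.0, "full_integration")
        params = ct.DetectionParams(0.3, 90.0)
        data = ct.CaptureData(
            events=(
                ct.CaptureEvent(0, 0, 0.3, 1.0),
                ct.CaptureEvent(1, 1, 0.6, 1.0),
            ),
            design=design,
        )
        sched = build_availability(data, design)
        phi = np.array([np.log(2.0)])
        exact = ct.singlecatch_loglik(phi, params, data, sched, design, mask)
        A, U = discretized_availability(data, design, dt=1e-3)
        approx_sched = ct.AvailabilitySchedule(
            individual_ids=sched.individual_ids, A=A, U=U, omega=sched.omega
        )
        approx = sc_loglik_inner(
            ct.DensityModel("constant", phi), params, approx_sched, design, mask
        )
        assert exact == pytest.approx(approx, rel=1e-3)
        np.testing.assert_allclose(A, sched.A, atol=2e-3)
        np.testing.assert_allclose(U, sched.U, atol=4e-3)

    def test_one_trap_waiting_time_density(self):
        """Single animal, single trap, one observed capture: the individual
        term is D(x) h(x) exp(-h(x) U) — the exponential waiting-time density
        marginalised over the mask."""
        traps = ct.build_grid_array(1, 1, 100.0)
        design = ct.SurveyDesign(traps, duration_T=5.0, num_occasions_L=5)
        mask = ct.build_mask(traps, 200.0, 100.0, "full_integration")
        params = ct.DetectionParams(0.4, 120.0)
        t1 = 1.7
        data = ct.CaptureData(
            events=(ct.CaptureEvent(0, 0, t1, 2.0),), design=design
        )
        sched = build_availability(data, design)
        D0 = 0.9
        got = ct.singlecatch_loglik(
            np.array([np.log(D0)]), params, data, sched, design, mask
        )
        h = ct.hazard_matrix(mask.points, traps, params)[:, 0]
        cell = mask.cell_area_ha
        U = 5.0 - (2.0 - t1)  # animal held from capture to reset at t = 2
        lam_hat = float(np.sum(D0 * (1 - np.exp(-h * U)) * cell))
        term = float(np.sum(D0 * h * np.exp(-h * U) * cell))
        assert got == pytest.approx(-lam_hat + np.log(term), rel=1e-12)


class TestFitSinglecatch:
    def test_optimum_beats_surrounding_grid(self, exp4_fit_setup):
        """The optimizer's maximum is not beaten by a surrounding grid in
        (logit g0, log sigma) with density coefficients held at the MLE."""
        design, mask, data = exp4_fit_setup
        fit = ct.fit_singlecatch(data, design, mask, "log_linear_east")
        assert fit.converged
        sched = build_availability(data, design)

        def ll(psi):
            phi, theta = unpack(psi, "log_linear_east")
            return sc_loglik_inner(
                ct.DensityModel("log_linear_east", phi), theta, sched, design, mask
            )

        best = ll(fit.psi_hat)
        p = 2  # index of logit g0
        for dg in np.linspace(-0.5, 0.5, 5):
            for ds in np.linspace(-0.2, 0.2, 5):
                psi = fit.psi_hat.copy()
                psi[p] += dg
                psi[p + 1] += ds
                assert ll(psi) <= best + 1e-6

    def test_recovers_truth_within_wald_intervals(self, exp4_fit_setup):
        design, mask, data = exp4_fit_setup
        fit = ct.fit_singlecatch(data, design, mask, "log_linear_east")
        assert fit.usable()
        lo, hi = fit.ci_g0(0.997)
        assert lo <= 0.2 <= hi
        lo, hi = fit.ci_sigma(0.997)
        assert lo <= 100.0 <= hi
        truth_slope = ct.get_scenario("exp4").density_model().phi[1]
        lo, hi = fit.ci_slope(0.997)
        assert lo <= truth_slope <= hi

    def test_quadratic_scenario_recovery(self):
        """The log-quadratic density form fits quadratic-scenario data and
        recovers g0, sigma and mean density within wide Wald intervals."""
        traps = ct.build_grid_array(5, 4, 100.0)
        design = ct.SurveyDesign(traps, duration_T=5.0, num_occasions_L=5)
        mask = ct.build_mask(traps, 400.0, 50.0, "full_integration")
        sc = ct.get_scenario("quad4")
        model = sc.density_model()
        params = ct.DetectionParams(sc.g0, sc.sigma)
        rng = np.random.default_rng(55)
        pop = ct.simulate_population(model, mask, rng)
        data = ct.simulate_survey(pop, design, params, rng)
        fit = ct.fit_singlecatch(data, design, mask, "quadratic_east")
        assert fit.converged
        lo, hi = fit.ci_g0(0.997)
        assert lo <= sc.g0 <= hi
        lo, hi = fit.ci_sigma(0.997)
        assert lo <= sc.sigma <= hi
        report = ct.build_mask(traps, 200.0, 50.0, "full_report")
        dd = ct.derived_density(fit, report, level=0.997)
        truth = ct.mean_density(model, report)
        assert dd["lo"] <= truth <= dd["hi"]

    def test_fit_is_deterministic(self, exp4_fit_setup):
        design, mask, data = exp4_fit_setup
        f1 = ct.fit_singlecatch(data, design, mask, "constant")
        f2 = ct.fit_singlecatch(data, design, mask, "constant")
        np.testing.assert_array_equal(f1.psi_hat, f2.psi_hat)
        assert f1.loglik == f2.loglik

    def test_requires_captures(self, study_design, integration_mask):
        data = ct.CaptureData(events=(), design=study_design)
        with pytest.raises(ValueError):
            ct.fit_singlecatch(data, study_design, integration_mask)


class TestDerivedDensity:
    def test_constant_fit_maps_to_exp_b0(self, exp4_fit_setup):
        design, mask, data = exp4_fit_setup
        fit = ct.fit_singlecatch(data, design, mask, "constant")
        region = ct.build_mask(design.traps, 200.0, 50.0, "full_report")
        dd = ct.derived_density(fit, region)
        assert dd["estimate"] == pytest.approx(np.exp(fit.phi_hat[0]), rel=1e-9)
        assert dd["lo"] <= dd["estimate"] <= dd["hi"]

    def test_flat_surface_equal_regions(self, exp4_fit_setup):
        design, mask, data = exp4_fit_setup
        fit = ct.fit_singlecatch(data, design, mask, "constant")
        full = ct.build_mask(design.traps, 200.0, 50.0, "full_report")
        red = ct.build_mask(design.traps, 0.0, 50.0, "reduced_report")
        assert ct.derived_density(fit, full)["estimate"] == pytest.approx(
            ct.derived_density(fit, red)["estimate"], rel=1e-12
        )
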