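"""Simulation-study driver and performance metrics.

Replicates a parameter-recovery study: simulate a population from a scenario
density surface, run a single-catch trap survey over it, fit the single-catch
and/or multicatch estimators, and summarise relative bias, root-mean-squared
prediction error (RMSPE), root-mean-squared bias (RMSB) and Wald-interval
coverage over the full (hull + 2 sigma) and reduced (hull) reporting regions.

Replicates are seeded independently (base seed + replicate index) so results
are reproducible and invariant to execution order. Fits that fail to
converge or produce invalid/huge variances are excluded from the summaries,
with counts reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import DensityModel, ScenarioSpec, mean_density
from .design import Mask, SurveyDesign, build_grid_array, build_mask
from .detection import DetectionParams
from .fitting import FitResult, derived_density
from .multicatch import discretize, fit_multicatch
from .simulate import simulate_population, simulate_survey, trap_saturation
from .singlecatch import fit_singlecatch


def relative_bias(estimates, truth: float) -> tuple[float, float]:
    """Relative bias in percent with its Monte-Carlo standard error."""
    est = np.asarray(estimates, dtype=float)
    if truth == 0:
        raise ValueError("relative bias undefined for zero truth")
    if est.size < 2:
        raise ValueError("need at least two estimates")
    rb = 100.0 * (est.mean() - truth) / truth
    se = 100.0 * est.std(ddof=1) / (np.sqrt(est.size) * abs(truth))
    return float(rb), float(se)


def rmspe(
    surfaces: np.ndarray, truth_surface: np.ndarray, cell_area_ha: float
) -> tuple[float, float]:
    """Mean over replicates of sqrt(MSPE_r), with SE = sd/sqrt(R).

    MSPE_r = mean over grid cells of (Dhat_mr - D_m)^2 * cell_area.
    """
    surf = np.atleast_2d(np.asarray(surfaces, float))
    truth = np.asarray(truth_surface, float)
    if surf.shape[1] != truth.size:
        raise ValueError("surface grids do not match")
    per_rep = np.sqrt(
        np.mean((surf - truth[None, :]) ** 2, axis=1) * cell_area_ha
    )
    se = per_rep.std(ddof=1) / np.sqrt(per_rep.size) if per_rep.size > 1 else 0.0
    return float(per_rep.mean()), float(se)


def rmsb(
    surfaces: np.ndarray,
    truth_surface: np.ndarray,
    cell_area_ha: float,
    n_boot: int = 1000,
    rng: np.random.Generator | int = 0,
) -> tuple[float, float]:
    """RMS bias of the replicate-mean surface, with a bootstrap SE."""
    surf = np.atleast_2d(np.asarray(surfaces, float))
    truth = np.asarray(truth_surface, float)
    if surf.shape[1] != truth.size:
        raise ValueError("surface grids do not match")

    def stat(s: np.ndarray) -> float:
        return float(
            np.sqrt(np.mean((s.mean(axis=0) - truth) ** 2) * cell_area_ha)
        )

    value = stat(surf)
    rng = np.random.default_rng(rng)
    R = surf.shape[0]
    boots = np.array(
        [stat(surf[rng.integers(0, R, R)]) for _ in range(n_boot)]
    )
    return value, float(boots.std(ddof=1))


def coverage(intervals, truth: float) -> float:
    """Fraction of (lo, hi) intervals containing the truth."""
    ivs = [iv for iv in intervals if not (np.isnan(iv[0]) or np.isnan(iv[1]))]
    if not ivs:
        return float("nan")
    return float(np.mean([lo <= truth <= hi for lo, hi in ivs]))


@dataclass
class StudyConfig:
    """One cell of the simulation study design."""

    scenario: ScenarioSpec
    estimators: tuple[str, ...] = ("singlecatch", "multicatch")
    R: int = 500
    L: int = 5
    base_seed: int = 1
    mask_spacing: float | None = None  # default sigma / 4
    max_transformed_se: float = 10.0
    rmsb_boot: int = 1000

    def __post_init__(self) -> None:
        if self.R < 1:
            raise ValueError("need at least one replicate")
        for est in self.estimators:
            if est not in ("singlecatch", "multicatch"):
                raise ValueError(f"unknown estimator {est!r}")


@dataclass
class StudyGeometry:
    design: SurveyDesign
    integration: Mask
    full_report: Mask
    reduced_report: Mask
    model: DensityModel
    params: DetectionParams
    truths: dict[str, float]


def build_geometry(config: StudyConfig) -> StudyGeometry:
    sc = config.scenario
    spacing = config.mask_spacing or sc.sigma / 4
    traps = build_grid_array(sc.n_cols, sc.n_rows, sc.trap_spacing)
    design = SurveyDesign(traps, duration_T=float(config.L), num_occasions_L=config.L)
    integration = build_mask(traps, 4 * sc.sigma, spacing, "full_integration")
    full_report = build_mask(traps, 2 * sc.sigma, spacing, "full_report")
    reduced = build_mask(traps, 0.0, spacing, "reduced_report")
    model = sc.density_model()
    truths = {
        "g0": sc.g0,
        "sigma": sc.sigma,
        "D_F": mean_density(model, full_report),
        "D_R": mean_density(model, reduced),
    }
    if sc.density_form == "log_linear_east":
        truths["slope"] = float(model.phi[1])
    return StudyGeometry(
        design=design,
        integration=integration,
        full_report=full_report,
        reduced_report=reduced,
        model=model,
        params=DetectionParams(sc.g0, sc.sigma),
        truths=truths,
    )


@dataclass
class EstimatorRecord:
    """Per-replicate outputs for one estimator."""

    fit: FitResult
    usable: bool
    estimates: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    surfaces: dict[str, np.ndarray]  # fitted D on report grids


@dataclass
class StudyResult:
    config: StudyConfig
    geometry: StudyGeometry
    n_captured: list[int] = field(default_factory=list)
    saturation: list[float] = field(default_factory=list)
    records: dict[str, list[EstimatorRecord]] = field(default_factory=dict)
    n_empty: int = 0  # replicates with no captures (resimulated counts)

    def usable_records(self, estimator: str) -> list[EstimatorRecord]:
        return [r for r in self.records.get(estimator, []) if r.usable]

    def n_excluded(self, estimator: str) -> int:
        recs = self.records.get(estimator, [])
        return len(recs) - len(self.usable_records(estimator))

    def summarize(self) -> dict:
        """Relative biases, RMSPE/RMSB and coverage per estimator."""
        out: dict = {
            "scenario": f"{self.config.scenario.simulation_type.lower()}"
            f"{self.config.scenario.scenario_id}",
            "R": self.config.R,
            "L": self.config.L,
            "mean_unique": float(np.mean(self.n_captured)),
            "mean_saturation_pct": float(np.mean(self.saturation)),
            "estimators": {},
        }
        truths = self.geometry.truths
        for est, recs in self.records.items():
            usable = [r for r in recs if r.usable]
            entry: dict = {"reps_used": len(usable), "reps_excluded": len(recs) - len(usable)}
            if len(usable) >= 2:
                rb = {}
                for name, truth in truths.items():
                    vals = [r.estimates[name] for r in usable if name in r.estimates]
                    if vals:
                        rb[name] = relative_bias(vals, truth)
                entry["relative_bias"] = rb
                entry["coverage"] = {
                    name: coverage(
                        [r.intervals[name] for r in usable if name in r.intervals],
                        truth,
                    )
                    for name, truth in truths.items()
                    if any(name in r.intervals for r in usable)
                }
                perf = {}
                for tag, region in (
                    ("full", self.geometry.full_report),
                    ("reduced", self.geometry.reduced_report),
                ):
                    truth_surf = self.geometry.model.intensity(region.points)
                    surf = np.array([r.surfaces[tag] for r in usable])
                    perf[tag] = {
                        "rmspe": rmspe(surf, truth_surf, region.cell_area_ha),
                        "rmsb": rmsb(
                            surf,
                            truth_surf,
                            region.cell_area_ha,
                            n_boot=self.config.rmsb_boot,
                            rng=self.config.base_seed + 10_000,
                        ),
                    }
                entry["surface_metrics"] = perf
            out["estimators"][est] = entry
        return out


def _record(
    fit: FitResult, geom: StudyGeometry, max_se: float
) -> EstimatorRecord:
    est: dict[str, float] = {
        "g0": fit.g0_hat,
        "sigma": fit.sigma_hat,
    }
    ivs: dict[str, tuple[float, float]] = {}
    usable = fit.usable(max_se)
    if usable:
        ivs["g0"] = fit.ci_g0()
        ivs["sigma"] = fit.ci_sigma()
    if fit.density_form == "log_linear_east":
        est["slope"] = float(fit.phi_hat[1])
        if usable:
            ivs["slope"] = fit.ci_slope()
    surfaces = {}
    model = fit.density_model
    for tag, region in (("full", geom.full_report), ("reduced", geom.reduced_report)):
        surfaces[tag] = model.intensity(region.points)
        key = "D_F" if tag == "full" else "D_R"
        dd = derived_density(fit, region) if usable else {"estimate": float(np.mean(surfaces[tag])), "lo": np.nan, "hi": np.nan}
        est[key] = dd["estimate"]
        if usable:
            ivs[key] = (dd["lo"], dd["hi"])
    return EstimatorRecord(
        fit=fit, usable=usable, estimates=est, intervals=ivs, surfaces=surfaces
    )


def run_replicate(
    config: StudyConfig, geom: StudyGeometry, seed: int
) -> tuple[int, float, dict[str, EstimatorRecord]] | None:
    """Simulate one survey and fit the requested estimators.

    Returns None when no animal is captured (recorded and skipped upstream).
    """
    rng = np.random.default_rng(seed)
    pop = simulate_population(geom.model, geom.integration, rng)
    data = simulate_survey(pop, geom.design, geom.params, rng)
    if data.n == 0:
        return None
    sat = trap_saturation(data, geom.design)
    records: dict[str, EstimatorRecord] = {}
    form = config.scenario.density_form
    if "multicatch" in config.estimators:
        hist = discretize(data, geom.design)
        fit = fit_multicatch(hist, geom.design, geom.integration, form)
        records["multicatch"] = _record(fit, geom, config.max_transformed_se)
    if "singlecatch" in config.estimators:
        fit = fit_singlecatch(data, geom.design, geom.integration, form)
        records["singlecatch"] = _record(fit, geom, config.max_transformed_se)
    return data.n, sat, records


def run_study(config: StudyConfig, progress: bool = False) -> StudyResult:
    """Run the full replicate loop for one study cell."""
    geom = build_geometry(config)
    result = StudyResult(config=config, geometry=geom)
    for est in config.estimators:
        result.records[est] = []
    rep = 0
    attempts = 0
    while rep < config.R:
        seed = config.base_seed + attempts
        attempts += 1
        out = run_replicate(config, geom, seed)
        if out is None:
            result.n_empty += 1
            continue
        n, sat, records = out
        result.n_captured.append(n)
        result.saturation.append(sat)
        for est, rec in records.items():
            result.records[est].append(rec)
        rep += 1
        if progress and rep % 10 == 0:
            print(f"  replicate {rep}/{config.R}", flush=True)
    return result


def simulate_summary(
    config: StudyConfig,
) -> dict[str, float]:
    """Simulation-only study: mean unique individuals and trap saturation.

    Much cheaper than run_study because no model is fitted; used to check
    the simulator against the scenario design targets.
    """
    geom = build_geometry(config)
    uniques = []
    sats = []
    events = []
    cap = geom.design.traps.n_traps * config.L
    for rep in range(config.R):
        rng = np.random.default_rng(config.base_seed + rep)
        pop = simulate_population(geom.model, geom.integration, rng)
        data = simulate_survey(pop, geom.design, geom.params, rng)
        uniques.append(data.n)
        events.append(data.n_events)
        sats.append(trap_saturation(data, geom.design))
    u = np.asarray(uniques, float)
    s = np.asarray(sats, float)
    return {
        "mean_unique": float(u.mean()),
        "se_unique": float(u.std(ddof=1) / np.sqrt(u.size)) if u.size > 1 else 0.0,
        "mean_saturation_pct": float(s.mean()),
        "se_saturation_pct": float(s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else 0.0,
        "max_events": int(max(events)),
        "capture_cap": int(cap),
    }
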