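"""File formats: timed capture records, fit results, and test fixtures.

Capture files are CSV with header ``individual_id, trap_id, capture_time_days,
release_time_days``; times are days from the survey origin, written with full
precision. Survey metadata (duration, occasions, seed, scenario) travels in a
YAML sidecar. Fit results round-trip through YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import SurveyDesign
from .fitting import FitResult
from .simulate import CaptureData, CaptureEvent


def write_captures(data: CaptureData, path, metadata: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "individual_id": [ev.individual_id for ev in data.events],
            "trap_id": [ev.trap_id for ev in data.events],
            "capture_time_days": [ev.capture_time for ev in data.events],
            "release_time_days": [ev.release_time for ev in data.events],
        }
    )
    # default float formatting is shortest-repr, hence lossless round-trip
    df.to_csv(path, index=False)
    if metadata is not None:
        side = Path(path).with_suffix(".meta.yaml")
        design = data.design
        meta = {
            "duration_T_days": float(design.duration_T),
            "num_occasions_L": int(design.num_occasions_L),
            "reset_time_of_day_h": float(design.reset_time_of_day),
            **metadata,
        }
        side.write_text(yaml.safe_dump(meta))


def read_captures(path, design: SurveyDesign) -> CaptureData:
    """Read and validate a timed capture file against a survey design.

    Occupancy conflicts and out-of-range times are rejected with row-level
    diagnostics.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    required = [
        "individual_id",
        "trap_id",
        "capture_time_days",
        "release_time_days",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"capture file missing columns: {missing}")
    events = []
    for row in df.itertuples():
        ct, rt = float(row.capture_time_days), float(row.release_time_days)
        if not 0.0 <= ct < rt <= design.duration_T + 1e-9:
            raise ValueError(
                f"row {row.Index}: times ({ct}, {rt}) outside [0, T={design.duration_T}]"
                " or out of order"
            )
        events.append(
            CaptureEvent(int(row.individual_id), int(row.trap_id), ct, rt)
        )
    try:
        return CaptureData(events=tuple(events), design=design)
    except ValueError as exc:
        raise ValueError(f"invalid capture data in {path}: {exc}") from exc


def write_fit(result: FitResult, path) -> None:
    """Serialise a fit result to YAML (lossless for all numeric fields)."""
    doc = {
        "density_form": result.density_form,
        "psi_hat": [float(v) for v in result.psi_hat],
        "param_names": result.names,
        "vcov": None
        if result.vcov is None
        else [[float(v) for v in row] for row in result.vcov],
        "loglik": float(result.loglik),
        "converged": bool(result.converged),
        "message": result.message,
        "n_evals": int(result.n_evals),
        "estimates": {
            "g0": float(result.g0_hat),
            "sigma_m": float(result.sigma_hat),
            "phi": [float(v) for v in result.phi_hat],
        },
    }
    if result.converged and result.vcov is not None:
        doc["ci95"] = {
            "g0": [float(v) for v in result.ci_g0()],
            "sigma_m": [float(v) for v in result.ci_sigma()],
        }
        if result.density_form == "log_linear_east":
            doc["ci95"]["slope"] = [float(v) for v in result.ci_slope()]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_fit(path) -> FitResult:
    doc = yaml.safe_load(Path(path).read_text())
    return FitResult(
        density_form=doc["density_form"],
        psi_hat=np.array(doc["psi_hat"], float),
        vcov=None if doc["vcov"] is None else np.array(doc["vcov"], float),
        loglik=float(doc["loglik"]),
        converged=bool(doc["converged"]),
        message=doc.get("message", ""),
        n_evals=int(doc.get("n_evals", 0)),
    )


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Write the small deterministic datasets used by the test suite.

    Two fixtures: a one-trap / one-animal survey with a hand-checkable
    likelihood, and a mini scenario-4 survey.
    """
    from .density import get_scenario
    from .design import build_grid_array, build_mask, write_traps
    from .detection import DetectionParams
    from .evaluation import StudyConfig, build_geometry
    from .simulate import Population, simulate_survey

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # 1-trap, 1-animal analytic case
    traps = build_grid_array(1, 1, 100.0)
    design = SurveyDesign(traps, duration_T=5.0, num_occasions_L=5)
    pop = Population(np.array([[50.0, 0.0]]))
    data = simulate_survey(pop, design, DetectionParams(0.5, 100.0), seed)
    paths["analytic_captures"] = out / "analytic_captures.csv"
    write_captures(data, paths["analytic_captures"], metadata={"seed": seed})
    paths["analytic_traps"] = out / "analytic_traps.csv"
    write_traps(traps, paths["analytic_traps"])

    # scenario-4 mini survey
    cfg = StudyConfig(scenario=get_scenario("exp4"), R=1, base_seed=seed)
    geom = build_geometry(cfg)
    rng = np.random.default_rng(seed)
    from .simulate import simulate_population

    pop4 = simulate_population(geom.model, geom.integration, rng)
    data4 = simulate_survey(pop4, geom.design, geom.params, rng)
    paths["scenario4_captures"] = out / "scenario4_captures.csv"
    write_captures(
        data4, paths["scenario4_captures"], metadata={"seed": seed, "scenario": "exp4"}
    )
    paths["scenario4_traps"] = out / "scenario4_traps.csv"
    write_traps(geom.design.traps, paths["scenario4_traps"])
    return paths
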