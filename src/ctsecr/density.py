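"""Inhomogeneous Poisson density surfaces and the simulation-study scenarios.

Density D(x; phi) is an intensity in animals per hectare evaluated at planar
coordinates in metres. Three forms are supported, all log-linear in their
coefficients so positivity is automatic:

- constant:        D = exp(b0)
- log_linear_east: D = exp(b0 + b1 * x_east)         (exponential gradient)
- quadratic_east:  D = exp(c0 + c1 * x_east + c2 * x_east^2)

The study scenarios calibrate these forms to a density DS at the western
array edge (x = 0) and a maximum DMax — at 4 sigma east of the array for the
exponential scenarios, at the profile peak for the quadratic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .design import M2_PER_HA, Mask

DensityForm = Literal["constant", "log_linear_east", "quadratic_east"]

#: number of free coefficients per density form
N_COEF = {"constant": 1, "log_linear_east": 2, "quadratic_east": 3}


@dataclass(frozen=True)
class DensityModel:
    """Log-linear intensity surface over the plane."""

    form: DensityForm
    phi: np.ndarray  # coefficient vector, see module docstring

    def __post_init__(self) -> None:
        phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        object.__setattr__(self, "phi", phi)
        if self.form not in N_COEF:
            raise ValueError(f"unknown density form {self.form!r}")
        if phi.size != N_COEF[self.form]:
            raise ValueError(
                f"form {self.form!r} needs {N_COEF[self.form]} coefficients"
            )
        if not np.all(np.isfinite(phi)):
            raise ValueError("coefficients must be finite")

    def log_intensity(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x = pts[:, 0]
        if self.form == "constant":
            return np.full(x.shape, self.phi[0])
        if self.form == "log_linear_east":
            return self.phi[0] + self.phi[1] * x
        return self.phi[0] + self.phi[1] * x + self.phi[2] * x**2

    def intensity(self, points: np.ndarray) -> np.ndarray:
        """D(x; phi), animals per hectare; strictly positive."""
        out = np.exp(self.log_intensity(points))
        return out if np.ndim(points) > 1 else out[0] if out.size == 1 else out

    def max_on_x_range(self, xmin: float, xmax: float) -> float:
        """Upper bound for the intensity over x in [xmin, xmax] (any y)."""
        cand = [xmin, xmax]
        if self.form == "quadratic_east" and self.phi[2] < 0:
            peak = -self.phi[1] / (2.0 * self.phi[2])
            if xmin <= peak <= xmax:
                cand.append(peak)
        pts = np.column_stack([cand, np.zeros(len(cand))])
        return float(np.exp(self.log_intensity(pts)).max())


def intensity(model: DensityModel, x) -> np.ndarray:
    """Functional alias for ``model.intensity``."""
    return model.intensity(x)


def mean_density(model: DensityModel, region: Mask) -> float:
    """Area-weighted mean intensity over a mask region (per hectare)."""
    return float(np.mean(model.intensity(region.points)))


def integrate_intensity(model: DensityModel, geometry, spacing: float) -> float:
    """Integral of D over a polygon (expected animal count), by a cell-centred
    midpoint rule at the given grid spacing.

    Cell centres tile the bounding box exactly, so rectangular regions are
    integrated without boundary overcount; non-rectangular regions lose at
    most one boundary sliver per edge.
    """
    import shapely

    xmin, ymin, xmax, ymax = geometry.bounds
    xs = np.arange(xmin + spacing / 2, xmax, spacing)
    ys = np.arange(ymin + spacing / 2, ymax, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(geometry, pts[:, 0], pts[:, 1])
    return float(
        model.intensity(pts[inside]).sum() * spacing**2 / M2_PER_HA
    )


def expected_population(model: DensityModel, region: Mask) -> float:
    """Expected number of activity centres in a mask's region."""
    spacing = float(np.sqrt(region.cell_area))
    return integrate_intensity(model, region.region, spacing)


def calibrate_exponential(
    DS: float, DMax: float, array_east_extent: float, sigma: float
) -> DensityModel:
    """Exponential east-west gradient hitting DS at x=0, DMax at 4 sigma east
    of the eastern array edge."""
    if not (DMax >= DS > 0):
        raise ValueError("need DMax >= DS > 0")
    span = array_east_extent + 4.0 * sigma
    if span <= 0:
        raise ValueError("degenerate geometry")
    b1 = np.log(DMax / DS) / span
    return DensityModel("log_linear_east", np.array([np.log(DS), b1]))


def calibrate_quadratic(
    DS: float, DMax: float, peak_east: float, validate_on: Mask | None = None
) -> DensityModel:
    """Eastward log-quadratic profile peaking at DMax, with D(0) = DS.

    log D = log(DMax) - a (x - peak)^2 with a >= 0 fixed by D(0) = DS; the
    log-scale quadratic guarantees positivity everywhere.
    """
    if DMax <= 0 or DS <= 0:
        raise ValueError("densities must be positive")
    if DMax < DS:
        raise ValueError("DMax must be >= DS")
    if DMax == DS:
        return DensityModel("quadratic_east", np.array([np.log(DMax), 0.0, 0.0]))
    if peak_east == 0:
        raise ValueError("peak at x=0 with DMax > DS is inconsistent with D(0)=DS")
    a = np.log(DMax / DS) / peak_east**2
    c2 = -a
    c1 = 2.0 * a * peak_east
    c0 = np.log(DMax) - a * peak_east**2
    model = DensityModel("quadratic_east", np.array([c0, c1, c2]))
    if validate_on is not None and np.any(model.intensity(validate_on.points) <= 0):
        raise ValueError("quadratic surface non-positive on the mask")
    return model


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the simulation-study design.

    Design constants shared by every scenario: half-normal detection with
    g0 = 0.2 and sigma = 100 m, a 5 x 4 trap array at 100 m spacing, daily
    resets. DMax / DS calibrate the density profile as in the module
    docstring; the exponential scenarios place DMax at 4 sigma east of the
    array, the quadratic ones at ``peak_east``.
    """

    simulation_type: Literal["Exponential", "Quadratic"]
    scenario_id: int
    DMax: float
    DS: float
    peak_east: float | None = None  # quadratic only
    sigma: float = 100.0
    g0: float = 0.2
    n_cols: int = 5
    n_rows: int = 4
    trap_spacing: float = 100.0

    @property
    def array_east_extent(self) -> float:
        return (self.n_cols - 1) * self.trap_spacing

    def density_model(self) -> DensityModel:
        if self.simulation_type == "Exponential":
            return calibrate_exponential(
                self.DS, self.DMax, self.array_east_extent, self.sigma
            )
        return calibrate_quadratic(self.DS, self.DMax, self.peak_east)

    @property
    def density_form(self) -> DensityForm:
        return (
            "log_linear_east"
            if self.simulation_type == "Exponential"
            else "quadratic_east"
        )


#: the simulation-study scenario library, keyed by e.g. "exp1", "quad3"
SCENARIOS: dict[str, ScenarioSpec] = {
    "exp1": ScenarioSpec("Exponential", 1, DMax=6.00, DS=2.00),
    "exp2": ScenarioSpec("Exponential", 2, DMax=6.00, DS=1.00),
    "exp3": ScenarioSpec("Exponential", 3, DMax=6.00, DS=0.50),
    "exp4": ScenarioSpec("Exponential", 4, DMax=2.00, DS=0.67),
    # quadratic peaks: array centre, except scenario 3 where the peak is
    # shifted to the eastern edge of the array
    "quad1": ScenarioSpec("Quadratic", 1, DMax=3.68, DS=2.48, peak_east=200.0),
    "quad2": ScenarioSpec("Quadratic", 2, DMax=3.71, DS=0.52, peak_east=200.0),
    "quad3": ScenarioSpec("Quadratic", 3, DMax=3.86, DS=0.03, peak_east=400.0),
    "quad4": ScenarioSpec("Quadratic", 4, DMax=1.49, DS=0.74, peak_east=200.0),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        ) from None
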