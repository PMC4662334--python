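"""Half-normal detection function and its continuous-time hazard link.

The discrete-occasion detection function g(d) = g0 exp(-d^2 / 2 sigma^2) is
the probability that a lone, always-available trap at distance d catches the
animal within one occasion. The continuous-time model uses the constant
hazard h(d) = -ln(1 - g(d)) per occasion (occasions are 1 day long), so that
1 - exp(-h(d) * 1 day) = g(d) exactly and the two parameterisations describe
the same detection process.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import SurveyDesign


@dataclass(frozen=True)
class DetectionParams:
    """Half-normal detection parameters: height g0 and range sigma (metres)."""

    g0: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 < self.g0 < 1.0:
            raise ValueError("g0 must be in (0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def halfnormal_g(d, params: DetectionParams) -> np.ndarray:
    """Per-occasion capture probability at distance d (metres)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    return params.g0 * np.exp(-(d**2) / (2.0 * params.sigma**2))


def hazard_rate(d, params: DetectionParams) -> np.ndarray:
    """Constant capture hazard (per day) linked to the half-normal g(d).

    h = -ln(1 - g(d)); a lone always-available trap then catches the animal
    within one 24-h occasion with probability exactly g(d).
    """
    g = halfnormal_g(d, params)
    if np.any(g >= 1.0):
        raise ValueError("detection probability must be < 1")
    return -np.log1p(-g)


def hazard_matrix(points: np.ndarray, traps, params: DetectionParams) -> np.ndarray:
    """Per-trap baseline hazards h_k(x), shape (n_points, K)."""
    return hazard_rate(traps.distances_to(points), params)


def survivor_overall(
    x,
    design: SurveyDesign,
    params: DetectionParams,
    availability: np.ndarray,
) -> np.ndarray:
    """P(animal at x never caught), given per-trap available-time totals.

    ``availability`` holds A_k (or the individual-specific U_ik), the total
    time in days trap k was simultaneously unoccupied and the animal free;
    the survivor is exp(-sum_k h_k(x) A_k) because hazards are constant in
    time.
    """
    avail = np.asarray(availability, dtype=float)
    if np.any(avail < 0) or np.any(avail > design.duration_T + 1e-9):
        raise ValueError("availability totals must lie in [0, T]")
    h = hazard_matrix(np.atleast_2d(x), design.traps, params)
    out = np.exp(-h @ avail)
    return out[0] if np.ndim(x) == 1 else out


def p_overall(x, design: SurveyDesign, params: DetectionParams) -> np.ndarray:
    """Overall detection probability p.(x) = 1 - S.(T, x) with full availability."""
    full = np.full(design.traps.n_traps, design.duration_T)
    return 1.0 - survivor_overall(x, design, params, full)
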