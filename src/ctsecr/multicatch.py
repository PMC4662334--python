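"""Discrete-occasion multicatch SECR likelihood (the comparator estimator).

Timed single-catch records are reduced to occasion-level capture histories
and fitted with the standard multicatch-trap likelihood: within an occasion
an animal at x is caught in trap k with probability

    p_k(x) = (h_k(x) / h.(x)) * (1 - exp(-h.(x)))

and escapes capture with probability exp(-h.(x)), where h_k is the linked
half-normal hazard and h. its sum over traps. Traps are assumed never to
fill — the assumption the single-catch likelihood removes. The full (Poisson
n) likelihood multiplies per-individual mask integrals by the Poisson term
for the number of distinct animals, with lambda = integral of
D(x) (1 - exp(-L h.(x))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .density import N_COEF, DensityForm, DensityModel
from .design import Mask, SurveyDesign, occasion_boundaries
from .detection import DetectionParams, hazard_matrix
from .fitting import (
    FitResult,
    maximize,
    observed_information_vcov,
    pack,
    unpack,
)
from .simulate import CaptureData, Population

_H_FLOOR = 1e-300  # keeps log h finite when exp underflows far from the array


@dataclass(frozen=True)
class DiscreteHistory:
    """Occasion-level capture counts omega_ik for the n captured individuals."""

    omega: np.ndarray  # (n, K) counts
    num_occasions_L: int
    individual_ids: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", om.reshape(-1, om.shape[-1] if om.ndim > 1 else 0))
        if np.any(self.omega < 0):
            raise ValueError("capture counts must be non-negative")
        if np.any(self.omega.sum(axis=1) > self.num_occasions_L):
            raise ValueError("more captures than occasions for some individual")

    @property
    def n(self) -> int:
        return int(self.omega.shape[0])


def discretize(data: CaptureData, design: SurveyDesign) -> DiscreteHistory:
    """Assign each timed capture to the occasion containing it."""
    bounds = occasion_boundaries(design)
    ids = data.individual_ids
    row = {ident: r for r, ident in enumerate(ids)}
    omega = np.zeros((len(ids), design.traps.n_traps))
    for ev in data.events:
        if not 0.0 <= ev.capture_time <= design.duration_T:
            raise ValueError(f"capture time {ev.capture_time} outside [0, T]")
        omega[row[ev.individual_id], ev.trap_id] += 1
    return DiscreteHistory(
        omega=omega,
        num_occasions_L=design.num_occasions_L,
        individual_ids=tuple(ids),
    )


def occasion_outcome_logprobs(
    points: np.ndarray, traps, params: DetectionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-occasion log P(caught in trap k | x) (M, K) and log P(escape | x) (M,)."""
    h = np.maximum(hazard_matrix(points, traps, params), _H_FLOOR)
    hdot = h.sum(axis=1)
    log_p_escape = -hdot
    # log(1 - exp(-hdot)) via expm1 for small hazards
    log_p_caught = np.log(-np.expm1(-hdot))
    log_pk = np.log(h) - np.log(hdot)[:, None] + log_p_caught[:, None]
    return log_pk, log_p_escape


def multicatch_loglik(
    phi: np.ndarray,
    theta: DetectionParams,
    hist: DiscreteHistory,
    design: SurveyDesign,
    mask: Mask,
) -> float:
    """Full-likelihood log L(phi, theta | histories) by mask summation."""
    model = DensityModel(
        "constant" if len(np.atleast_1d(phi)) == 1 else
        ("log_linear_east" if len(np.atleast_1d(phi)) == 2 else "quadratic_east"),
        phi,
    )
    return _loglik(model, theta, hist, design, mask)


def _loglik(
    model: DensityModel,
    theta: DetectionParams,
    hist: DiscreteHistory,
    design: SurveyDesign,
    mask: Mask,
) -> float:
    L = hist.num_occasions_L
    log_pk, log_p_escape = occasion_outcome_logprobs(
        mask.points, design.traps, theta
    )
    logD = model.log_intensity(mask.points)
    log_cell = np.log(mask.cell_area_ha)
    with np.errstate(over="ignore"):  # inf lambda -> -inf loglik, rejected upstream
        lam = float(
            np.sum(np.exp(logD) * -np.expm1(L * log_p_escape)) * mask.cell_area_ha
        )
    ll = -lam - gammaln(hist.n + 1)
    if hist.n:
        W = hist.omega  # (n, K)
        caught = W.sum(axis=1)  # per-individual total captures
        per_point = W @ log_pk.T + (L - caught)[:, None] * log_p_escape[None, :]
        ll += float(np.sum(logsumexp(per_point + logD[None, :] + log_cell, axis=1)))
    return ll


def _default_starts(
    hist: DiscreteHistory, design: SurveyDesign, mask: Mask, form: DensityForm
) -> list[np.ndarray]:
    n = max(hist.n, 1)
    area_ha = mask.area / 1e4
    d0 = max(n / area_ha, 1e-3)
    caught = hist.omega.sum() / (n * hist.num_occasions_L) if hist.n else 0.1
    g0 = float(np.clip(caught, 0.02, 0.8))
    coords = design.traps.coords
    pd = np.hypot(
        coords[:, None, 0] - coords[None, :, 0],
        coords[:, None, 1] - coords[None, :, 1],
    )
    sigma0 = max(np.median(pd[pd > 0]) / 2 if np.any(pd > 0) else 100.0, 1.0)
    phi0 = np.zeros(N_COEF[form])
    phi0[0] = np.log(d0)
    base = pack(phi0, DetectionParams(g0, sigma0))
    alt1 = base.copy()
    alt1[-1] += np.log(2.0)  # wider sigma
    alt2 = base.copy()
    alt2[N_COEF[form]] -= 1.5  # lower g0
    return [base, alt1, alt2]


def fit_multicatch(
    hist: DiscreteHistory,
    design: SurveyDesign,
    mask: Mask,
    density_form: DensityForm = "constant",
    start_values: np.ndarray | None = None,
    reltol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood fit of the multicatch comparator model."""
    if hist.n < 1:
        raise ValueError("need at least one captured individual")

    def negloglik(psi: np.ndarray) -> float:
        phi, theta = unpack(psi, density_form)
        val = _loglik(DensityModel(density_form, phi), theta, hist, design, mask)
        return -val if np.isfinite(val) else 1e12

    starts = (
        [np.asarray(start_values, float)]
        if start_values is not None
        else _default_starts(hist, design, mask, density_form)
    )
    psi, ll, ok, msg, nev = maximize(negloglik, starts, reltol=reltol)
    vcov = observed_information_vcov(negloglik, psi) if ok else None
    return FitResult(
        density_form=density_form,
        psi_hat=psi,
        vcov=vcov,
        loglik=ll,
        converged=ok,
        message=msg,
        n_evals=nev,
        mask=mask,
    )


def simulate_multicatch_history(
    pop: Population,
    design: SurveyDesign,
    params: DetectionParams,
    rng: np.random.Generator | int,
) -> DiscreteHistory:
    """Simulate occasion histories under the multicatch model itself (traps
    never fill); used for self-consistency checks of the comparator."""
    rng = np.random.default_rng(rng)
    K = design.traps.n_traps
    L = design.num_occasions_L
    if pop.size == 0:
        return DiscreteHistory(np.zeros((0, K)), L)
    log_pk, log_p_escape = occasion_outcome_logprobs(
        pop.centers, design.traps, params
    )
    probs = np.column_stack([np.exp(log_pk), np.exp(log_p_escape)])
    probs /= probs.sum(axis=1, keepdims=True)
    rows = []
    ids = []
    for i in range(pop.size):
        draws = rng.choice(K + 1, size=L, p=probs[i])
        counts = np.bincount(draws[draws < K], minlength=K)
        if counts.sum() > 0:
            rows.append(counts)
            ids.append(i)
    if not rows:
        return DiscreteHistory(np.zeros((0, K)), L)
    return DiscreteHistory(np.array(rows, float), L, tuple(ids))
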