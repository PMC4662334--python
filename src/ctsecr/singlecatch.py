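"""Continuous-time single-catch SECR estimator from observed capture times.

The likelihood treats captures as a competing-hazards survival process in
which both the animal and the trap leave the risk set at a capture. With
constant hazards, observed availability enters only through the totals
U_ik (time individual i was free while trap k was empty) and A_k (time trap
k was empty), and the log-likelihood is

    log L = -lambda_hat - log n!
            + sum_i log [ sum_mask D(x) exp(-sum_k h_k(x) U_ik)
                          prod_k h_k(x)^omega_ik * cell_area ]

where lambda_hat = sum_mask D(x) (1 - exp(-sum_k h_k(x) A_k)) * cell_area
plugs the observed trap availability into the expected number of distinct
captures. Because the availability indicators depend on random capture
times, the plug-in estimator is not an exact MLE; its bias and the coverage
of observed-information Wald intervals are assessed by simulation in
:mod:`ctsecr.evaluation`.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln, logsumexp

from .availability import AvailabilitySchedule, build_availability
from .density import DensityForm, DensityModel, N_COEF
from .design import Mask, SurveyDesign
from .detection import DetectionParams, hazard_matrix
from .fitting import (
    FitResult,
    derived_density,
    maximize,
    observed_information_vcov,
    unpack,
)
from .multicatch import _default_starts, discretize
from .simulate import CaptureData

__all__ = [
    "singlecatch_loglik",
    "fit_singlecatch",
    "build_availability",
    "derived_density",
]

_H_FLOOR = 1e-300


def singlecatch_loglik(
    phi: np.ndarray,
    theta: DetectionParams,
    data: CaptureData,
    sched: AvailabilitySchedule,
    design: SurveyDesign,
    mask: Mask,
) -> float:
    form = {1: "constant", 2: "log_linear_east", 3: "quadratic_east"}[
        len(np.atleast_1d(phi))
    ]
    return _loglik(DensityModel(form, phi), theta, sched, design, mask)


def _loglik(
    model: DensityModel,
    theta: DetectionParams,
    sched: AvailabilitySchedule,
    design: SurveyDesign,
    mask: Mask,
) -> float:
    h = np.maximum(hazard_matrix(mask.points, design.traps, theta), _H_FLOOR)
    logD = model.log_intensity(mask.points)
    cell_ha = mask.cell_area_ha
    # plug-in expected number of distinct captures, from observed A_k
    exposure = h @ sched.A  # (M,)
    with np.errstate(over="ignore"):  # inf lambda -> -inf loglik, rejected upstream
        lam_hat = float(np.sum(np.exp(logD) * -np.expm1(-exposure)) * cell_ha)
    ll = -lam_hat - gammaln(sched.n + 1)
    if sched.n:
        # (n, M): log D(x) - sum_k h_k U_ik + sum_k omega_ik log h_k
        per_point = (
            logD[None, :] - sched.U @ h.T + sched.omega @ np.log(h).T
        )
        ll += float(
            np.sum(logsumexp(per_point + np.log(cell_ha), axis=1))
        )
    return ll


def fit_singlecatch(
    data: CaptureData,
    design: SurveyDesign,
    mask: Mask,
    density_form: DensityForm = "constant",
    start_values: np.ndarray | None = None,
    reltol: float = 1e-8,
) -> FitResult:
    """Maximise the observed-availability single-catch likelihood.

    Returns transformed-scale estimates with an observed-information
    covariance; derived density summaries over reporting regions come from
    :func:`ctsecr.fitting.derived_density`.
    """
    if data.n < 1:
        raise ValueError("need at least one captured individual")
    sched = build_availability(data, design)

    def negloglik(psi: np.ndarray) -> float:
        phi, theta = unpack(psi, density_form)
        val = _loglik(DensityModel(density_form, phi), theta, sched, design, mask)
        return -val if np.isfinite(val) else 1e12

    if start_values is not None:
        starts = [np.asarray(start_values, float)]
    else:
        hist = discretize(data, design)
        starts = _default_starts(hist, design, mask, density_form)
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
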