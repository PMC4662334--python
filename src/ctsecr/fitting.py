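"""Shared maximum-likelihood machinery: parameter transforms, optimisation,
observed-information variances and delta-method derived densities.

Both estimators maximise over an unconstrained transformed vector

    psi = (phi..., logit g0, log sigma)

where the density coefficients phi are already log-scale (identity transform)
and the detection parameters use the standard logit/log transforms. The
covariance is the inverse numerical Hessian of the negative log-likelihood at
the optimum (observed information); Wald intervals are built on the
transformed scale and back-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .density import N_COEF, DensityForm, DensityModel
from .design import Mask
from .detection import DetectionParams

#: exclusion threshold: a fit with any transformed-scale SE above this is
#: treated as having "very large variance" in simulation studies
MAX_TRANSFORMED_SE = 10.0

#: gradient coefficients are optimised per hectometre (and per hm^2) so that
#: all transformed parameters are O(1) and finite-difference steps are sane
COEF_SCALE = {
    "constant": np.array([1.0]),
    "log_linear_east": np.array([1.0, 100.0]),
    "quadratic_east": np.array([1.0, 100.0, 10000.0]),
}


def pack(phi: np.ndarray, theta: DetectionParams, form: DensityForm | None = None) -> np.ndarray:
    phi = np.asarray(phi, float)
    if form is None:
        form = {1: "constant", 2: "log_linear_east", 3: "quadratic_east"}[phi.size]
    return np.concatenate(
        [phi * COEF_SCALE[form], [logit(theta.g0), np.log(theta.sigma)]]
    )


def unpack(psi: np.ndarray, form: DensityForm) -> tuple[np.ndarray, DetectionParams]:
    p = N_COEF[form]
    phi = np.asarray(psi[:p], float) / COEF_SCALE[form]
    g0 = float(expit(psi[p]))
    with np.errstate(over="ignore"):  # optimizer may probe huge log sigma
        sigma = float(np.exp(psi[p + 1]))
    # keep strictly inside the parameter domain
    g0 = min(max(g0, 1e-12), 1.0 - 1e-12)
    return phi, DetectionParams(g0=g0, sigma=max(sigma, 1e-12))


def param_names(form: DensityForm) -> list[str]:
    base = {"constant": ["b0"], "log_linear_east": ["b0", "b1"],
            "quadratic_east": ["c0", "c1", "c2"]}[form]
    return base + ["logit_g0", "log_sigma"]


@dataclass
class FitResult:
    """Maximum-likelihood fit of a density surface and detection function."""

    density_form: DensityForm
    psi_hat: np.ndarray  # transformed-scale estimates
    vcov: np.ndarray | None  # transformed-scale covariance (observed information)
    loglik: float
    converged: bool
    message: str = ""
    n_evals: int = 0
    mask: Mask | None = field(default=None, repr=False, compare=False)

    @property
    def phi_hat(self) -> np.ndarray:
        return unpack(self.psi_hat, self.density_form)[0]

    @property
    def theta_hat(self) -> DetectionParams:
        return unpack(self.psi_hat, self.density_form)[1]

    @property
    def g0_hat(self) -> float:
        return self.theta_hat.g0

    @property
    def sigma_hat(self) -> float:
        return self.theta_hat.sigma

    @property
    def names(self) -> list[str]:
        return param_names(self.density_form)

    @property
    def density_model(self) -> DensityModel:
        return DensityModel(self.density_form, self.phi_hat)

    def se_transformed(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        d = np.diag(self.vcov)
        return np.sqrt(np.where(d >= 0, d, np.nan))

    def usable(self, max_se: float = MAX_TRANSFORMED_SE) -> bool:
        """Replicate-inclusion rule for simulation studies: converged, a valid
        covariance, no negative variances, no huge transformed-scale SEs."""
        if not self.converged or self.vcov is None:
            return False
        d = np.diag(self.vcov)
        if np.any(~np.isfinite(d)) or np.any(d < 0):
            return False
        return bool(np.all(np.sqrt(d) <= max_se))

    def ci_transformed(self, index: int, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        se = self.se_transformed()
        if se is None or not np.isfinite(se[index]):
            return (np.nan, np.nan)
        lo = self.psi_hat[index] - z * se[index]
        hi = self.psi_hat[index] + z * se[index]
        return (float(lo), float(hi))

    def ci_g0(self, level: float = 0.95) -> tuple[float, float]:
        p = N_COEF[self.density_form]
        lo, hi = self.ci_transformed(p, level)
        return (float(expit(lo)), float(expit(hi)))

    def ci_sigma(self, level: float = 0.95) -> tuple[float, float]:
        p = N_COEF[self.density_form]
        lo, hi = self.ci_transformed(p + 1, level)
        return (float(np.exp(lo)), float(np.exp(hi)))

    def ci_slope(self, level: float = 0.95) -> tuple[float, float]:
        """Wald CI for the east-west gradient coefficient (log-linear form),
        on the natural per-metre scale."""
        if self.density_form != "log_linear_east":
            raise ValueError("slope CI only defined for the log-linear form")
        scale = COEF_SCALE[self.density_form][1]
        lo, hi = self.ci_transformed(1, level)
        return (lo / scale, hi / scale)


def numerical_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, step: float = 1e-4
) -> np.ndarray:
    """Central-difference Hessian on the transformed scale."""
    p = x.size
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = step
            ej[j] = step
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f(x) + f(x - ei)) / step**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * step**2)
    return H


def observed_information_vcov(
    negloglik: Callable[[np.ndarray], float], psi_hat: np.ndarray
) -> np.ndarray | None:
    """Inverse Hessian of the negative log-likelihood; wider stencils are tried
    if the first is not positive definite."""
    for step in (1e-4, 1e-3, 5e-3):
        H = numerical_hessian(negloglik, psi_hat, step=step)
        if not np.all(np.isfinite(H)):
            continue
        try:
            eigs = np.linalg.eigvalsh(H)
        except np.linalg.LinAlgError:
            continue
        if np.all(eigs > 0):
            return np.linalg.inv(H)
    return None


def maximize(
    negloglik: Callable[[np.ndarray], float],
    starts: list[np.ndarray],
    reltol: float = 1e-8,
) -> tuple[np.ndarray, float, bool, str, int]:
    """Quasi-Newton maximisation; later starts are fallbacks used only when an
    earlier one fails to converge (the likelihoods here are well-behaved, and
    alternate starts reach the same optimum when the first succeeds)."""
    best = None
    n_evals = 0
    for x0 in starts:
        res = optimize.minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            options={"ftol": reltol, "gtol": 1e-6, "maxiter": 500},
        )
        n_evals += res.nfev
        if best is None or res.fun < best.fun:
            best = res
        if best.success and np.isfinite(best.fun):
            break
    assert best is not None
    return best.x, -best.fun, bool(best.success), str(best.message), n_evals


def derived_density(
    fit: FitResult, region: Mask, level: float = 0.95
) -> dict[str, float]:
    """Mean density over a region with a delta-method SE and a log-scale Wald CI.

    D-hat is the area-weighted mean of the fitted surface over the region's
    mask points; its variance propagates the transformed-scale covariance
    through a numerical gradient.
    """
    from scipy.stats import norm

    def dbar(psi: np.ndarray) -> float:
        phi, _ = unpack(psi, fit.density_form)
        return float(
            np.mean(DensityModel(fit.density_form, phi).intensity(region.points))
        )

    est = dbar(fit.psi_hat)
    out = {"estimate": est, "se": np.nan, "lo": np.nan, "hi": np.nan}
    if fit.vcov is None:
        return out
    step = 1e-5
    grad = np.zeros(fit.psi_hat.size)
    for i in range(fit.psi_hat.size):
        e = np.zeros(fit.psi_hat.size)
        e[i] = step
        grad[i] = (dbar(fit.psi_hat + e) - dbar(fit.psi_hat - e)) / (2 * step)
    var = float(grad @ fit.vcov @ grad)
    if var < 0 or est <= 0:
        return out
    se = np.sqrt(var)
    z = norm.ppf(0.5 + level / 2)
    # Wald interval on the log scale keeps the CI positive
    se_log = se / est
    out.update(
        se=se, lo=float(est * np.exp(-z * se_log)), hi=float(est * np.exp(z * se_log))
    )
    return out
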