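"""REML variance-component estimation for the two-kinship mixed model.

The trait model is y = Xβ + ξ + ζ + e with additive effects ξ ~ N(0, K_a σa²),
pairwise-interaction effects ζ ~ N(0, K_aa σaa²) and residual e ~ N(0, I σ²),
X an intercept column.  Writing λa = σa²/σ², λaa = σaa²/σ² and
C = λa·K_a + λaa·K_aa + I, both β and σ² profile out of the restricted
likelihood, leaving a two-parameter surface

    l(λa, λaa) = −½ ln|C| − ½ ln|XᵀC⁻¹X| − ((n−r)/2)(ln σ̂² + 1),

with β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y and σ̂² = (y−Xβ̂)ᵀC⁻¹(y−Xβ̂)/(n−r), r = rank(X) = 1.
The surface is maximized by a derivative-free simplex over (ln λa, ln λaa)
from several starts, since it can be flat or multimodal near the boundary.

From the optimum: σa² = λ̂a σ̂², σaa² = λ̂aa σ̂², the variance fractions
ratio_* = σ*²/(σa²+σaa²+σ²), and broad-sense heritability
H = (σa² + σaa²)/(σa² + σaa² + σ²) — the model-explained share of
phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .datamodel import TraitVector, ValidationError
from .kinship import KinshipSet

__all__ = [
    "VarianceComponents",
    "RemlOptions",
    "restricted_loglik",
    "estimate_variance_components",
    "heritability",
]

#: λ values at/below this bound are reported as exactly 0 with a boundary flag
LAMBDA_FLOOR = 1e-6
LAMBDA_CEIL = 1e6

DEFAULT_RESTARTS = ((0.01, 0.01), (1.0, 1.0), (10.0, 0.1), (0.1, 10.0),
                    (5.0, 5.0))


class ConvergenceError(RuntimeError):
    """No optimizer restart converged; carries the best point found."""

    def __init__(self, msg, best=None):
        super().__init__(msg)
        self.best = best


@dataclass
class RemlOptions:
    restarts: tuple = DEFAULT_RESTARTS
    maxiter: int = 400
    tol: float = 1e-9          # simplex tolerance on the log-likelihood


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_aa: float
    sigma2_e: float
    lambda_a: float
    lambda_aa: float
    loglik: float
    converged: bool
    n_restarts_used: int = 0
    boundary_a: bool = False
    boundary_aa: bool = False

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_aa + self.sigma2_e

    @property
    def ratio_a(self) -> float:
        return self.sigma2_a / self.total

    @property
    def ratio_aa(self) -> float:
        return self.sigma2_aa / self.total

    @property
    def ratio_e(self) -> float:
        return self.sigma2_e / self.total

    @property
    def H(self) -> float:
        return heritability(self.sigma2_a, self.sigma2_aa, self.sigma2_e)

    def as_dict(self) -> dict[str, float]:
        return {"sigma2_a": self.sigma2_a, "sigma2_aa": self.sigma2_aa,
                "sigma2_e": self.sigma2_e, "lambda_a": self.lambda_a,
                "lambda_aa": self.lambda_aa, "ratio_a": self.ratio_a,
                "ratio_aa": self.ratio_aa, "ratio_e": self.ratio_e,
                "H": self.H}


def heritability(sigma2_a: float, sigma2_aa: float, sigma2_e: float) -> float:
    """Broad-sense heritability H = (σa² + σaa²)/(σa² + σaa² + σ²).

    Scale-invariant: multiplying all three components by a positive
    constant leaves H unchanged.
    """
    total = sigma2_a + sigma2_aa + sigma2_e
    if total <= 0:
        raise ValidationError("all variance components are zero")
    return (sigma2_a + sigma2_aa) / total


def restricted_loglik(lambda_a: float, lambda_aa: float, y: TraitVector,
                      K: KinshipSet) -> tuple[float, float, float]:
    """Profiled restricted log-likelihood at fixed variance ratios.

    Returns ``(loglik, sigma2_profiled, beta_profiled)``.  The intercept is
    the only fixed effect, so adding a constant to y shifts β̂ but leaves
    the likelihood untouched.
    """
    if lambda_a < 0 or lambda_aa < 0:
        raise ValidationError("variance ratios must be non-negative")
    yv = y.values
    n = yv.shape[0]
    if K.n != n:
        raise ValidationError("trait and kinships have different n; align first")
    C = K.hmat(lambda_a, lambda_aa)
    C[np.diag_indices_from(C)] += 1.0
    try:
        cho = linalg.cho_factor(C, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(C)
        raise ValidationError(
            f"covariance numerically singular (cond ~ {cond:.3g})") from exc
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    X = np.ones(n)
    Ci_y = linalg.cho_solve(cho, yv, check_finite=False)
    Ci_X = linalg.cho_solve(cho, X, check_finite=False)
    xtcx = float(X @ Ci_X)
    beta = float(X @ Ci_y) / xtcx
    r = yv - beta            # X is the unity vector
    Ci_r = Ci_y - beta * Ci_X
    df = n - 1               # r(X) = 1, intercept only
    sigma2 = float(r @ Ci_r) / df
    if sigma2 <= 0 or not np.isfinite(sigma2):
        raise ValidationError("profiled residual variance is not positive")
    loglik = (-0.5 * logdet_C - 0.5 * np.log(xtcx)
              - 0.5 * df * np.log(sigma2) - 0.5 * df)
    return float(loglik), sigma2, beta


def estimate_variance_components(y: TraitVector, K: KinshipSet,
                                 opts: RemlOptions | None = None
                                 ) -> VarianceComponents:
    """Maximize the restricted likelihood over (λa, λaa) and unpack the
    three variance components.

    The search runs over (ln λa, ln λaa) with λ clipped to
    [1e−6, 1e6]; estimates landing on the lower box edge are reported as
    exactly 0 with a boundary flag.
    """
    opts = opts or RemlOptions()

    def negll(u: np.ndarray) -> float:
        lam = np.clip(np.exp(u), LAMBDA_FLOOR, LAMBDA_CEIL)
        try:
            ll, _, _ = restricted_loglik(lam[0], lam[1], y, K)
        except ValidationError:
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    best = None
    n_used = 0
    any_converged = False
    for start in opts.restarts:
        n_used += 1
        res = optimize.minimize(
            negll, np.log(np.asarray(start, dtype=float)),
            method="Nelder-Mead",
            options={"maxiter": opts.maxiter, "fatol": opts.tol,
                     "xatol": 1e-7})
        if not np.isfinite(res.fun):
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("restricted likelihood non-finite at every "
                               "restart", best=best)
    lam = np.clip(np.exp(best.x), LAMBDA_FLOOR, LAMBDA_CEIL)
    if not any_converged:
        raise ConvergenceError(
            f"no optimizer restart converged; best point λ=({lam[0]:.4g}, "
            f"{lam[1]:.4g}) with loglik {-best.fun:.6g}", best=best)
    ll, sigma2, _beta = restricted_loglik(lam[0], lam[1], y, K)
    boundary_a = lam[0] <= LAMBDA_FLOOR * (1 + 1e-9)
    boundary_aa = lam[1] <= LAMBDA_FLOOR * (1 + 1e-9)
    lambda_a = 0.0 if boundary_a else float(lam[0])
    lambda_aa = 0.0 if boundary_aa else float(lam[1])
    return VarianceComponents(
        sigma2_a=lambda_a * sigma2,
        sigma2_aa=lambda_aa * sigma2,
        sigma2_e=sigma2,
        lambda_a=lambda_a,
        lambda_aa=lambda_aa,
        loglik=ll,
        converged=True,
        n_restarts_used=n_used,
        boundary_a=boundary_a,
        boundary_aa=boundary_aa,
    )
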