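"""Leave-one-out predictability of intermediate omic markers from genotypes.

Each transcript or metabolite is treated as an intermediate quantitative
trait w and regressed on the genotype-derived kinships under the same
two-component mixed model.  Its predictability is the cross-validated

    PRED = R² = 1 − PRESS/SS,

where SS is the total sum of squares of w and PRESS the predicted residual
error sum of squares.  Rather than n refits, PRESS comes from the hat
(smoother) matrix: with C = H + I, H = λa·K_a + λaa·K_aa and
Px = X(XᵀC⁻¹X)⁻¹XᵀC⁻¹ the GLS projector onto the intercept, the fitted
values ŵ = S·w use the BLUP-inclusive smoother

    S = Px + H C⁻¹ (I − Px),

and the leave-one-out residuals are the leverage-corrected
r_i = (w_i − ŵ_i)/(1 − S_ii), giving PRESS = Σ r_i².  For a fixed
covariance this reproduces explicit leave-one-out refits exactly.
PRED can be negative for markers predicted worse than their mean; it is
reported as-is, never clamped.

A threshold sweep rebuilds the trait-level kinships from the markers with
PRED ≥ t and traces broad-sense heritability H of the downstream trait as
the marker panel shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .datamodel import MarkerMatrix, TraitVector, ValidationError
from .kinship import KinshipSet, compute_kinships
from .reml import RemlOptions, VarianceComponents, estimate_variance_components

__all__ = [
    "PredictabilityResult",
    "press_r2",
    "predictability_scan",
    "pred_threshold_curve",
]

LEVERAGE_TOL = 1e-10


@dataclass
class PredictabilityResult:
    marker_id: str
    pred: float
    press: float
    ss: float

    def __post_init__(self) -> None:
        assert abs(self.pred - (1.0 - self.press / self.ss)) <= 1e-12 * max(
            1.0, abs(self.pred))


def _smoother(K: KinshipSet, lambda_a: float, lambda_aa: float,
              blup: bool = True) -> np.ndarray:
    n = K.n
    H = K.hmat(lambda_a, lambda_aa)
    C = H + np.eye(n)
    Cinv = linalg.inv(C)
    X = np.ones((n, 1))
    XtCi = X.T @ Cinv
    Px = X @ (XtCi / float((XtCi @ X).item()))
    if not blup:
        return Px
    return Px + H @ Cinv @ (np.eye(n) - Px)


def press_r2(w: TraitVector, K_geno: KinshipSet, *,
             lambdas: tuple[float, float] | None = None,
             additive_only: bool = False,
             smoother: str = "blup",
             reml_opts: RemlOptions | None = None) -> PredictabilityResult:
    """HAT-method leave-one-out R² of one omic marker from genotypes.

    Variance ratios are re-estimated by REML for this marker unless
    ``lambdas`` pins them (the fast, approximate mode).  ``additive_only``
    drops the epistatic kinship from the model.  ``smoother`` selects the
    BLUP-inclusive hat matrix (default) or the fixed-effect-only projector
    (``"fixed"``).
    """
    if w.n != K_geno.n:
        raise ValidationError("marker-trait and kinships have different n")
    if lambdas is None:
        vc = estimate_variance_components(w, K_geno, reml_opts)
        lam_a, lam_aa = vc.lambda_a, vc.lambda_aa
    else:
        lam_a, lam_aa = float(lambdas[0]), float(lambdas[1])
    if additive_only:
        lam_aa = 0.0
    S = _smoother(K_geno, lam_a, lam_aa, blup=(smoother == "blup"))
    diag = np.diag(S)
    if np.any(diag >= 1.0 - LEVERAGE_TOL):
        raise ValidationError("degenerate leverage: smoother diagonal at 1")
    wv = w.values
    resid = (wv - S @ wv) / (1.0 - diag)
    press = float(resid @ resid)
    ss = float(np.sum((wv - wv.mean()) ** 2))
    if ss <= 0:
        raise ValidationError("constant marker: zero total sum of squares")
    return PredictabilityResult(w.trait_name, 1.0 - press / ss, press, ss)


def predictability_scan(Zomic: MarkerMatrix, K_geno: KinshipSet, *,
                        lambdas: tuple[float, float] | None = None,
                        additive_only: bool = False,
                        reml_opts: RemlOptions | None = None) -> pd.DataFrame:
    """PRED for every row of an omic panel; columns marker_id,pred,press,ss."""
    rows = []
    for i, mid in enumerate(Zomic.marker_ids):
        w = TraitVector(Zomic.values[i], Zomic.individual_ids, mid)
        r = press_r2(w, K_geno, lambdas=lambdas, additive_only=additive_only,
                     reml_opts=reml_opts)
        rows.append((mid, r.pred, r.press, r.ss))
    return pd.DataFrame(rows, columns=["marker_id", "pred", "press", "ss"])


def pred_threshold_curve(Zomic: MarkerMatrix, preds: pd.DataFrame,
                         y: TraitVector, thresholds,
                         reml_opts: RemlOptions | None = None) -> pd.DataFrame:
    """Broad-sense heritability of the trait as the omic panel is restricted
    to markers with PRED ≥ t, for each threshold t.

    Returns a ``threshold,n_selected,H`` table; thresholds keeping fewer
    than 2 markers get ``H = NaN`` (curve point unavailable).  ``n_selected``
    is non-increasing as the threshold grows.
    """
    lookup = dict(zip(preds["marker_id"], preds["pred"]))
    missing = [m for m in Zomic.marker_ids if m not in lookup]
    if missing:
        raise ValidationError(
            f"predictability missing for {len(missing)} markers "
            f"(first: {missing[0]!r})")
    rows = []
    for t in thresholds:
        keep = [m for m in Zomic.marker_ids if lookup[m] >= t]
        if len(keep) < 2:
            rows.append((float(t), len(keep), np.nan))
            continue
        sub = Zomic.select_markers(keep)
        K = compute_kinships(sub)
        vc = estimate_variance_components(y, K, reml_opts)
        rows.append((float(t), len(keep), vc.H))
    return pd.DataFrame(rows, columns=["threshold", "n_selected", "H"])
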