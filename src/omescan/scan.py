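"""1D per-marker and 2D per-pair association scans by generalized least
squares with Wald tests.

After REML the variance ratios (λa, λaa) are frozen, making every
single-marker (model I: y = Xβ + Z_i a_i + e) and marker-pair fit
(model II: y = Xβ + Z_i a_i + Z_j a_j + W_ij γ_ij + e, W_ij = Z_i∗Z_j)
a fixed-effects GLS problem under the common covariance
V = (H + I)σ² with H = λa·K_a + λaa·K_aa.  One eigen-decomposition
H = U diag(δ) Uᵀ turns every fit into a diagonally weighted least squares:
with P* = UᵀP, y* = Uᵀy and weights w_i = 1/(δ_i+1),

    b̂ = (P*ᵀWP*)⁻¹ P*ᵀW y*,  σ̂² = (y*−P*b̂)ᵀW(y*−P*b̂)/(n−r(P)),
    var(b̂) = (P*ᵀWP*)⁻¹ σ̂².

The Wald statistic for the tested coefficient (â_i in model I, γ̂_ij in
model II) is its squared estimate over its variance, referred to χ²₁:
p = 1 − Pr(χ²₁ < Wald).  p-values are floored at 1e−300 before taking
−log10 so the significance scale stays finite.

The 2D scan walks pairs in row-major i<j order in chunks; chunking is a
pure partition of the pair list, so results are identical for any chunk
size.  Dense all-pairs output is allowed up to ``DENSE_PAIR_CAP`` markers;
beyond that a storage threshold on −log10(p) is mandatory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MarkerMatrix, TraitVector, ValidationError
from .kinship import KinshipSet
from .reml import VarianceComponents

__all__ = [
    "EigenContext",
    "ScanResult1D",
    "ScanResult2D",
    "build_eigen_context",
    "fit_gls",
    "scan_1d",
    "scan_2d",
    "conditional_slice",
    "threshold_pairs",
]

P_FLOOR = 1e-300
#: condition-number cutoff above which a design is declared singular
COND_MAX = 1e12
#: markers beyond which dense all-pairs storage is refused
DENSE_PAIR_CAP = 2000

STATUS_OK = "ok"
STATUS_SINGULAR = "singular"


@dataclass
class EigenContext:
    """One-time eigen-decomposition of the polygenic covariance core."""

    U: np.ndarray          # n×n orthogonal eigenvectors
    delta: np.ndarray      # n eigenvalues of H
    wdiag: np.ndarray      # 1/(δ_i + 1), all in (0, 1]
    y_star: np.ndarray     # Uᵀy
    lambda_a: float
    lambda_aa: float
    individual_ids: list[str]

    @property
    def n(self) -> int:
        return self.U.shape[0]


@dataclass
class ScanResult1D:
    """Per-marker additive-effect scan table.

    Columns: marker_id, effect, var_effect, wald, p, neglog10p, status.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ScanResult2D:
    """Per-pair interaction-effect scan table (pairs stored with i<j only;
    p(i,j) = p(j,i) by construction since W_ij = W_ji).

    Columns: marker_i, marker_j, gamma, var_gamma, wald, p, neglog10p,
    status.  ``store_threshold`` records the −log10(p) cutoff applied at
    scan time (None for dense output).
    """

    table: pd.DataFrame
    marker_ids: list[str]
    store_threshold: float | None = None

    def __len__(self) -> int:
        return len(self.table)


def _neglog10(p: np.ndarray) -> np.ndarray:
    return -np.log10(np.maximum(p, P_FLOOR))


def build_eigen_context(K: KinshipSet, vc: VarianceComponents,
                        y: TraitVector) -> EigenContext:
    """Decompose H = λa·K_a + λaa·K_aa once and transform the trait."""
    if K.n != y.n:
        raise ValidationError("trait and kinships have different n; align first")
    H = K.hmat(vc.lambda_a, vc.lambda_aa)
    delta, U = np.linalg.eigh(H)
    scale = max(float(delta[-1]), 1.0)
    if delta[0] < -1e-8 * scale:
        raise ValidationError(
            f"polygenic covariance core has negative eigenvalue {delta[0]:.3g}; "
            "kinships are not PSD")
    delta = np.maximum(delta, 0.0)
    return EigenContext(U=U, delta=delta, wdiag=1.0 / (delta + 1.0),
                        y_star=U.T @ y.values,
                        lambda_a=float(vc.lambda_a),
                        lambda_aa=float(vc.lambda_aa),
                        individual_ids=list(y.individual_ids))


def fit_gls(P: np.ndarray, ec: EigenContext):
    """Weighted least squares for one design in the eigen-rotated basis.

    ``P`` is the n×2 (model I) or n×4 (model II) design in the original
    basis, intercept first.  Returns ``(b_hat, var_b, sigma2_hat, status)``;
    on a rank-deficient design the status is ``"singular"`` and the
    coefficient outputs are None.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.shape[1] not in (2, 4):
        raise ValidationError("design must have 2 or 4 columns")
    Pstar = ec.U.T @ P
    return _fit_rotated(Pstar, ec.wdiag, ec.y_star)


def _fit_rotated(Pstar: np.ndarray, wdiag: np.ndarray, y_star: np.ndarray):
    n, r = Pstar.shape
    WP = Pstar * wdiag[:, None]
    A = Pstar.T @ WP
    if not np.all(np.isfinite(A)) or np.linalg.cond(A) > COND_MAX:
        return None, None, None, STATUS_SINGULAR
    Ainv = np.linalg.inv(A)
    b = Ainv @ (WP.T @ y_star)
    resid = y_star - Pstar @ b
    sigma2 = float(resid @ (wdiag * resid)) / (n - r)
    var_b = Ainv * sigma2
    return b, var_b, sigma2, STATUS_OK


def _wald_p(est: float, var: float) -> tuple[float, float]:
    wald = est * est / var
    return wald, float(stats.chi2.sf(wald, df=1))


def scan_1d(Z: MarkerMatrix, ec: EigenContext) -> ScanResult1D:
    """Model-I scan: one Wald test of H0: a_i = 0 per marker, in input
    marker order.  Constant markers yield a ``singular`` row; the scan
    continues."""
    if Z.individual_ids != ec.individual_ids:
        raise ValidationError("marker panel not aligned with eigen context")
    ones_star = ec.U.T @ np.ones(ec.n)
    Zstar = Z.values @ ec.U           # row i = Uᵀ Z_i
    rows = []
    for i, mid in enumerate(Z.marker_ids):
        Pstar = np.column_stack([ones_star, Zstar[i]])
        b, var_b, _s2, status = _fit_rotated(Pstar, ec.wdiag, ec.y_star)
        if status != STATUS_OK:
            rows.append((mid, np.nan, np.nan, np.nan, np.nan, np.nan,
                         STATUS_SINGULAR))
            continue
        wald, p = _wald_p(b[1], var_b[1, 1])
        rows.append((mid, b[1], var_b[1, 1], wald, p,
                     float(_neglog10(np.array([p]))[0]), STATUS_OK))
    table = pd.DataFrame(rows, columns=["marker_id", "effect", "var_effect",
                                        "wald", "p", "neglog10p", "status"])
    return ScanResult1D(table)


def _iter_pair_chunks(pairs: np.ndarray, chunk_size: int):
    for k in range(0, len(pairs), chunk_size):
        yield pairs[k:k + chunk_size]


def all_pairs(m: int) -> np.ndarray:
    """Row-major i<j pair enumeration (the canonical pair order)."""
    iu = np.triu_indices(m, k=1)
    return np.column_stack(iu)


def scan_2d(Z: MarkerMatrix, ec: EigenContext, *, chunk_size: int = 2048,
            store_threshold: float | None = None,
            pair_subset: np.ndarray | None = None) -> ScanResult2D:
    """Model-II scan: one Wald test of H0: γ_ij = 0 per marker pair.

    Pairs run in row-major i<j order; ``chunk_size`` only controls the
    working-set size and never changes the output.  With
    ``store_threshold`` set, only rows with −log10(p) at or above it are
    materialized (singular rows are dropped too); dense output requires
    m ≤ 2000.  ``pair_subset`` restricts the scan to an explicit (k, 2)
    index array.
    """
    if Z.individual_ids != ec.individual_ids:
        raise ValidationError("marker panel not aligned with eigen context")
    m = Z.m
    if m < 2:
        raise ValidationError("no marker pairs: need at least 2 markers")
    if chunk_size < 1:
        raise ValidationError("chunk_size must be positive")
    if pair_subset is None:
        if store_threshold is None and m > DENSE_PAIR_CAP:
            raise ValidationError(
                f"dense all-pairs output refused for m={m} > {DENSE_PAIR_CAP}; "
                "set store_threshold")
        pairs = all_pairs(m)
    else:
        pairs = np.asarray(pair_subset, dtype=int)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValidationError("pair_subset must be a (k, 2) index array")
        if np.any(pairs[:, 0] >= pairs[:, 1]) or np.any(pairs < 0) \
                or np.any(pairs >= m):
            raise ValidationError("pair_subset entries must satisfy 0 <= i < j < m")

    ones_star = ec.U.T @ np.ones(ec.n)
    Zv = Z.values
    Zstar = Zv @ ec.U
    out = []
    for chunk in _iter_pair_chunks(pairs, chunk_size):
        # pair design columns W_ij live in the original basis; rotate en bloc
        Wchunk = Zv[chunk[:, 0]] * Zv[chunk[:, 1]]
        Wstar = Wchunk @ ec.U
        for k, (i, j) in enumerate(chunk):
            Pstar = np.column_stack([ones_star, Zstar[i], Zstar[j], Wstar[k]])
            b, var_b, _s2, status = _fit_rotated(Pstar, ec.wdiag, ec.y_star)
            if status != STATUS_OK:
                if store_threshold is None:
                    out.append((Z.marker_ids[i], Z.marker_ids[j], np.nan,
                                np.nan, np.nan, np.nan, np.nan,
                                STATUS_SINGULAR))
                continue
            wald, p = _wald_p(b[3], var_b[3, 3])
            nlp = float(_neglog10(np.array([p]))[0])
            if store_threshold is not None and nlp < store_threshold:
                continue
            out.append((Z.marker_ids[i], Z.marker_ids[j], b[3], var_b[3, 3],
                        wald, p, nlp, STATUS_OK))
    table = pd.DataFrame(out, columns=["marker_i", "marker_j", "gamma",
                                       "var_gamma", "wald", "p", "neglog10p",
                                       "status"])
    return ScanResult2D(table, list(Z.marker_ids),
                        store_threshold=store_threshold)


def conditional_slice(res: ScanResult2D, marker_id: str) -> pd.DataFrame:
    """The conditional 1D association profile of one marker: every stored
    pair significance involving it, ordered by partner marker index.

    Columns mirror a 1D scan (partner_id, gamma, var_gamma, wald, p,
    neglog10p, status).
    """
    if marker_id not in res.marker_ids:
        raise KeyError(f"unknown marker id: {marker_id!r}")
    t = res.table
    hit = t[(t["marker_i"] == marker_id) | (t["marker_j"] == marker_id)].copy()
    hit["partner_id"] = np.where(hit["marker_i"] == marker_id,
                                 hit["marker_j"], hit["marker_i"])
    order = {mid: k for k, mid in enumerate(res.marker_ids)}
    hit["_pos"] = hit["partner_id"].map(order)
    hit = hit.sort_values("_pos", kind="stable")
    cols = ["partner_id", "gamma", "var_gamma", "wald", "p", "neglog10p",
            "status"]
    return hit[cols].reset_index(drop=True)


def threshold_pairs(res: ScanResult2D, th: float) -> pd.DataFrame:
    """Significant pairs at −log10(p) ≥ th, most significant first; ties
    break by (marker_i index, marker_j index).  Singular rows never pass."""
    if th < 0:
        raise ValidationError("threshold must be non-negative")
    t = res.table
    keep = t[(t["status"] == STATUS_OK) & (t["neglog10p"] >= th)].copy()
    order = {mid: k for k, mid in enumerate(res.marker_ids)}
    keep["_i"] = keep["marker_i"].map(order)
    keep["_j"] = keep["marker_j"].map(order)
    keep = keep.sort_values(["neglog10p", "_i", "_j"],
                            ascending=[False, True, True], kind="stable")
    return keep.drop(columns=["_i", "_j"]).reset_index(drop=True)
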