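"""Additive and epistatic kinship matrices.

With Z the m x n marker panel and Z_i the length-n vector of marker i
across individuals, the additive relationship is

    K_a  = (1/d_a)  sum_i Z_i Z_i^T,          d_a  = tr(sum_i Z_i Z_i^T)/n

and the additive-by-additive (epistatic) relationship is built from the
elementwise products W_ij = Z_i * Z_j over all marker pairs i < j:

    K_aa = (1/d_aa) sum_{i<j} W_ij W_ij^T,    d_aa = tr(...)/n.

The trace normalizers keep the diagonals near unity (trace equals n
exactly).  The pair sum is never formed pairwise: with G = Z^T Z and
S_kl = sum_i Z_ik^2 Z_il^2 it collapses to (G∘G − S)/2, an O(m n^2)
computation that handles tens of thousands of markers.  The literal
double-loop version is kept as a cross-checking oracle for small panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MarkerMatrix, ValidationError

__all__ = [
    "KinshipSet",
    "kinship_additive",
    "kinship_epistatic",
    "kinship_epistatic_bruteforce",
    "compute_kinships",
]


class DegenerateInputError(ValidationError):
    """Marker panel carries no usable signal (e.g. all-zero matrix)."""


@dataclass
class KinshipSet:
    """Trace-normalized additive and epistatic kinships for one panel."""

    K_a: np.ndarray
    K_aa: np.ndarray
    d_a: float
    d_aa: float
    individual_ids: list[str]

    @property
    def n(self) -> int:
        return self.K_a.shape[0]

    def hmat(self, lambda_a: float, lambda_aa: float) -> np.ndarray:
        """Polygenic covariance core λa·K_a + λaa·K_aa (the matrix that,
        plus the identity and times σ², is var(y))."""
        return lambda_a * self.K_a + lambda_aa * self.K_aa

    def validate(self, sym_tol: float = 1e-10, psd_tol: float = 1e-8,
                 trace_tol: float = 1e-8) -> None:
        n = self.n
        for name, M in (("K_a", self.K_a), ("K_aa", self.K_aa)):
            if not np.allclose(M, M.T, atol=sym_tol, rtol=0):
                raise ValidationError(f"{name} is not symmetric")
            ev = np.linalg.eigvalsh(M)
            if ev[0] < -psd_tol * max(ev[-1], 1.0):
                raise ValidationError(f"{name} is not positive semidefinite")
            if abs(np.trace(M) - n) > trace_tol * n:
                raise ValidationError(f"trace({name}) != n")

    def permuted(self, order: np.ndarray) -> "KinshipSet":
        order = np.asarray(order)
        return KinshipSet(self.K_a[np.ix_(order, order)],
                          self.K_aa[np.ix_(order, order)],
                          self.d_a, self.d_aa,
                          [self.individual_ids[i] for i in order])


def kinship_additive(Z: MarkerMatrix) -> tuple[np.ndarray, float]:
    """Additive kinship and its trace normalizer."""
    G = Z.values.T @ Z.values
    d_a = float(np.trace(G)) / Z.n
    if d_a <= 0:
        raise DegenerateInputError("additive normalizer d_a is zero "
                                   "(all-zero marker matrix?)")
    K_a = G / d_a
    return 0.5 * (K_a + K_a.T), d_a


def _pair_sum_closed_form(Zv: np.ndarray) -> np.ndarray:
    # sum_{i<j} (Z_i*Z_j)(Z_i*Z_j)^T elementwise is (G_kl^2 - S_kl)/2
    G = Zv.T @ Zv
    Z2 = Zv * Zv
    S = Z2.T @ Z2
    return 0.5 * (G * G - S)


def kinship_epistatic(Z: MarkerMatrix) -> tuple[np.ndarray, float]:
    """Epistatic kinship via the O(m·n²) closed form."""
    if Z.m < 2:
        raise ValidationError("no marker pairs: need at least 2 markers")
    E = _pair_sum_closed_form(Z.values)
    d_aa = float(np.trace(E)) / Z.n
    if d_aa <= 0:
        raise DegenerateInputError("epistatic normalizer d_aa is zero")
    K_aa = E / d_aa
    return 0.5 * (K_aa + K_aa.T), d_aa


def kinship_epistatic_bruteforce(Z: MarkerMatrix) -> tuple[np.ndarray, float]:
    """Literal double-sum over marker pairs; test oracle for small m."""
    if Z.m < 2:
        raise ValidationError("no marker pairs: need at least 2 markers")
    Zv = Z.values
    E = np.zeros((Z.n, Z.n))
    for i in range(Z.m - 1):
        for j in range(i + 1, Z.m):
            w = Zv[i] * Zv[j]
            E += np.outer(w, w)
    d_aa = float(np.trace(E)) / Z.n
    if d_aa <= 0:
        raise DegenerateInputError("epistatic normalizer d_aa is zero")
    return E / d_aa, d_aa


def compute_kinships(Z: MarkerMatrix) -> KinshipSet:
    """Both kinships for one panel, ready for variance-component analysis."""
    K_a, d_a = kinship_additive(Z)
    K_aa, d_aa = kinship_epistatic(Z)
    return KinshipSet(K_a, K_aa, d_a, d_aa, list(Z.individual_ids))
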