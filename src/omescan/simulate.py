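"""Synthetic data with the statistical structure the model assumes.

Three generators make the full pipeline testable end to end with known
ground truth:

* RIL-like genotypes: each individual's chromosome is a two-state
  {−1, +1} Markov chain along marker order with transition probability
  ``switch_prob``, which creates linkage-disequilibrium blocks of mean
  length 1/switch_prob markers — the structure of genotype bins in a
  recombinant inbred population (near-homozygous lines, two-state
  markers);
* quantitative omic markers: per-marker standardized Gaussian rows with
  optional within-block correlation, emulating log2 expression or log2
  abundance panels;
* traits: y = β + Σ Z_i a_i + Σ_{i<j} W_ij γ_ij + e with a_i, γ_ij and
  e drawn from zero-mean normals on randomly chosen causal sets.  By
  default each of the three components is rescaled so its empirical
  variance hits the requested target exactly — recovery tests need
  controlled truth — and everything drawn is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MarkerMatrix, TraitVector, ValidationError

__all__ = [
    "SimulationTruth",
    "simulate_ril_genotypes",
    "simulate_quantitative_markers",
    "simulate_trait",
]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated trait: the effects exactly as used."""

    additive_effects: dict[str, float]
    interaction_effects: dict[tuple[str, str], float]
    sigma2_e: float
    beta: float
    realized_ratios: tuple[float, float, float]

    def __post_init__(self) -> None:
        assert abs(sum(self.realized_ratios) - 1.0) < 1e-9


def simulate_ril_genotypes(n: int, m: int, n_chrom: int = 12,
                           switch_prob: float = 0.02, seed=0
                           ) -> MarkerMatrix:
    """{−1, +1} genotype bins with LD blocks along each chromosome.

    Markers split as evenly as possible over ``n_chrom`` chromosomes; the
    chain restarts at each chromosome, so markers on different chromosomes
    are independent.  Chromosome and position metadata are attached.

    Defaults emulate a rice-style RIL bin map: 12 chromosomes and a small
    between-bin switch probability, since bins sit between recombination
    breakpoints and neighbouring bins are strongly correlated (expected
    run length 1/switch_prob bins).
    """
    if n < 2 or m < 1 or n_chrom < 1 or n_chrom > m:
        raise ValidationError("invalid dimensions for genotype simulation")
    if not 0.0 < switch_prob < 1.0:
        raise ValidationError("switch_prob must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_chrom, m // n_chrom)
    sizes[: m % n_chrom] += 1
    cols = []
    chrom_labels = []
    pos_labels = []
    for c, size in enumerate(sizes):
        start = rng.choice([-1.0, 1.0], size=n)
        block = np.empty((size, n))
        block[0] = start
        flips = rng.random((size - 1, n)) < switch_prob if size > 1 else None
        for k in range(1, size):
            block[k] = np.where(flips[k - 1], -block[k - 1], block[k - 1])
        cols.append(block)
        chrom_labels += [f"chr{c + 1}"] * size
        pos_labels += list(range(size))
    values = np.vstack(cols)
    marker_ids = [f"G_{k + 1}" for k in range(m)]
    meta = pd.DataFrame({"chromosome": chrom_labels,
                         "position_index": pos_labels},
                        index=marker_ids)
    return MarkerMatrix(values, marker_ids,
                        [f"RIL_{k + 1}" for k in range(n)], meta)


def simulate_quantitative_markers(n: int, m: int,
                                  block_size: int | None = None,
                                  block_rho: float = 0.0,
                                  seed: int = 0) -> MarkerMatrix:
    """Standardized Gaussian omic panel, optionally correlated in blocks.

    With ``block_size`` set, markers within consecutive blocks share a
    latent factor giving pairwise correlation ``block_rho``; rows are then
    standardized to zero mean, unit variance (ddof=1).
    """
    if n < 3 or m < 1:
        raise ValidationError("invalid dimensions for marker simulation")
    if not 0.0 <= block_rho < 1.0:
        raise ValidationError("block_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((m, n))
    if block_size and block_rho > 0:
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            shared = rng.standard_normal(n)
            X[start:stop] = (np.sqrt(block_rho) * shared
                             + np.sqrt(1 - block_rho) * X[start:stop])
    X -= X.mean(axis=1, keepdims=True)
    X /= X.std(axis=1, ddof=1, keepdims=True)
    return MarkerMatrix(X, [f"Q_{k + 1}" for k in range(m)],
                        [f"S_{k + 1}" for k in range(n)])


def _rescale(component: np.ndarray, target: float) -> tuple[np.ndarray, float]:
    v = float(np.var(component, ddof=1))
    if target <= 0 or v <= 0:
        return np.zeros_like(component), 0.0
    s = np.sqrt(target / v)
    return component * s, s


def simulate_trait(Z: MarkerMatrix, sigma2_a: float = 0.4,
                   sigma2_aa: float = 0.3, sigma2_e: float = 0.3,
                   n_causal_add: int | None = None,
                   n_causal_pairs: int | None = None,
                   beta: float = 0.0, seed: int = 0,
                   scale_to_target: bool = True
                   ) -> tuple[TraitVector, SimulationTruth]:
    """Trait under the additive + pairwise-interaction generative model.

    Causal markers and pairs are drawn uniformly (default: every marker
    and every pair, matching the model's exchangeable random-effect
    reading); effects come from N(0, σa²/k) and
    N(0, σaa²/k'), residuals from N(0, σe²).  With ``scale_to_target``
    each component is rescaled so its empirical variance equals the target
    exactly; the recorded effects are the rescaled ones actually used.
    """
    if sigma2_a < 0 or sigma2_aa < 0 or sigma2_e < 0:
        raise ValidationError("variance targets must be non-negative")
    if sigma2_a + sigma2_aa + sigma2_e <= 0:
        raise ValidationError("all variance targets are zero")
    rng = np.random.default_rng(seed)
    m, n = Z.m, Z.n
    Zv = Z.values
    if n_causal_add is None:
        n_causal_add = m
    n_pairs_all = m * (m - 1) // 2
    if n_causal_pairs is None:
        n_causal_pairs = n_pairs_all
    if n_causal_add > m or n_causal_pairs > n_pairs_all:
        raise ValidationError("more causal terms requested than available")

    add_idx = np.sort(rng.choice(m, size=n_causal_add, replace=False)) \
        if n_causal_add else np.empty(0, dtype=int)
    a = rng.normal(0.0, np.sqrt(sigma2_a / max(n_causal_add, 1)),
                   size=n_causal_add)
    A = a @ Zv[add_idx] if n_causal_add else np.zeros(n)

    if n_causal_pairs:
        flat = rng.choice(n_pairs_all, size=n_causal_pairs, replace=False)
        iu = np.triu_indices(m, k=1)
        pi, pj = iu[0][flat], iu[1][flat]
        g = rng.normal(0.0, np.sqrt(sigma2_aa / n_causal_pairs),
                       size=n_causal_pairs)
        E = g @ (Zv[pi] * Zv[pj])
    else:
        pi = pj = np.empty(0, dtype=int)
        g = np.empty(0)
        E = np.zeros(n)

    e = rng.normal(0.0, np.sqrt(sigma2_e) if sigma2_e > 0 else 0.0, size=n)

    if scale_to_target:
        A, sa = _rescale(A, sigma2_a) if n_causal_add else (A, 0.0)
        E, sg = _rescale(E, sigma2_aa) if n_causal_pairs else (E, 0.0)
        e, _ = _rescale(e, sigma2_e) if sigma2_e > 0 else (e * 0, 0.0)
        a = a * sa
        g = g * sg

    y = beta + A + E + e
    comp_vars = np.array([np.var(A, ddof=1), np.var(E, ddof=1),
                          np.var(e, ddof=1)])
    if comp_vars.sum() <= 0:
        raise ValidationError(
            "degenerate trait: constant y = intercept (no causal effects "
            "and no residual variance)")
    ratios = tuple(comp_vars / comp_vars.sum())
    truth = SimulationTruth(
        additive_effects={Z.marker_ids[i]: float(v)
                          for i, v in zip(add_idx, a)},
        interaction_effects={(Z.marker_ids[i], Z.marker_ids[j]): float(v)
                             for i, j, v in zip(pi, pj, g)},
        sigma2_e=float(np.var(e, ddof=1)),
        beta=float(beta),
        realized_ratios=ratios,
    )
    return TraitVector(y, list(Z.individual_ids), "sim_trait"), truth
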