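"""Core data containers for ome-wide association mapping.

A marker panel is stored marker-by-individual: rows are omic markers
(genotype bins coded numerically, log2 transcript expression, or log2
metabolite abundance), columns are individuals.  The trait is a plain
per-individual vector.  Both carry explicit identifiers so that sample
alignment is always by id, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "TraitVector",
    "BinMap",
    "ValidationError",
    "align_samples",
]

#: tissue labels accepted in marker metadata
TISSUES = ("leaf", "seed", "other")


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicate ids, missing
    values, degenerate dimensions)."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class MarkerMatrix:
    """An m-marker x n-individual numeric panel.

    Parameters
    ----------
    values
        Real matrix of shape (m, n); no missing values allowed.
    marker_ids, individual_ids
        Unique identifiers for rows and columns.
    meta
        Optional per-marker metadata indexed by marker id, with any of the
        columns ``chromosome``, ``position_index``, ``bin_id``, ``tissue``.
    """

    values: np.ndarray
    marker_ids: list[str]
    individual_ids: list[str]
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.marker_ids = [str(x) for x in self.marker_ids]
        self.individual_ids = [str(x) for x in self.individual_ids]
        if self.values.ndim != 2:
            raise ValidationError("marker values must be a 2D matrix")
        m, n = self.values.shape
        if m < 1:
            raise ValidationError("need at least one marker")
        if n < 2:
            raise ValidationError("need at least two individuals")
        if len(self.marker_ids) != m or len(self.individual_ids) != n:
            raise ValidationError(
                f"id lengths ({len(self.marker_ids)}, {len(self.individual_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"missing/non-finite value at marker {self.marker_ids[i]!r}, "
                f"individual {self.individual_ids[j]!r}"
            )
        _check_unique(self.marker_ids, "marker")
        _check_unique(self.individual_ids, "individual")
        if self.meta is not None:
            bad = [t for t in self.meta.get("tissue", pd.Series(dtype=object)).dropna()
                   if t not in TISSUES]
            if bad:
                raise ValidationError(f"unknown tissue label(s): {sorted(set(bad))}")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def marker_index(self, marker_id: str) -> int:
        try:
            return self.marker_ids.index(marker_id)
        except ValueError:
            raise KeyError(f"unknown marker id: {marker_id!r}") from None

    def select_markers(self, marker_ids) -> "MarkerMatrix":
        """Row subset (in the given order), carrying metadata along."""
        idx = [self.marker_index(x) for x in marker_ids]
        meta = None
        if self.meta is not None:
            keep = [x for x in marker_ids if x in self.meta.index]
            meta = self.meta.loc[keep]
        return MarkerMatrix(self.values[idx], list(marker_ids),
                            list(self.individual_ids), meta)

    def reorder_individuals(self, individual_ids) -> "MarkerMatrix":
        pos = {x: k for k, x in enumerate(self.individual_ids)}
        idx = [pos[x] for x in individual_ids]
        return MarkerMatrix(self.values[:, idx], list(self.marker_ids),
                            list(individual_ids), self.meta)

    def standardized(self) -> "MarkerMatrix":
        """Per-marker zero-mean unit-variance copy (optional; off by default
        everywhere — the model takes markers as coded)."""
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd == 0):
            raise ValidationError("cannot standardize a constant marker")
        return MarkerMatrix((self.values - mu) / sd, list(self.marker_ids),
                            list(self.individual_ids), self.meta)


@dataclass
class TraitVector:
    """A quantitative trait measured on n individuals."""

    values: np.ndarray
    individual_ids: list[str]
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        self.individual_ids = [str(x) for x in self.individual_ids]
        if len(self.individual_ids) != self.values.shape[0]:
            raise ValidationError("trait ids do not match value count")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("trait contains missing/non-finite values")
        _check_unique(self.individual_ids, "individual")
        if self.values.size < 2 or np.var(self.values, ddof=1) <= 0:
            raise ValidationError(
                f"trait {self.trait_name!r} has zero variance"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def reorder(self, individual_ids) -> "TraitVector":
        pos = {x: k for k, x in enumerate(self.individual_ids)}
        idx = [pos[x] for x in individual_ids]
        return TraitVector(self.values[idx], list(individual_ids), self.trait_name)


@dataclass
class BinMap:
    """Many-to-one map from transcripts to genotype bins.

    ``bin_order`` fixes the chromosomal ordering of bins used when emitting
    positionally aligned per-bin tables.
    """

    entries: dict[str, str] = field(default_factory=dict)
    bin_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.bin_order, "bin")
        known = set(self.bin_order)
        for t, b in self.entries.items():
            if b not in known:
                raise ValidationError(
                    f"transcript {t!r} maps to bin {b!r} absent from bin_order"
                )

    def bin_of(self, transcript_id: str) -> str | None:
        return self.entries.get(transcript_id)


def align_samples(Z: MarkerMatrix, y: TraitVector,
                  logger=None) -> tuple[MarkerMatrix, TraitVector]:
    """Reorder marker columns and trait entries to a shared individual order.

    The order of ``y``'s ids restricted to the intersection wins; individuals
    absent from either side are dropped (counts are logged when a logger is
    given).  Idempotent: aligning aligned inputs is a no-op.
    """
    zset = set(Z.individual_ids)
    order = [x for x in y.individual_ids if x in zset]
    if len(order) < 3:
        raise ValidationError(
            f"only {len(order)} individuals shared between markers and trait; "
            "need at least 3"
        )
    dropped_z = Z.n - len(order)
    dropped_y = y.n - len(order)
    if logger is not None and (dropped_z or dropped_y):
        logger.info("align_samples: dropped %d marker-side and %d trait-side "
                    "individuals", dropped_z, dropped_y)
    return Z.reorder_individuals(order), y.reorder(order)
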