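"""CSV readers and writers for the pipeline's inputs and outputs.

Formats (all comma-separated, '.' decimal, UTF-8, header row mandatory):

* marker matrix  -- ``marker_id,<ind1>,...,<indN>`` then one numeric row
  per marker;
* trait          -- ``individual_id,value`` two-column rows;
* marker metadata-- ``marker_id,chromosome,position_index,bin_id,tissue``;
* kinship        -- square matrix with individual ids as first row/column;
* variance components -- ``key,value`` lines in a fixed key order;
* scan results   -- fixed column orders (see ``write_results``).

Missing values are rejected, never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import BinMap, MarkerMatrix, TraitVector, ValidationError

__all__ = [
    "read_marker_matrix",
    "write_marker_matrix",
    "read_trait",
    "write_trait",
    "read_bin_map",
    "write_results",
    "read_kinship_csv",
    "read_variance_components",
]

META_COLUMNS = ("chromosome", "position_index", "bin_id", "tissue")

VC_KEYS = ("sigma2_a", "sigma2_aa", "sigma2_e", "lambda_a", "lambda_aa",
           "ratio_a", "ratio_aa", "ratio_e", "H")

SCAN1D_COLUMNS = ("marker_id", "effect", "var_effect", "wald", "p",
                  "neglog10p", "status")
SCAN2D_COLUMNS = ("marker_i", "marker_j", "gamma", "var_gamma", "wald", "p",
                  "neglog10p", "status")


def _read_numeric_body(df: pd.DataFrame, path) -> np.ndarray:
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().values)[0]
        raise ValidationError(
            f"{path}: empty cell at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    try:
        # numpy's strtod is exact to the stored decimal representation
        return df.to_numpy(dtype=float)
    except (ValueError, TypeError):
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                try:
                    float(df.iat[i, j])
                except (ValueError, TypeError):
                    raise ValidationError(
                        f"{path}: non-numeric value {df.iat[i, j]!r} at row "
                        f"{df.index[i]!r}, column {df.columns[j]!r}"
                    ) from None
        raise


def read_marker_matrix(path, meta_path=None) -> MarkerMatrix:
    """Read a marker-by-individual CSV, optionally merging per-marker
    metadata by marker id."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    values = _read_numeric_body(df, path)
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, index_col=0, dtype=str)
        if "position_index" in meta.columns:
            meta["position_index"] = pd.to_numeric(meta["position_index"])
        meta = meta[[c for c in META_COLUMNS if c in meta.columns]]
        meta = meta.loc[[x for x in df.index.astype(str) if x in meta.index]]
    return MarkerMatrix(values, list(df.index.astype(str)),
                        list(df.columns.astype(str)), meta)


def write_marker_matrix(Z: MarkerMatrix, path, meta_path=None) -> None:
    df = pd.DataFrame(Z.values, index=Z.marker_ids, columns=Z.individual_ids)
    df.index.name = "marker_id"
    df.to_csv(path, float_format="%.17g")
    if meta_path is not None and Z.meta is not None:
        out = Z.meta.copy()
        out.index.name = "marker_id"
        out.to_csv(meta_path)


def read_trait(path, trait_name: str | None = None) -> TraitVector:
    """Read a two-column ``individual_id,value`` trait CSV; file order is
    preserved."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] == 1:
        ids = [str(i) for i in range(1, len(df) + 1)]
        raw = df.iloc[:, 0]
        name = trait_name or str(df.columns[0])
    else:
        ids = list(df.iloc[:, 0].astype(str))
        raw = df.iloc[:, 1]
        name = trait_name or str(df.columns[1])
    try:
        vals = raw.to_numpy(dtype=float)
    except (ValueError, TypeError):
        for k, v in enumerate(raw):
            try:
                float(v)
            except (ValueError, TypeError):
                raise ValidationError(
                    f"{path}: non-numeric trait value {v!r} at row {k}"
                ) from None
        raise
    if np.any(pd.isna(raw.to_numpy())):
        raise ValidationError(f"{path}: missing trait value")
    return TraitVector(vals, ids, name)


def write_trait(y: TraitVector, path) -> None:
    df = pd.DataFrame({"individual_id": y.individual_ids,
                       y.trait_name: y.values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_bin_map(path) -> BinMap:
    """``transcript_id,bin_id`` CSV; bin order is first-appearance order."""
    df = pd.read_csv(path, dtype=str)
    entries: dict[str, str] = {}
    order: list[str] = []
    seen = set()
    for t, b in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if t in entries:
            raise ValidationError(f"transcript {t!r} mapped to more than one bin")
        entries[str(t)] = str(b)
        if b not in seen:
            seen.add(b)
            order.append(str(b))
    return BinMap(entries, order)


def read_kinship_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValidationError(f"{path}: kinship row/column ids differ")
    return df.to_numpy(dtype=float), list(df.columns.astype(str))


def read_variance_components(path) -> dict[str, float]:
    df = pd.read_csv(path, header=None, names=["key", "value"])
    return dict(zip(df["key"].astype(str), df["value"].astype(float)))


def _write_square(M: np.ndarray, ids, path) -> None:
    df = pd.DataFrame(M, index=ids, columns=ids)
    df.index.name = "individual_id"
    df.to_csv(path, float_format="%.17g")


def write_results(obj, path) -> None:
    """Write a pipeline product with a fixed, bitwise-stable column order.

    Dispatches on type: 1D/2D scan tables and predictability tables go out
    as CSV; variance components as ``key,value`` lines; a kinship set as a
    pair of square CSVs (``path`` with ``_Ka``/``_Kaa`` inserted before the
    extension) plus their normalizers.
    """
    from .kinship import KinshipSet
    from .reml import VarianceComponents
    from .scan import ScanResult1D, ScanResult2D

    if isinstance(obj, ScanResult1D):
        obj.table[list(SCAN1D_COLUMNS)].to_csv(path, index=False,
                                               float_format="%.17g")
    elif isinstance(obj, ScanResult2D):
        obj.table[list(SCAN2D_COLUMNS)].to_csv(path, index=False,
                                               float_format="%.17g")
    elif isinstance(obj, VarianceComponents):
        vals = obj.as_dict()
        with open(path, "w", encoding="utf-8") as fh:
            for k in VC_KEYS:
                fh.write(f"{k},{vals[k]:.17g}\n")
    elif isinstance(obj, KinshipSet):
        base, dot, ext = str(path).rpartition(".")
        if not dot:
            base, ext = str(path), "csv"
        _write_square(obj.K_a, obj.individual_ids, f"{base}_Ka.{ext}")
        _write_square(obj.K_aa, obj.individual_ids, f"{base}_Kaa.{ext}")
        with open(f"{base}_normalizers.{ext}", "w", encoding="utf-8") as fh:
            fh.write(f"d_a,{obj.d_a:.17g}\nd_aa,{obj.d_aa:.17g}\n")
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False, float_format="%.17g")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
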