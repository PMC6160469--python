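"""Cross-omics integration utilities.

Three products built downstream of the association scans:

* transcript-to-bin reduction — collapse a transcript panel onto genotype
  bins, keeping one representative transcript per bin (the one with the
  highest 1D −log10(p)), so transcript and genotype association maps share
  a coordinate system and marker counts become comparable;
* tissue-stratified top-n tables — rank markers by 1D significance and
  count, for each top-n cut, how many come from each tissue (leaf vs seed
  metabolites);
* weighted association networks — graphs whose edges are significant
  marker pairs from the 2D scan, weighted by −log10(p), optionally
  restricted to the star around one focal (hub) marker.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import BinMap, MarkerMatrix, ValidationError
from .scan import ScanResult1D

__all__ = [
    "reduce_to_bins",
    "bin_level_minp",
    "tissue_topn_table",
    "build_network",
    "write_edge_list",
]


def _scan_lookup(scan: ScanResult1D) -> dict[str, float]:
    t = scan.table
    return dict(zip(t["marker_id"], t["neglog10p"]))


def reduce_to_bins(scan: ScanResult1D, binmap: BinMap, Z: MarkerMatrix,
                   logger=None) -> tuple[MarkerMatrix, dict[str, str]]:
    """One representative transcript per genotype bin.

    The representative is the bin's transcript with the highest −log10(p)
    in the 1D scan (ties break by lowest marker index).  The reduced panel
    keeps one row per occupied bin, ordered by ``bin_order``; scanned
    transcripts absent from the map are dropped (count logged).
    """
    nlp = _scan_lookup(scan)
    index = {mid: k for k, mid in enumerate(Z.marker_ids)}
    best: dict[str, str] = {}
    dropped = 0
    for mid in scan.table["marker_id"]:
        b = binmap.bin_of(mid)
        if b is None or mid not in index:
            dropped += 1
            continue
        cur = best.get(b)
        score = nlp.get(mid, np.nan)
        if cur is None:
            best[b] = mid
        else:
            cur_score = nlp.get(cur, np.nan)
            if (np.nan_to_num(score, nan=-np.inf)
                    > np.nan_to_num(cur_score, nan=-np.inf)):
                best[b] = mid
            elif score == cur_score and index[mid] < index[cur]:
                best[b] = mid
    if not best:
        raise ValidationError("no scanned marker maps to any bin")
    if logger is not None and dropped:
        logger.info("reduce_to_bins: dropped %d unmapped transcripts", dropped)
    keep_bins = [b for b in binmap.bin_order if b in best]
    reps = [best[b] for b in keep_bins]
    reduced = Z.select_markers(reps)
    return reduced, {b: best[b] for b in keep_bins}


def bin_level_minp(scan: ScanResult1D, binmap: BinMap) -> pd.DataFrame:
    """Per-bin representative significance for positionally aligned plots.

    One ``bin_id,neglog10p`` row per bin in ``bin_order``, carrying the
    maximum −log10(p) (equivalently the minimum p) over the bin's
    transcripts; empty bins emit a null (NaN) row.
    """
    nlp = _scan_lookup(scan)
    per_bin: dict[str, float] = {}
    for mid, v in nlp.items():
        b = binmap.bin_of(mid)
        if b is None or not np.isfinite(v):
            continue
        per_bin[b] = max(per_bin.get(b, -np.inf), v)
    rows = [(b, per_bin.get(b, np.nan)) for b in binmap.bin_order]
    return pd.DataFrame(rows, columns=["bin_id", "neglog10p"])


def tissue_topn_table(scan: ScanResult1D, tissue: dict[str, str],
                      top_ns) -> pd.DataFrame:
    """Tissue composition of the top-n most significant markers.

    Markers rank by ascending p (ties resolved by input marker index); for
    each requested n the table records the −log10(p) of the nth-ranked
    marker (the significance threshold that cut would imply) and the leaf
    and seed counts among the top n.
    """
    t = scan.table[scan.table["status"] == "ok"].reset_index()
    missing = [m for m in t["marker_id"] if m not in tissue]
    if missing:
        raise ValidationError(
            f"tissue label missing for {len(missing)} markers "
            f"(first: {missing[0]!r})")
    ranked = t.sort_values(["p", "index"], kind="stable").reset_index(drop=True)
    rows = []
    for n in top_ns:
        n = int(n)
        if n < 1 or n > len(ranked):
            raise ValidationError(f"top_n={n} outside [1, {len(ranked)}]")
        head = ranked.iloc[:n]
        labels = head["marker_id"].map(tissue)
        rows.append((n, float(head["neglog10p"].iloc[-1]),
                     int((labels == "leaf").sum()),
                     int((labels == "seed").sum())))
    return pd.DataFrame(rows, columns=["top_n", "significance_th", "n_leaf",
                                       "n_seed"])


def build_network(pairs: pd.DataFrame, *, mode: str = "threshold",
                  top_k: int | None = None, threshold: float = 3.0,
                  focal: str | None = None) -> nx.Graph:
    """Weighted association network from a thresholded pair table.

    ``pairs`` is a ``threshold_pairs``-style table sorted by descending
    significance.  ``mode="top_k"`` keeps the k most significant pairs;
    ``mode="threshold"`` keeps pairs with −log10(p) ≥ threshold (default
    3.0, i.e. p ≤ 0.001).  With ``focal`` set, only edges incident to that
    marker survive.  Edge attribute ``weight`` is −log10(p).  An empty
    selection yields an empty graph.
    """
    if mode == "top_k":
        if top_k is None:
            raise ValidationError("top_k mode requires top_k")
        sel = pairs.iloc[:int(top_k)]
    elif mode == "threshold":
        sel = pairs[pairs["neglog10p"] >= threshold]
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    G = nx.Graph()
    for _, row in sel.iterrows():
        i, j = row["marker_i"], row["marker_j"]
        if i == j:
            continue
        if focal is not None and focal not in (i, j):
            continue
        G.add_edge(i, j, weight=float(row["neglog10p"]))
    if focal is not None and focal not in G and len(sel) > 0:
        G.add_node(focal)
    return G


def write_edge_list(G: nx.Graph, path) -> None:
    """Tab-separated ``marker_i  marker_j  neglog10p`` edge list, heaviest
    first."""
    edges = sorted(G.edges(data="weight"),
                   key=lambda e: (-e[2], str(e[0]), str(e[1])))
    with open(path, "w", encoding="utf-8") as fh:
        for i, j, w in edges:
            fh.write(f"{i}\t{j}\t{w:.6g}\n")
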