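"""Missingness filtering and weighted-KNN imputation.

Missing IC50, copy-number and mutation entries are filled from the K cell
lines nearest in gene-expression space (expression itself is always complete).
Real-valued targets get a weighted mean of the neighbours' values; binary
mutation targets get a majority vote with ties resolved to wild type (0).

Two weight normalisations are provided.  ``"as_printed"`` uses
``w_k = d(c,k) / sum_k d(c,k)``, which gives *farther* neighbours more weight;
``"inverse_distance"`` (the default) uses ``w_k ∝ 1 / (d(c,k) + eps)``, the
evident intent of a nearest-neighbour scheme.  See docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd


from .core_io import DegenerateDataError, FeatureMatrix, ResponseTable

logger = logging.getLogger("autoborutarf")

_EPS = 1e-8

WEIGHT_MODES = ("inverse_distance", "as_printed")


class ImputationError(ValueError):
    """An entry cannot be imputed (no candidate neighbour observed)."""


@dataclass
class NeighborSet:
    """The (at most K) nearest candidate cell lines for one missing entry."""

    target: str
    neighbor_ids: list[str]
    distances: np.ndarray  # nondecreasing, aligned with neighbor_ids

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.target in self.neighbor_ids:
            raise ValueError("target cell line cannot be its own neighbour")
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be nondecreasing")
        if np.any(self.distances < 0):
            raise ValueError("distances must be nonnegative")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_missing(features: dict[str, FeatureMatrix], response: ResponseTable,
                   feature_threshold: float = 0.5, cell_threshold: float = 0.5,
                   joint_cell_filter: bool = True):
    """Drop over-missing feature columns / drug rows, then over-missing cells.

    A feature column (or drug row of the response table) is removed when its
    missing fraction is *strictly greater* than ``feature_threshold``; a cell
    line is then removed when its missing fraction across the surviving
    feature columns (plus the surviving response entries when
    ``joint_cell_filter``) is strictly greater than ``cell_threshold``.
    Returns filtered copies plus a removal report.
    """
    if not 0 < feature_threshold <= 1 or not 0 < cell_threshold <= 1:
        raise ValueError("thresholds must be in (0, 1]")

    report: dict[str, list[str]] = {"features": [], "drugs": [], "cells": []}

    kept: dict[str, FeatureMatrix] = {}
    for kind, fm in features.items():
        frac = fm.values.isna().mean(axis=0)
        drop = frac.index[frac > feature_threshold]
        report["features"] += [f"{kind}:{f}" for f in drop]
        kept[kind] = FeatureMatrix(fm.values.drop(columns=drop), fm.kind)
        if kept[kind].values.shape[1] == 0 and fm.values.shape[1] > 0:
            raise DegenerateDataError(f"all {kind} features removed")

    drug_frac = response.ic50.isna().mean(axis=1)
    drop_drugs = drug_frac.index[drug_frac > feature_threshold]
    report["drugs"] = list(drop_drugs)
    resp = ResponseTable(response.ic50.drop(index=drop_drugs))
    if resp.ic50.shape[0] == 0 and response.ic50.shape[0] > 0:
        raise DegenerateDataError("all drugs removed")

    blocks = [fm.values.isna() for fm in kept.values()]
    if joint_cell_filter:
        blocks.append(resp.ic50.T.isna())
    cells = kept[next(iter(kept))].values.index
    miss = pd.concat([b.reindex(cells) for b in blocks], axis=1)
    cell_frac = miss.mean(axis=1)
    drop_cells = cell_frac.index[cell_frac > cell_threshold]
    report["cells"] = list(drop_cells)
    survivors = [c for c in cells if c not in set(drop_cells)]
    if not survivors:
        raise DegenerateDataError("all cell lines removed")

    kept = {k: fm.subset(cells=survivors) for k, fm in kept.items()}
    resp = resp.subset_cells(survivors)
    if report["features"] or report["drugs"] or report["cells"]:
        logger.info("filter_missing removed %d features, %d drugs, %d cells",
                    len(report["features"]), len(report["drugs"]),
                    len(report["cells"]))
    return kept, resp, report


# ---------------------------------------------------------------------------
# distances and neighbours
# ---------------------------------------------------------------------------


def cell_distance(c: str, k: str, expression: FeatureMatrix) -> float:
    """Squared Euclidean distance between two cell lines' expression profiles."""
    if expression.n_missing:
        raise ValueError("expression matrix must be complete")
    a = expression.values.loc[c].to_numpy()
    b = expression.values.loc[k].to_numpy()
    return float(((a - b) ** 2).sum())


def distance_matrix(expression: FeatureMatrix) -> pd.DataFrame:
    """All pairwise squared Euclidean expression distances."""
    if expression.n_missing:
        raise ValueError("expression matrix must be complete")
    arr = expression.values.to_numpy()
    # entry-wise with the exact reduction of cell_distance: neighbour ranking
    # is order-sensitive, so the two paths must agree bit for bit
    n = len(arr)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ((arr[i] - arr[j]) ** 2).sum()
    ids = expression.cell_line_ids
    return pd.DataFrame(d, index=ids, columns=ids)


def find_neighbors(c: str, K: int, expression: FeatureMatrix,
                   candidates) -> NeighborSet:
    """The K candidates nearest to ``c`` in expression space.

    ``candidates`` are the cell lines with an observed value for the variable
    being imputed; the target itself is excluded.  Ties at the K-th distance
    are broken by stable candidate order.  Fewer than K candidates are
    returned in full with a warning; zero candidates is an error.
    """
    cand = [x for x in candidates if x != c]
    if not cand:
        raise ImputationError(f"no candidate neighbour for cell {c!r}")
    target = expression.values.loc[c].to_numpy()
    arr = expression.values.loc[cand].to_numpy()
    d = np.array([((row - target) ** 2).sum() for row in arr])
    if len(cand) < K:
        logger.warning("only %d candidates (< K=%d) for cell %s",
                       len(cand), K, c)
        order = np.argsort(d, kind="stable")
    else:
        order = np.argsort(d, kind="stable")[:K]
    return NeighborSet(target=c, neighbor_ids=[cand[i] for i in order],
                       distances=d[order])


# ---------------------------------------------------------------------------
# single-entry imputation
# ---------------------------------------------------------------------------


def _weights(distances: np.ndarray, weight_mode: str) -> np.ndarray:
    if weight_mode not in WEIGHT_MODES:
        raise ValueError(f"unknown weight mode {weight_mode!r}")
    d = np.asarray(distances, dtype=float)
    if weight_mode == "as_printed":
        tot = d.sum()
        if tot == 0:
            return np.full(d.shape, 1.0 / len(d))
        return d / tot
    w = 1.0 / (d + _EPS)
    return w / w.sum()


def impute_real(values: np.ndarray, neighbors: NeighborSet,
                weight_mode: str = "inverse_distance") -> float:
    """Weighted mean of the neighbours' observed values (weights sum to 1)."""
    if len(neighbors.neighbor_ids) == 0:
        raise ImputationError("empty neighbour set")
    w = _weights(neighbors.distances, weight_mode)
    return float(w @ np.asarray(values, dtype=float))


def impute_binary(values: np.ndarray, neighbors: NeighborSet) -> float:
    """1 iff strictly more neighbour 1s than 0s; ties and minorities give 0."""
    if len(neighbors.neighbor_ids) == 0:
        raise ImputationError("empty neighbour set")
    v = np.asarray(values, dtype=float)
    return 1.0 if (v == 1).sum() > (v == 0).sum() else 0.0


# ---------------------------------------------------------------------------
# whole-table imputation
# ---------------------------------------------------------------------------


def _impute_frame(df: pd.DataFrame, binary: bool, dmat: pd.DataFrame, K: int,
                  weight_mode: str, what: str) -> pd.DataFrame:
    """Fill every NaN in ``df`` (cells x variables) via expression-KNN."""
    out = df.copy()
    cells = list(df.index)
    for g in df.columns[df.isna().any(axis=0)]:
        col = df[g]
        observed = [c for c in cells if not np.isnan(col.loc[c])]
        for c in col.index[col.isna()]:
            if not observed:
                raise ImputationError(
                    f"cannot impute {what} {g!r} for cell {c!r}: "
                    "no observed value in any other cell line")
            cand = [x for x in observed if x != c]
            d = dmat.loc[c, cand].to_numpy()
            order = np.argsort(d, kind="stable")[:K]
            ns = NeighborSet(target=c,
                             neighbor_ids=[cand[i] for i in order],
                             distances=d[order])
            vals = col.loc[ns.neighbor_ids].to_numpy()
            if binary:
                out.loc[c, g] = impute_binary(vals, ns)
            else:
                out.loc[c, g] = impute_real(vals, ns, weight_mode)
    return out


def impute_all(features: dict[str, FeatureMatrix], response: ResponseTable,
               K: int = 10, weight_mode: str = "inverse_distance"):
    """Fill every missing CNA/SNV/IC50 entry; observed entries are untouched.

    Distances are always computed on the (complete) expression matrix.  The
    response table is imputed per drug exactly like a feature column.
    """
    if "expression" not in features:
        raise ValueError("expression matrix required for imputation distances")
    expr = features["expression"]
    if expr.n_missing:
        raise ValueError("expression matrix must be complete before imputation")

    dmat = distance_matrix(expr)
    out: dict[str, FeatureMatrix] = {"expression": expr}
    for kind, fm in features.items():
        if kind == "expression":
            continue
        filled = _impute_frame(fm.values, binary=(kind == "snv"), dmat=dmat,
                               K=K, weight_mode=weight_mode, what=kind)
        out[kind] = FeatureMatrix(filled, fm.kind)

    resp_filled = _impute_frame(response.ic50.T, binary=False, dmat=dmat,
                                K=K, weight_mode=weight_mode, what="drug").T
    return out, ResponseTable(resp_filled)
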