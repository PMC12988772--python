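"""Built-in multi-sample analyses.

Four analyses operate on experiments/samples assembled elsewhere in the
package: cellular composition (per-group cell-type proportions), cell-type
density inside annotation/region polygons (cells per mm²), two-group
differential expression, and pseudobulk aggregation (per-group raw count
sums).

Differential expression uses deliberately simple, documented defaults:
counts are normalized per cell to the median total of the pooled groups,
each feature is tested with a two-sided Wilcoxon rank-sum test (normal
approximation with tie correction), the log2 fold change is computed on
normalized group means with a small pseudocount, and p-values are adjusted
with Benjamini–Hochberg over the tested feature set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._exceptions import FeatureMismatchError, InvalidPolygonError
from .core import CellLayer, Sample
from .geometry import points_in_polygon, polygon_area

logger = logging.getLogger(__name__)

LFC_EPS = 1e-9


# ---------------------------------------------------------------------------
# composition & density
# ---------------------------------------------------------------------------

def cell_composition(
    experiment, group_key: str = "uid", celltype_key: str = "cell_type",
    layer: str | None = None,
) -> pd.DataFrame:
    """Per-group cell-type proportions.

    Groups are the values of metadata column ``group_key`` (``"uid"`` for
    per-sample rows); cells of all samples in a group are pooled. Every
    row sums to 1; types absent from a group get 0. Groups without cells
    are dropped.
    """
    if group_key not in experiment.metadata.columns:
        raise KeyError(f"unknown metadata column {group_key!r}")
    counts: dict = {}
    for row, sample in experiment:
        group = row[group_key]
        for lname, clayer in sample.cells.items():
            if layer is not None and lname != layer:
                continue
            if celltype_key not in clayer.cell_table.columns:
                raise KeyError(
                    f"sample {sample.uid}: cell table has no column {celltype_key!r}"
                )
            vc = clayer.cell_table[celltype_key].value_counts()
            acc = counts.setdefault(group, {})
            for ctype, n in vc.items():
                acc[ctype] = acc.get(ctype, 0) + int(n)
    if not counts:
        return pd.DataFrame()
    table = pd.DataFrame(counts).T.fillna(0.0).sort_index(axis=1)
    table = table.loc[table.sum(axis=1) > 0]
    table = table.div(table.sum(axis=1), axis=0)
    table.index.name = group_key
    return table


def cell_type_density(
    sample: Sample, polygon_set_name: str, celltype_key: str = "cell_type",
    layer: str | None = None,
) -> pd.DataFrame:
    """Cell-type densities (cells per mm²) inside each polygon of a named set.

    The set is looked up among the sample's annotations, then regions.
    Density = count of centroids of that type inside the polygon divided
    by the polygon area in mm². Zero-area polygons are rejected.
    """
    pset = sample.annotations.get(polygon_set_name) or sample.regions.get(polygon_set_name)
    if pset is None:
        raise KeyError(f"no annotation or region set named {polygon_set_name!r}")
    frames = []
    for lname, clayer in sample.cells.items():
        if layer is not None and lname != layer:
            continue
        if celltype_key not in clayer.cell_table.columns:
            raise KeyError(f"cell table has no column {celltype_key!r}")
        cents = clayer.centroids()
        types = clayer.cell_table[celltype_key].to_numpy()
        all_types = sorted(pd.unique(types).astype(str))
        for entry in pset:
            area_mm2 = polygon_area(entry.vertices) / 1e6
            if area_mm2 == 0:
                raise InvalidPolygonError(f"polygon {entry.name!r} has zero area")
            inside = points_in_polygon(cents, entry.vertices)
            for ctype in all_types:
                n = int(np.sum(inside & (types.astype(str) == ctype)))
                frames.append(
                    {"polygon": entry.name, "class": entry.class_label, "layer": lname,
                     "cell_type": ctype, "n_cells": n, "density_per_mm2": n / area_mm2}
                )
    return pd.DataFrame(frames)


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, clipped at 1; ties share identical q-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def _normalized(dense: np.ndarray, target: float) -> np.ndarray:
    totals = dense.sum(axis=1)
    factors = np.divide(target, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0)
    return dense * factors[:, None]


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum per column (normal approx., tie-corrected)."""
    na, nb = len(a), len(b)
    n = na + nb
    combined = np.vstack([a, b])
    ranks = sstats.rankdata(combined, axis=0)
    w = ranks[:na].sum(axis=0)
    mu = na * (n + 1) / 2.0
    # tie correction per column
    tie_term = np.zeros(combined.shape[1])
    for j in range(combined.shape[1]):
        _, counts = np.unique(combined[:, j], return_counts=True)
        t = counts[counts > 1]
        tie_term[j] = (t**3 - t).sum()
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (w - mu) / np.sqrt(var), 0.0)
    p = np.where(var > 0, 2 * sstats.norm.sf(np.abs(z)), 1.0)
    return z, p


def _dense_features(layer_or_pair):
    if isinstance(layer_or_pair, CellLayer):
        return layer_or_pair.dense_matrix().astype(float), layer_or_pair.features
    matrix, features = layer_or_pair
    m = matrix.toarray() if hasattr(matrix, "toarray") else np.asarray(matrix)
    return m.astype(float), pd.Index(features)


def differential_expression(cells_a, cells_b) -> pd.DataFrame:
    """Two-group differential expression over the shared feature set.

    Accepts :class:`CellLayer` objects or ``(matrix, features)`` pairs.
    Each group needs at least two cells; disjoint feature sets are an
    error; features missing from one group are dropped with a warning
    (intersection), never zero-filled. Returns one row per feature with
    normalized group means, log2 fold change (A over B), the rank-sum
    z statistic, p-value and BH q-value.
    """
    mat_a, feats_a = _dense_features(cells_a)
    mat_b, feats_b = _dense_features(cells_b)
    if len(mat_a) < 2 or len(mat_b) < 2:
        raise ValueError("each group needs at least 2 cells")
    shared = feats_a.intersection(feats_b)
    if len(shared) == 0:
        raise FeatureMismatchError("groups share no features")
    if len(shared) < len(feats_a) or len(shared) < len(feats_b):
        logger.warning(
            "restricting to %d shared features (of %d and %d)",
            len(shared), len(feats_a), len(feats_b),
        )
    a = mat_a[:, feats_a.get_indexer(shared)]
    b = mat_b[:, feats_b.get_indexer(shared)]

    target = float(np.median(np.concatenate([a.sum(axis=1), b.sum(axis=1)])))
    an = _normalized(a, target)
    bn = _normalized(b, target)

    mean_a = an.mean(axis=0)
    mean_b = bn.mean(axis=0)
    lfc = np.log2((mean_a + LFC_EPS) / (mean_b + LFC_EPS))
    z, p = _rank_sum_z(an, bn)
    return pd.DataFrame(
        {
            "feature": shared,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2_fold_change": lfc,
            "statistic": z,
            "p_value": p,
            "q_value": bh_adjust(p),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

def pseudobulk(experiment, group_key: str = "uid", layer: str | None = None) -> pd.DataFrame:
    """Per-group element-wise sums of raw counts (groups × features).

    Features are intersected across samples (a warning is logged when any
    are dropped); an empty intersection is an error. Groups come from the
    metadata column ``group_key``.
    """
    if group_key not in experiment.metadata.columns:
        raise KeyError(f"unknown metadata column {group_key!r}")
    layers: list[tuple[object, CellLayer]] = []
    for row, sample in experiment:
        for lname, clayer in sample.cells.items():
            if layer is not None and lname != layer:
                continue
            layers.append((row[group_key], clayer))
    if not layers:
        return pd.DataFrame()
    shared = layers[0][1].features
    for _, clayer in layers[1:]:
        shared = shared.intersection(clayer.features)
    if len(shared) == 0:
        raise FeatureMismatchError("samples share no features")
    if any(len(shared) < cl.n_features for _, cl in layers):
        logger.warning("pseudobulk restricted to %d shared features", len(shared))
    sums: dict = {}
    for group, clayer in layers:
        dense = clayer.dense_matrix()[:, clayer.features.get_indexer(shared)]
        sums[group] = sums.get(group, 0) + dense.sum(axis=0)
    out = pd.DataFrame(sums).T
    out.columns = shared
    out.index.name = group_key
    return out.sort_index()
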