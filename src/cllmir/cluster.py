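"""Hierarchical ordering of features and samples for heatmap display.

Agglomerative average-linkage clustering with distance
``1 - Pearson correlation``, applied to rows and columns independently.
Constant rows (undefined correlation) fall back to zero correlation,
i.e. distance 1 to everything. Input ids are sorted before clustering
so tie-breaking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

__all__ = ["ClusterOrdering", "hierarchical_order"]


@dataclass
class ClusterOrdering:
    feature_order: list
    sample_order: list
    feature_heights: np.ndarray
    sample_heights: np.ndarray


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)  # constant rows: zero correlation
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    return squareform(dist, checks=False)


def _order(values: np.ndarray, ids: list):
    link = average(_correlation_distance(values))
    leaves = leaves_list(link)
    return [ids[i] for i in leaves], link[:, 2]


def hierarchical_order(matrix: pd.DataFrame) -> ClusterOrdering:
    """Joint row/column dendrogram orderings of a features-x-samples
    matrix; returns leaf orders and nondecreasing merge heights."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 features and 2 samples")
    rows = matrix.sort_index(axis=0).sort_index(axis=1)
    f_order, f_heights = _order(rows.to_numpy(dtype=float), list(rows.index))
    s_order, s_heights = _order(rows.to_numpy(dtype=float).T, list(rows.columns))
    return ClusterOrdering(
        feature_order=f_order,
        sample_order=s_order,
        feature_heights=f_heights,
        sample_heights=s_heights,
    )
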