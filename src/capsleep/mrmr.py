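"""Minimal-redundancy-maximal-relevance (mRMR) feature ranking.

Features are scored by their mutual information with the target class
(relevance) penalized by their mean mutual information with the already
selected features (redundancy); the greedy incremental "max(D - R)" scheme
ranks all features from most to least relevant. Continuous features are
discretized by equal-frequency binning fit on the training data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MrmrResult:
    """Greedy mRMR ranking: names most-to-least relevant plus step scores."""

    ordering: list
    scores: list

    def __post_init__(self):
        if len(self.ordering) != len(self.scores):
            raise ValueError("one score per ranked feature")


def mutual_information(x, y) -> float:
    """Plug-in mutual information (bits) of two discrete series.

    I(X;Y) = sum_ij p(i,j) log2 [ p(i,j) / (p(i) p(j)) ] over observed cells.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D series")
    n = len(x)
    if n == 0:
        raise ValueError("empty series")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / (px @ py)[mask])))


def discretize(column, n_bins: int = 10):
    """Equal-frequency binning; returns (codes, bin_edges) for reuse.

    If the column has fewer distinct values than bins, the distinct values
    become the bins (logged notice).
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    column = np.asarray(column, dtype=np.float64)
    quantiles = np.quantile(column, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(quantiles[1:-1])
    if len(edges) < n_bins - 1:
        logger.info("fewer distinct values than bins; collapsing to %d bins",
                    len(edges) + 1)
    codes = np.searchsorted(edges, column, side="left")
    return codes, edges


def apply_bins(column, edges) -> np.ndarray:
    """Bin new data with edges frozen on the training data."""
    return np.searchsorted(edges, np.asarray(column, dtype=np.float64), side="left")


def rank_features(features: pd.DataFrame, labels, n_bins: int = 10) -> MrmrResult:
    """Greedy incremental mRMR ranking of all feature columns.

    Step 1 picks the feature with maximal mutual information with the
    labels; step k maximizes relevance minus mean redundancy with the
    already-selected set. Exact ties break by original column order.
    """
    labels = np.asarray(labels)
    if len(features) != len(labels):
        raise ValueError("features and labels must be aligned")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; relevance undefined")

    names = list(features.columns)
    discrete = {name: discretize(features[name].to_numpy(), n_bins)[0]
                for name in names}
    relevance = {name: mutual_information(discrete[name], labels)
                 for name in names}

    selected: list = []
    scores: list = []
    remaining = list(names)
    pairwise: dict = {}

    def redundancy(cand: str) -> float:
        if not selected:
            return 0.0
        total = 0.0
        for s in selected:
            key = (cand, s) if cand < s else (s, cand)
            if key not in pairwise:
                pairwise[key] = mutual_information(discrete[cand], discrete[s])
            total += pairwise[key]
        return total / len(selected)

    while remaining:
        crit = [relevance[c] - redundancy(c) for c in remaining]
        best = int(np.argmax(crit))  # argmax keeps the first of exact ties
        selected.append(remaining.pop(best))
        scores.append(float(crit[best]))
    return MrmrResult(ordering=selected, scores=scores)


def nested_feature_sets(result: MrmrResult) -> list:
    """Candidate sets: the first k ranked features, for k = 1..n."""
    if not result.ordering:
        raise ValueError("empty ranking")
    return [result.ordering[:k] for k in range(1, len(result.ordering) + 1)]
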