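"""Pre-aggregated neighborhood features and reference regressors.

These are the comparison predictors for the radius sweep: each cell is
described by its own ligand/receptor expression, the arithmetic mean of its
neighbors' expression, and (when cell types are encoded in the node features)
the neighborhood cell-type proportions. A linear model or gradient-boosting
model is then fit on this fixed-dimensional table. Averaging collapses
neighborhoods with very different structure onto the same representation,
which is exactly the limitation the graph-convolutional model removes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import ElasticNet, Lasso, Ridge

from .graphs import TissueGraph
from .io import ValidationError

__all__ = [
    "aggregate_neighborhood_features",
    "NeighborhoodBaselineRegressor",
    "fit_baseline",
    "evaluate_baseline",
]

BASELINE_KINDS = ("ridge", "lasso", "elastic_net", "boosting")


def aggregate_neighborhood_features(
    graph: TissueGraph, include_cell_types: bool = True
) -> pd.DataFrame:
    """Fixed-dimensional per-cell feature table from a tissue graph.

    Columns: own node features, per-feature neighbor means (zero-filled for
    isolated cells; for one-hot cell-type columns the mean *is* the
    neighborhood cell-type proportion vector), and the neighbor count.
    Means are taken over in-neighbors; edges are symmetric so the direction
    is immaterial.
    """
    n = graph.n_nodes
    X = graph.features
    deg = graph.in_degrees()
    sums = np.zeros_like(X)
    if graph.n_edges:
        np.add.at(sums, graph.edge_index[1], X[graph.edge_index[0]])
    means = sums / np.maximum(deg, 1.0)[:, None]
    names = list(graph.feature_names) or [f"f{i}" for i in range(X.shape[1])]
    out = pd.DataFrame(X, columns=names)
    keep_nbr = [
        i
        for i, nm in enumerate(names)
        if include_cell_types or not nm.startswith("cell_type=")
    ]
    for i in keep_nbr:
        out[f"nbr_mean:{names[i]}"] = means[:, i]
    out["n_neighbors"] = deg
    out.index = pd.Index(graph.node_ids, name="cell_id")
    return out


class NeighborhoodBaselineRegressor(BaseEstimator):
    """Multi-output reference regressor on aggregated neighborhood features.

    ``kind`` selects ridge, lasso, elastic_net (scikit-learn), or boosting
    (one LightGBM model per response gene). Linear kinds take ``alpha`` and,
    for the elastic net, ``l1_ratio``; extra keyword hyperparameters are
    forwarded to LightGBM for the boosting kind.
    """

    def __init__(
        self,
        kind: str = "ridge",
        alpha: float = 1.0,
        l1_ratio: float = 0.5,
        seed: int = 0,
        boosting_params: dict | None = None,
    ):
        self.kind = kind
        self.alpha = alpha
        self.l1_ratio = l1_ratio
        self.seed = seed
        self.boosting_params = boosting_params

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        Y = np.atleast_2d(np.asarray(y, dtype=float))
        if Y.shape[0] != X.shape[0]:
            Y = Y.T
        if X.shape[0] != Y.shape[0]:
            raise ValidationError("feature and target row counts differ")
        if np.allclose(X.std(axis=0), 0.0):
            raise ValidationError("degenerate design matrix: every column is constant")
        if self.kind == "ridge":
            self.model_ = Ridge(alpha=self.alpha, random_state=self.seed).fit(X, Y)
        elif self.kind == "lasso":
            self.model_ = Lasso(alpha=self.alpha, random_state=self.seed).fit(X, Y)
        elif self.kind == "elastic_net":
            self.model_ = ElasticNet(
                alpha=self.alpha, l1_ratio=self.l1_ratio, random_state=self.seed
            ).fit(X, Y)
        elif self.kind == "boosting":
            from lightgbm import LGBMRegressor

            params = dict(self.boosting_params or {})
            params.setdefault("n_estimators", 100)
            params.setdefault("verbose", -1)
            self.model_ = [
                LGBMRegressor(random_state=self.seed, **params).fit(X, Y[:, j])
                for j in range(Y.shape[1])
            ]
        else:
            raise ValueError(f"unknown baseline kind {self.kind!r}; one of {BASELINE_KINDS}")
        self.n_features_in_ = X.shape[1]
        self.n_responses_ = Y.shape[1]
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.kind == "boosting":
            return np.column_stack([m.predict(X) for m in self.model_])
        pred = self.model_.predict(X)
        return pred.reshape(len(X), self.n_responses_)


def fit_baseline(
    features, targets, kind: str = "ridge", hyperparams: dict | None = None, seed: int = 0
) -> NeighborhoodBaselineRegressor:
    """Fit a reference regressor; thin functional wrapper over the estimator."""
    hyperparams = dict(hyperparams or {})
    if kind == "boosting":
        known = {k: hyperparams.pop(k) for k in ("alpha", "l1_ratio") if k in hyperparams}
        est = NeighborhoodBaselineRegressor(
            kind=kind, seed=seed, boosting_params=hyperparams, **known
        )
    else:
        est = NeighborhoodBaselineRegressor(kind=kind, seed=seed, **hyperparams)
    return est.fit(features, targets)


def evaluate_baseline(model, features, targets) -> np.ndarray:
    """Per-response-gene mean squared prediction error."""
    pred = model.predict(np.asarray(features, dtype=float))
    Y = np.atleast_2d(np.asarray(targets, dtype=float))
    if Y.shape[0] != pred.shape[0]:
        Y = Y.T
    return ((pred - Y) ** 2).mean(axis=0)
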