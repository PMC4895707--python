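"""Weighted-KNN and local-least-squares imputation over a distance matrix.

Both estimators fill each missing cell (i, t) from the K rows nearest to row
i under a caller-supplied distance matrix — expression-only D or the
GO-combined C — restricted to rows holding a valid value at sample t.

* KNN: inverse-distance-weighted mean, ``w_j = (1/C_ij) / sum_k 1/C_ik``.
  Zero-distance neighbours take the whole weight mass, split equally.
* LLS: the target row is regressed on the K neighbour rows over the samples
  where all of them are simultaneously valid; the missing value is the same
  linear combination of the neighbours' values at t.  Rank-deficient systems
  take the minimum-norm solution; with no shared sample the cell falls back
  to the KNN estimate.

A cell with no admissible neighbour at all falls back to the row mean of
observed values.  Observed cells pass through bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .distance import combined_distance, pairwise_expression_distance


class ImputationError(ValueError):
    pass


@dataclass
class ImputationResult:
    """Completed matrix plus provenance of every estimate.

    ``imputed_cells`` holds ``(row_index, col_index, estimate)`` triples for
    every originally missing cell; ``fallback_cells`` the subset that used a
    fallback rule (row mean, or KNN inside LLS).
    """

    completed: pd.DataFrame
    method: str
    K: int
    imputed_cells: list[tuple[int, int, float]] = field(default_factory=list)
    fallback_cells: list[tuple[int, int]] = field(default_factory=list)


def _validate(expr, C):
    if isinstance(expr, pd.DataFrame):
        values = expr.to_numpy(dtype=float)
        ids, cols = list(expr.index), list(expr.columns)
    else:
        values = np.asarray(expr, dtype=float)
        ids, cols = list(range(values.shape[0])), list(range(values.shape[1]))
    c_vals = C.to_numpy(dtype=float) if isinstance(C, pd.DataFrame) else np.asarray(C, dtype=float)
    if c_vals.shape != (values.shape[0], values.shape[0]):
        raise ValueError(
            f"distance matrix shape {c_vals.shape} does not match {values.shape[0]} rows"
        )
    if isinstance(C, pd.DataFrame) and isinstance(expr, pd.DataFrame):
        if list(C.index) != ids:
            raise ValueError("distance matrix ids do not match expression rows")
    return values, c_vals, ids, cols


def select_neighbors(C, expr, row: int, col: int, K: int) -> list[int]:
    """Indices of the K nearest admissible neighbours of (row, col).

    Admissible: a different row, valid at *col*, with a defined (finite)
    distance to *row*.  Ordered by (distance, row index); fewer than K are
    returned when candidates run out, an empty list signals the fallback.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    values, c_vals, _, _ = _validate(expr, C)
    if np.isfinite(values[row, col]):
        raise ValueError(f"cell ({row}, {col}) is not missing")
    return _neighbors_for(values, c_vals, row, col, K)


def _neighbors_for(values, c_vals, row, col, K) -> list[int]:
    dist = c_vals[row]
    cand = np.flatnonzero(np.isfinite(values[:, col]) & np.isfinite(dist))
    cand = cand[cand != row]
    if cand.size == 0:
        return []
    order = np.lexsort((cand, dist[cand]))  # distance first, row index breaks ties
    return cand[order[:K]].tolist()


def _knn_estimate(values, c_vals, row, col, nb) -> float:
    d = c_vals[row, nb]
    v = values[nb, col]
    zero = d == 0.0
    if zero.any():
        return float(v[zero].mean())
    w = 1.0 / d
    return float((w * v).sum() / w.sum())


def _row_mean_fallback(values, row, ids) -> float:
    obs = values[row][np.isfinite(values[row])]
    if obs.size == 0:
        raise ImputationError(
            f"row {ids[row]!r} has no observed value and no neighbour; cannot impute"
        )
    return float(obs.mean())


def _impute(expr, C, K: int, method: str) -> ImputationResult:
    if K < 1:
        raise ValueError("K must be >= 1")
    values, c_vals, ids, cols = _validate(expr, C)
    out = values.copy()
    valid = np.isfinite(values)
    result = ImputationResult(completed=None, method=method, K=K)
    for row, col in zip(*np.nonzero(~valid)):
        nb = _neighbors_for(values, c_vals, row, col, K)
        if not nb:
            est = _row_mean_fallback(values, row, ids)
            result.fallback_cells.append((int(row), int(col)))
        elif method == "knn":
            est = _knn_estimate(values, c_vals, row, col, nb)
        else:  # lls
            shared = valid[row] & valid[nb].all(axis=0)
            if shared.sum() < 1:
                est = _knn_estimate(values, c_vals, row, col, nb)
                result.fallback_cells.append((int(row), int(col)))
            else:
                A = values[np.ix_(nb, np.flatnonzero(shared))].T
                y = values[row, shared]
                w, *_ = np.linalg.lstsq(A, y, rcond=None)
                est = float(w @ values[nb, col])
        out[row, col] = est
        result.imputed_cells.append((int(row), int(col), float(est)))
    result.completed = pd.DataFrame(out, index=ids, columns=cols)
    return result


def knn_impute(expr, C, K: int = 5) -> ImputationResult:
    """Weighted K-nearest-neighbour imputation of every missing cell."""
    return _impute(expr, C, K, "knn")


def lls_impute(expr, C, K: int = 5) -> ImputationResult:
    """Local-least-squares imputation; neighbours selected by C, the same
    rule as KNN (the distance steers selection only, not the coefficients)."""
    return _impute(expr, C, K, "lls")


class _BaseGOImputer(TransformerMixin, BaseEstimator):
    """Shared fit/transform machinery; subclasses fix the estimator."""

    _method: str = ""

    def __init__(self, n_neighbors: int = 5, alpha: float = 1.0,
                 functional_similarity=None):
        self.n_neighbors = n_neighbors
        self.alpha = alpha
        self.functional_similarity = functional_similarity

    def _check_X(self, X):
        if isinstance(X, pd.DataFrame):
            check_array(X, ensure_all_finite="allow-nan", dtype=float)
            return X
        arr = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        return pd.DataFrame(arr)

    def _aligned_similarity(self, X: pd.DataFrame):
        H = self.functional_similarity
        if H is None:
            return None
        if isinstance(H, pd.DataFrame):
            if isinstance(self._X_index_, list) and list(H.index) != self._X_index_:
                missing = set(self._X_index_) - set(H.index)
                if missing:
                    raise ValueError(
                        f"functional_similarity lacks {len(missing)} row id(s), "
                        f"e.g. {sorted(missing)[:5]}"
                    )
                H = H.loc[self._X_index_, self._X_index_]
            return H.to_numpy(dtype=float)
        H = np.asarray(H, dtype=float)
        return H

    def fit(self, X, y=None):
        """Validate X and align the functional-similarity matrix to its rows."""
        X = self._check_X(X)
        self.n_features_in_ = X.shape[1]
        self._X_index_ = list(X.index)
        H = self._aligned_similarity(X)
        if H is not None and H.shape != (X.shape[0], X.shape[0]):
            raise ValueError(
                f"functional_similarity shape {H.shape} does not match "
                f"{X.shape[0]} rows"
            )
        self.similarity_ = H
        self.n_rows_ = X.shape[0]
        return self

    def transform(self, X):
        """Return X with every missing entry imputed.

        The distance matrix is built from X itself (the estimator is
        transductive, like nearest-neighbour imputers generally): expression
        distance D, then C = (1 - H)^alpha * D when a functional-similarity
        matrix is attached.
        """
        check_is_fitted(self, "n_rows_")
        was_frame = isinstance(X, pd.DataFrame)
        X = self._check_X(X)
        if X.shape[0] != self.n_rows_ or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has shape {X.shape}; fitted for ({self.n_rows_}, {self.n_features_in_})"
            )
        D = pairwise_expression_distance(X)
        if self.similarity_ is None or self.alpha == 0:
            C = D
        else:
            C = combined_distance(D, self.similarity_, self.alpha)
        result = _impute(X, C, self.n_neighbors, self._method)
        self.imputation_result_ = result
        return result.completed if was_frame else result.completed.to_numpy()

    def _more_tags(self):  # pragma: no cover - sklearn compat
        return {"allow_nan": True}


class GOKNNImputer(_BaseGOImputer):
    """Weighted-KNN imputer whose neighbours are chosen by the combined
    GO/expression measure.

    Parameters
    ----------
    n_neighbors : int, default 5
        K; 4-5 is a good regime for miRNA arrays, whose rows are far fewer
        than mRNA arrays'.
    alpha : float, default 1.0
        Weight of GO similarity in C = (1 - H)^alpha * D; 0 recovers the
        conventional expression-only KNNimpute.
    functional_similarity : DataFrame or ndarray, optional
        The miRNA x miRNA matrix H (see :mod:`mirgoimpute.similarity`).
        When omitted the imputer is purely expression-based.

    Attributes
    ----------
    similarity_ : ndarray or None
        H aligned to the fitted row order.
    imputation_result_ : ImputationResult
        Cell-level provenance of the last :meth:`transform`.
    """

    _method = "knn"


class GOLLSImputer(_BaseGOImputer):
    """Local-least-squares imputer; GO information enters through neighbour
    selection only, so its influence is milder than in KNN.  Parameters as
    :class:`GOKNNImputer`."""

    _method = "lls"
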