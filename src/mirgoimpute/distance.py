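"""Expression distance and the combined GO/expression measure.

The expression distance between two miRNA rows is the root mean squared
difference over the samples where *both* rows hold valid values:

    d(i, j) = sqrt( sum_{s in shared} (G_is - G_js)^2 / n ),

with n the shared-sample count, so rows with different amounts of
missingness remain comparable.  A pair with no shared valid sample has an
undefined distance (NaN) and is excluded from neighbour candidacy.

The combined measure down-weights expression distance by functional
similarity:

    C_ij = (1 - H_ij)^alpha * D_ij,

alpha >= 0 setting how strongly GO knowledge steers neighbour selection;
alpha = 0 recovers D exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import read_expression, write_expression  # noqa: F401  (module surface)


def _as_values(expr) -> tuple[np.ndarray, list, bool]:
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), list(expr.index), True
    arr = np.asarray(expr, dtype=float)
    return arr, list(range(arr.shape[0])), False


def pairwise_expression_distance(expr) -> pd.DataFrame:
    """Pairwise-complete Euclidean distance between miRNA rows.

    Parameters
    ----------
    expr : DataFrame or ndarray, shape (n_mirnas, n_samples)
        NaN marks missing entries.

    Returns
    -------
    DataFrame, square and symmetric with zero diagonal; NaN where a pair
    shares no valid sample.
    """
    values, ids, _ = _as_values(expr)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("expression matrix must be 2-D with at least 2 rows")
    valid = np.isfinite(values)
    b = np.where(valid, values, 0.0)
    m = valid.astype(float)
    b2 = b * b
    # sum over shared samples of (x_i - x_j)^2, via masked cross-products
    ssd = b2 @ m.T + m @ b2.T - 2.0 * (b @ b.T)
    np.maximum(ssd, 0.0, out=ssd)  # clip fp negatives
    n = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(ssd / n)
    d[n == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


def shared_sample_counts(expr) -> pd.DataFrame:
    """Per-pair count n of samples where both rows are valid."""
    values, ids, _ = _as_values(expr)
    m = np.isfinite(values).astype(float)
    return pd.DataFrame((m @ m.T).astype(int), index=ids, columns=ids)


def combined_distance(D, H, alpha: float) -> pd.DataFrame:
    """Combine expression distance D and functional similarity H.

    ``C = (1 - H)^alpha * D`` elementwise.  Undefined (NaN) distances stay
    undefined.  Requires D and H to share one id ordering.

    Raises
    ------
    ValueError
        If alpha < 0, the id orderings differ, or H has entries outside [0, 1].
    """
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    d_vals, d_ids, d_labelled = _as_values(D)
    h_vals, h_ids, h_labelled = _as_values(H)
    if d_vals.shape != h_vals.shape:
        raise ValueError(f"shape mismatch: D {d_vals.shape} vs H {h_vals.shape}")
    if d_labelled and h_labelled and d_ids != h_ids:
        raise ValueError("D and H must share the same id ordering")
    finite_h = h_vals[np.isfinite(h_vals)]
    if finite_h.size and (finite_h.min() < 0.0 or finite_h.max() > 1.0):
        raise ValueError("similarity entries must lie in [0, 1]")
    c = (1.0 - h_vals) ** alpha * d_vals
    np.fill_diagonal(c, 0.0)
    ids = d_ids if d_labelled else h_ids
    return pd.DataFrame(c, index=ids, columns=ids)
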