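"""NRMSE scoring, alpha selection and the benchmark grid.

Imputation error is the normalised root mean square error

    NRMSE = sqrt( mean[(G_est - G_true)^2] ) / sigma[G_true],

taken by default over the artificially masked cells only (the full-matrix
variant, where observed cells contribute zero error and dilute the score by
the missing fraction, sits behind ``scope="full"``).  sigma is the
population standard deviation.

The benchmark runs a full factorial over methods x K x p; within one
repetition every configuration sees the *same* mask, so method comparisons
are paired and the expression-only and GO-based variants differ only in the
distance matrix steering neighbour selection.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import combined_distance, pairwise_expression_distance
from .impute import knn_impute, lls_impute
from .simulate import SimulationConfig, apply_mask, generate_missing_mask

DEFAULT_ALPHA_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
DEFAULT_METHODS = (
    ("knn", "expression_only"),
    ("knn", "go_based"),
    ("lls", "expression_only"),
    ("lls", "go_based"),
)

_IMPUTERS = {"knn": knn_impute, "lls": lls_impute}


def nrmse(g_est, g_true, mask=None, scope: str = "masked") -> float:
    """Normalised root mean square imputation error.

    Parameters
    ----------
    g_est, g_true : DataFrame or ndarray of identical shape
    mask : boolean array marking the artificially missing cells
        (required for ``scope="masked"``)
    scope : {"masked", "full"}
        Which cells enter the mean and the normalising sigma.
    """
    est = np.asarray(g_est, dtype=float)
    true = np.asarray(g_true, dtype=float)
    if est.shape != true.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {true.shape}")
    if scope == "full":
        err = est - true
        sigma = true.std()
    elif scope == "masked":
        if mask is None:
            raise ValueError('scope="masked" requires a mask')
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != true.shape:
            raise ValueError("mask shape does not match the matrices")
        if not mask.any():
            raise ValueError("mask marks no cells; NRMSE undefined")
        err = est[mask] - true[mask]
        sigma = true[mask].std()  # population sd
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if sigma == 0.0:
        raise ValueError("true values have zero standard deviation; NRMSE undefined")
    return float(np.sqrt(np.mean(err ** 2)) / sigma)


def _mask_rng(seed, p, rep) -> np.random.Generator:
    # one deterministic stream per (seed, p, repetition)
    return np.random.default_rng([0 if seed is None else int(seed), int(p), int(rep)])


def _align_H(H, complete: pd.DataFrame):
    if H is None:
        return None
    if isinstance(H, pd.DataFrame):
        if list(H.index) != list(complete.index):
            H = H.loc[complete.index, complete.index]
        return H.to_numpy(dtype=float)
    return np.asarray(H, dtype=float)


def select_alpha(
    complete: pd.DataFrame,
    H,
    grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    config: SimulationConfig | None = None,
    method: str = "knn",
    K: int = 5,
    scope: str = "masked",
) -> float:
    """Pick alpha by mean NRMSE over simulated masks of a complete matrix.

    Every alpha is scored on the same mask sequence (paired); ties go to the
    smallest alpha.  This is the evaluation-set protocol for tuning the GO
    weight before imputing real missingness.
    """
    if not len(grid):
        raise ValueError("alpha grid is empty")
    if config is None:
        config = SimulationConfig(p=20)
    grid = sorted(float(a) for a in grid)
    h_vals = _align_H(H, complete)
    impute = _IMPUTERS[method]
    scores = np.zeros(len(grid))
    n, s = complete.shape
    for rep in range(config.repetitions):
        rng = _mask_rng(config.seed, config.p, rep)
        mask = generate_missing_mask(n, s, config, rng)
        masked = apply_mask(complete, mask)
        D = pairwise_expression_distance(masked)
        for gi, alpha in enumerate(grid):
            C = D if alpha == 0 else combined_distance(D, h_vals, alpha)
            result = impute(masked, C, K)
            scores[gi] += nrmse(result.completed, complete, mask, scope=scope)
    return grid[int(np.argmin(scores))]


def benchmark(
    complete: pd.DataFrame,
    H,
    methods: Sequence[tuple[str, str]] = DEFAULT_METHODS,
    K_grid: Sequence[int] = (5,),
    p_grid: Sequence[int] = (40,),
    config: SimulationConfig | None = None,
    alpha: float = 1.0,
    scope: str = "masked",
) -> pd.DataFrame:
    """Full factorial benchmark on a complete matrix.

    Returns one row per (method, mode, K, p) with the NRMSE mean and sd over
    ``config.repetitions`` masks, the repetition count, alpha and seed.
    ``expression_only`` rows never touch H (the alpha = 0 path).
    """
    if complete.isna().any().any():
        raise ValueError("benchmark requires a complete matrix")
    if config is None:
        config = SimulationConfig(p=int(p_grid[0]))
    h_vals = _align_H(H, complete)
    n, s = complete.shape
    records: dict[tuple, list[float]] = {
        (m, mode, int(K), int(p)): []
        for (m, mode), K, p in itertools.product(methods, K_grid, p_grid)
    }
    for p in p_grid:
        p_cfg = SimulationConfig(p=int(p), select_fraction=config.select_fraction,
                                 repetitions=config.repetitions, seed=config.seed)
        for rep in range(config.repetitions):
            rng = _mask_rng(config.seed, p, rep)
            mask = generate_missing_mask(n, s, p_cfg, rng)
            masked = apply_mask(complete, mask)
            D = pairwise_expression_distance(masked)
            C_go = None
            for (method, mode), K in itertools.product(methods, K_grid):
                if mode == "expression_only":
                    C = D
                else:
                    if h_vals is None:
                        raise ValueError("go_based methods require H")
                    if C_go is None:
                        C_go = combined_distance(D, h_vals, alpha)
                    C = C_go
                result = _IMPUTERS[method](masked, C, int(K))
                score = nrmse(result.completed, complete, mask, scope=scope)
                records[(method, mode, int(K), int(p))].append(score)
    rows = []
    for (method, mode, K, p), scores in records.items():
        arr = np.asarray(scores)
        rows.append({
            "method": method, "mode": mode, "K": K, "p": p,
            "alpha": 0.0 if mode == "expression_only" else float(alpha),
            "mean_nrmse": float(arr.mean()),
            "sd_nrmse": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "reps": int(arr.size), "seed": config.seed,
        })
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Serialise an evaluation report as TSV or JSON records."""
    if fmt == "json":
        report.to_json(path, orient="records", indent=2)
    else:
        report.to_csv(path, sep="\t", index=False)
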