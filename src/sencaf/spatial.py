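"""Regional and point-pattern statistics on detected cells.

Consumes already-detected cell centroids (region_id, x, y, label tables) —
no image processing happens here.  Three operations: nearest-neighbour
distances from a query class to a reference class (e.g. p16+ CAFs to the
nearest cancer cell), a Welch two-sample t comparison of two distance
groups, and regional correlation (Spearman or Pearson) of, say, the
senescent-CAF fraction against T-cell density across tumor regions.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import DataError

#: Below this n, Spearman p-values are computed by exact permutation.
EXACT_SPEARMAN_MAX_N = 10


def nearest_neighbor_distances(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Euclidean distance from each query point to its closest reference
    point, in query order."""
    query = np.atleast_2d(np.asarray(query, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if reference.size == 0:
        raise DataError("reference point set is empty")
    if query.size == 0:
        return np.empty(0)
    if query.shape[1] != 2 or reference.shape[1] != 2:
        raise DataError("points must be (n, 2) arrays")
    if not (np.all(np.isfinite(query)) and np.all(np.isfinite(reference))):
        raise DataError("point coordinates must be finite")
    d, _ = cKDTree(reference).query(query)
    return np.asarray(d, dtype=float)


def points_by_label(points: pd.DataFrame, label: str) -> np.ndarray:
    """Extract the (n, 2) coordinate array of one class from a points frame."""
    sub = points[points["label"] == label]
    if len(sub) == 0:
        raise DataError(f"no points with label {label!r}")
    return sub[["x", "y"]].to_numpy(float)


def group_distance_comparison(
    d_pos: np.ndarray, d_neg: np.ndarray, equal_var: bool = False
) -> tuple[float, float, float, float]:
    """Compare two distance groups: (mean_pos, mean_neg, t, p).

    Welch's unequal-variance t test by default (appropriate for the very
    unequal group sizes typical of marker+/- comparisons); ``equal_var``
    restores the pooled test.  When both groups are constant and equal the
    test is degenerate: t=0, p=1 with a warning.
    """
    d_pos = np.asarray(d_pos, dtype=float)
    d_neg = np.asarray(d_neg, dtype=float)
    if len(d_pos) < 2 or len(d_neg) < 2:
        raise DataError("each group needs n >= 2")
    if np.ptp(d_pos) == 0 and np.ptp(d_neg) == 0:
        if d_pos[0] == d_neg[0]:
            warnings.warn("both groups constant and equal; returning t=0, p=1")
            return float(d_pos.mean()), float(d_neg.mean()), 0.0, 1.0
    t, p = stats.ttest_ind(d_pos, d_neg, equal_var=equal_var)
    return float(d_pos.mean()), float(d_neg.mean()), float(t), float(p)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho at small n.

    Enumerates all permutations of y against fixed x, using average ranks
    so ties are handled identically to the observed statistic.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rhos = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def regional_correlation(
    records: pd.DataFrame, x: str, y: str, method: str = "spearman"
) -> tuple[float, float]:
    """Correlation of two per-region quantities with a two-sided p-value.

    ``records`` holds one row per region; ``x`` and ``y`` name numeric
    columns (e.g. pct_p16_caf vs T-cell density).  Spearman uses average
    ranks for ties, with an exact permutation p below n=10 and the
    asymptotic approximation otherwise.  Constant input is an error.
    """
    if x not in records.columns or y not in records.columns:
        missing = [c for c in (x, y) if c not in records.columns]
        raise DataError(f"missing region fields: {missing}")
    xa = records[x].to_numpy(float)
    ya = records[y].to_numpy(float)
    if len(xa) < 4:
        raise DataError("need at least 4 regions")
    if np.any(~np.isfinite(xa)) or np.any(~np.isfinite(ya)):
        raise DataError("region fields contain missing or non-finite values")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DataError("zero variance in correlation input")
    if method == "pearson":
        r, p = stats.pearsonr(xa, ya)
        return float(r), float(p)
    if method != "spearman":
        raise DataError(f"unknown correlation method {method!r}")
    rho = float(stats.spearmanr(xa, ya).statistic)
    if len(xa) < EXACT_SPEARMAN_MAX_N:
        return rho, _exact_spearman_p(xa, ya, rho)
    p = float(stats.spearmanr(xa, ya).pvalue)
    return rho, p


def distance_table(points: pd.DataFrame, query_labels, reference_label: str) -> pd.DataFrame:
    """Nearest-reference distances for several query classes, long format."""
    ref = points_by_label(points, reference_label)
    rows = []
    for lbl in query_labels:
        q = points_by_label(points, lbl)
        d = nearest_neighbor_distances(q, ref)
        rows.append(pd.DataFrame({"label": lbl, "distance": d}))
    return pd.concat(rows, ignore_index=True)
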