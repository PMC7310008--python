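"""Cross-table correlation with p-values and BH correction.

The workhorse of the pipeline: every heatmap-style result and the
pseudo-gold training standard derive from the product-moment correlation
of a column of one patient-indexed table against a column of another,

    R(i, j) = sum_p (X_pi - mean X_i)(Y_pj - mean Y_j)
              / sqrt(sum_p (X_pi - mean X_i)^2) / sqrt(sum_p (Y_pj - mean Y_j)^2)

summed over the shared patients p.  Two-sided p-values come from the
t-transform with n-2 degrees of freedom (a permutation alternative is
available for small n); all pairs tested in one call form a single
Benjamini-Hochberg family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable

__all__ = ["CorrelationResult", "correlate_tables", "bh_adjust"]


@dataclass
class CorrelationResult:
    """Pairwise correlation matrices between the columns of two tables.

    ``r``/``p``/``q`` are N_i x N_j DataFrames (rows: X columns, columns:
    Y columns); ``n_used`` holds the per-pair sample size after
    pairwise-complete deletion.  Pairs involving a constant or too-sparse
    column are NaN, not zero.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    n_used: pd.DataFrame
    method: str

    def to_long(self) -> pd.DataFrame:
        """Long-format view: one row per (entity_i, entity_j) pair."""
        rows = []
        for i in self.r.index:
            for j in self.r.columns:
                rows.append((i, j, self.r.at[i, j], self.p.at[i, j],
                             self.q.at[i, j], int(self.n_used.at[i, j])))
        return pd.DataFrame(rows, columns=["entity_i", "entity_j", "r", "p", "q", "n"])


def _as_frame(table) -> pd.DataFrame:
    return table.data if isinstance(table, AbundanceTable) else table


def correlate_tables(
    X,
    Y,
    method: str = "pearson",
    n_perm: int | None = None,
    seed: int = 0,
) -> CorrelationResult:
    """Correlate every column of X against every column of Y.

    X and Y must already be harmonized (identical patient row order).
    Missing values (clinical tables) are handled by pairwise-complete
    deletion with the per-pair n recorded.  ``n_perm`` switches the
    p-values to a two-sided permutation test (useful at small n).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    xf, yf = _as_frame(X), _as_frame(Y)
    if list(xf.index) != list(yf.index):
        raise ValueError("tables are not harmonized: patient rows differ")
    xv = xf.to_numpy(dtype=float)
    yv = yf.to_numpy(dtype=float)
    has_nan = np.isnan(xv).any() or np.isnan(yv).any()

    if has_nan:
        r, n_used = _pairwise_complete(xv, yv, method)
    else:
        if method == "spearman":
            xv = stats.rankdata(xv, axis=0)
            yv = stats.rankdata(yv, axis=0)
        r = _pearson_matrix(xv, yv)
        n_used = np.full(r.shape, xv.shape[0], dtype=int)

    if np.isnan(r).any():
        warnings.warn("constant or too-sparse columns produced missing correlations")

    if n_perm is not None:
        p = _permutation_p(xv, yv, r, method, n_perm, seed)
    else:
        p = _t_pvalues(r, n_used)
    q = bh_adjust(p)
    idx, cols = xf.columns, yf.columns
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        n_used=pd.DataFrame(n_used, index=idx, columns=cols),
        method=method,
    )


def _pearson_matrix(xv: np.ndarray, yv: np.ndarray) -> np.ndarray:
    n = xv.shape[0]
    xc = xv - xv.mean(axis=0)
    yc = yv - yv.mean(axis=0)
    xs = np.sqrt((xc**2).sum(axis=0))
    ys = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / np.outer(xs, ys)
    r[:, ys == 0] = np.nan
    r[xs == 0, :] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)


def _pairwise_complete(xv, yv, method):
    ni, nj = xv.shape[1], yv.shape[1]
    r = np.full((ni, nj), np.nan)
    n_used = np.zeros((ni, nj), dtype=int)
    for i in range(ni):
        for j in range(nj):
            mask = ~(np.isnan(xv[:, i]) | np.isnan(yv[:, j]))
            n = int(mask.sum())
            n_used[i, j] = n
            if n < 3:
                continue
            a, b = xv[mask, i], yv[mask, j]
            if a.std() == 0 or b.std() == 0:
                continue
            if method == "spearman":
                a, b = stats.rankdata(a), stats.rankdata(b)
                if a.std() == 0 or b.std() == 0:
                    continue
            r[i, j] = np.corrcoef(a, b)[0, 1]
    return r, n_used


def _t_pvalues(r: np.ndarray, n_used: np.ndarray) -> np.ndarray:
    p = np.full(r.shape, np.nan)
    ok = ~np.isnan(r) & (n_used > 2)
    rr = np.clip(r[ok], -1 + 1e-15, 1 - 1e-15)
    df = n_used[ok] - 2
    t = rr * np.sqrt(df / (1 - rr**2))
    p[ok] = 2 * stats.t.sf(np.abs(t), df)
    return p


def _permutation_p(xv, yv, r_obs, method, n_perm, seed):
    rng = np.random.default_rng(seed)
    if method == "spearman":
        xv = stats.rankdata(xv, axis=0)
        yv = stats.rankdata(yv, axis=0)
    exceed = np.zeros(r_obs.shape, dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(xv.shape[0])
        r_null = _pearson_matrix(xv[perm], yv)
        exceed += np.abs(r_null) >= np.abs(r_obs) - 1e-15
    p = (exceed + 1) / (n_perm + 1)
    p[np.isnan(r_obs)] = np.nan
    return p


def bh_adjust(p) -> np.ndarray | pd.DataFrame:
    """Benjamini-Hochberg step-up over all finite entries of ``p``.

    The matrix is flattened row-major into one testing family; NaN
    entries (untestable pairs) are passed through as NaN and do not
    count toward the family size.  Output has the input's shape/type.
    """
    frame = isinstance(p, pd.DataFrame)
    arr = p.to_numpy(dtype=float) if frame else np.asarray(p, dtype=float)
    flat = arr.ravel()
    finite = ~np.isnan(flat)
    if ((flat[finite] < 0) | (flat[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(flat.shape, np.nan)
    if finite.any():
        q[finite] = multipletests(flat[finite], method="fdr_bh")[1]
    q = q.reshape(arr.shape)
    if frame:
        return pd.DataFrame(q, index=p.index, columns=p.columns)
    return q
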