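"""Supervised cell-type deconvolution by nu-support-vector regression.

A bulk expression profile is modeled as a non-negative mixture of
reference cell-type signatures, G = F S', where S' holds the expression
of ~600 signature genes in each of the reference cell types (22 in the
standard immune reference).  Per patient, the signature-gene profile is
regressed on the cell-type signatures with linear nu-SVR over a small nu
grid (the support-vector machinery performs gene selection, curbing
overfitting); negative coefficients are clipped and the rest normalized
to fractions.  Goodness of fit is a permutation p-value on the
correlation between reconstructed and observed profile.  After solving
for F, the signatures are expanded to all genes by solving the same
equation for S.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import NuSVR

from .tables import AbundanceTable

__all__ = [
    "SignatureMatrix",
    "DeconvResult",
    "fit_fractions",
    "expand_signatures",
    "aggregate_cell_types",
]

logger = logging.getLogger(__name__)

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class SignatureMatrix:
    """Reference cell-type expression over signature genes (cells x genes)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate cell-type or gene ids in signature matrix")
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any() or not np.isfinite(values).all():
            raise ValueError("signature matrix must be finite and non-negative")
        if (values.max(axis=0) == 0).any():
            dead = self.data.columns[values.max(axis=0) == 0][0]
            raise ValueError(f"signature gene {dead!r} is zero in every cell type")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    @property
    def cell_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class DeconvResult:
    """Cell fractions with per-patient fit statistics."""

    F: pd.DataFrame  # patients x cell types, rows sum to 1
    fit_r: pd.Series  # reconstruction-vs-observation correlation
    fit_p: pd.Series  # permutation p-value of fit_r
    best_nu: pd.Series
    S_expanded: pd.DataFrame | None = None


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _svr_fractions(X: np.ndarray, y: np.ndarray, nu_grid) -> tuple[np.ndarray, float, np.ndarray]:
    """Fit linear nu-SVR for each nu, keep lowest-RMSE model; return raw
    coefficients, the winning nu, and its reconstruction."""
    best = None
    for nu in nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        recon = model.predict(X)
        rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
        if best is None or rmse < best[0]:
            best = (rmse, nu, model.coef_.ravel().copy(), recon)
    _, nu, coef, recon = best
    return coef, nu, recon


def fit_fractions(
    G: AbundanceTable,
    Sref: SignatureMatrix,
    nu_grid=DEFAULT_NU_GRID,
    n_perm: int = 100,
    seed: int = 0,
) -> DeconvResult:
    """Estimate per-patient cell-type fractions from signature genes.

    Both tables are restricted to their shared genes (at least 25% of the
    signature set must be present).  The signature matrix is standardized
    globally and each patient profile per sample, which leaves the
    fraction estimates invariant to the affine rescaling.  The
    permutation null shuffles the gene labels of the patient profile and
    refits with the winning nu.
    """
    shared = [g for g in Sref.gene_ids if g in set(G.col_ids)]
    if len(shared) < 0.25 * len(Sref.gene_ids):
        raise ValueError(
            f"only {len(shared)}/{len(Sref.gene_ids)} signature genes found in "
            "the gene table; need at least 25%"
        )
    S = Sref.data[shared].to_numpy(dtype=float)  # N_f x n_shared
    X = S.T  # genes x cell types
    X = (X - X.mean()) / X.std()  # global standardization keeps columns comparable
    gmat = G.data[shared].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    n_patients = gmat.shape[0]
    n_cells = S.shape[0]
    F = np.zeros((n_patients, n_cells))
    fit_r = np.full(n_patients, np.nan)
    fit_p = np.full(n_patients, np.nan)
    best_nu = np.full(n_patients, np.nan)
    for p in range(n_patients):
        profile = gmat[p]
        if profile.max() == 0:
            logger.warning("patient %s has an all-zero profile; flagged", G.row_ids[p])
            continue
        y = _zscore(profile)
        coef, nu, recon = _svr_fractions(X, y, nu_grid)
        w = np.clip(coef, 0.0, None)
        if w.sum() == 0:
            logger.warning("patient %s: all coefficients non-positive; flagged",
                           G.row_ids[p])
            continue
        F[p] = w / w.sum()
        best_nu[p] = nu
        r_obs = np.corrcoef(recon, y)[0, 1]
        fit_r[p] = r_obs
        if n_perm > 0:
            exceed = 0
            for _ in range(n_perm):
                yp = y[rng.permutation(len(y))]
                _, _, recon_p = _svr_fractions(X, yp, (nu,))
                if np.corrcoef(recon_p, yp)[0, 1] >= r_obs - 1e-12:
                    exceed += 1
            fit_p[p] = (exceed + 1) / (n_perm + 1)

    return DeconvResult(
        F=pd.DataFrame(F, index=G.row_ids, columns=Sref.cell_ids),
        fit_r=pd.Series(fit_r, index=G.row_ids, name="fit_r"),
        fit_p=pd.Series(fit_p, index=G.row_ids, name="fit_p"),
        best_nu=pd.Series(best_nu, index=G.row_ids, name="nu"),
    )


def expand_signatures(F: pd.DataFrame, G: AbundanceTable) -> pd.DataFrame:
    """Solve G = F S for the full signature table S by least squares.

    Requires more patients than cell types and full column rank in F;
    rank-deficient inputs raise an error naming the collinear cell types.
    Negative inferred expressions are clipped to zero (count logged).
    """
    fmat = F.to_numpy(dtype=float)
    if fmat.shape[0] < fmat.shape[1]:
        raise ValueError("expand_signatures needs at least as many patients as cell types")
    rank = np.linalg.matrix_rank(fmat)
    if rank < fmat.shape[1]:
        corr = np.corrcoef(fmat.T)
        pairs = [
            (F.columns[i], F.columns[j])
            for i in range(corr.shape[0])
            for j in range(i + 1, corr.shape[0])
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"cell-fraction table is rank-deficient; collinear cell types: {pairs}")
    if list(F.index) != list(G.row_ids):
        raise ValueError("F and G are not harmonized on patients")
    S = np.linalg.pinv(fmat) @ G.values
    n_neg = int((S < 0).sum())
    if n_neg:
        logger.info("clipped %d negative inferred expression values", n_neg)
    S = np.clip(S, 0.0, None)
    return pd.DataFrame(S, index=F.columns, columns=G.col_ids)


def aggregate_cell_types(F: pd.DataFrame, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Sum fraction columns into named groups; ungrouped columns pass through."""
    members = [m for lst in groups.values() for m in lst]
    unknown = set(members) - set(F.columns)
    if unknown:
        raise ValueError(f"unknown cell types in grouping: {sorted(unknown)}")
    if len(members) != len(set(members)):
        raise ValueError("cell-type groups must be disjoint")
    out = {}
    for name, lst in groups.items():
        out[name] = F[lst].sum(axis=1)
    for col in F.columns:
        if col not in members:
            out[col] = F[col]
    return pd.DataFrame(out, index=F.index)
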