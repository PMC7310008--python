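"""Data model and I/O for patient-indexed abundance tables.

Every analysis stage works on rectangular patients x entities tables:
a gene expression table G (non-negative FPKM/TPM/RPM-like values), a
microbe relative-abundance table M, an optional clinical table C (mixed
numeric, may contain missing values) and cell-fraction tables F produced
by deconvolution.  This module provides the :class:`AbundanceTable`
container, TSV round-trip I/O, patient harmonization across tables,
taxonomic rollup of microbe columns, the integer count scaling used to
feed the collapsed Gibbs sampler, and hierarchical clustering of patients
on taxon profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "AbundanceTable",
    "LineageMap",
    "ScaledCounts",
    "TableError",
    "load_table",
    "write_table",
    "harmonize",
    "rollup_taxa",
    "scale_counts",
    "cluster_patients_by_taxa",
]

#: table kinds; gene/microbe tables must be dense and non-negative,
#: clinical tables may carry missing values of either sign.
KINDS = ("gene", "microbe", "clinical", "cellfraction")


class TableError(ValueError):
    """Raised on malformed or inconsistent table input."""


@dataclass
class AbundanceTable:
    """A patients x entities numeric matrix with identifiers.

    Parameters
    ----------
    data:
        DataFrame indexed by patient id with entity ids as columns.
    kind:
        One of ``gene``, ``microbe``, ``clinical``, ``cellfraction``.
    unit:
        Free-text declared unit of the values (e.g. ``"TPM"``); abundances
        are treated as opaque non-negative quantities downstream, the unit
        is carried as metadata only.
    """

    data: pd.DataFrame
    kind: str
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise TableError(f"unknown table kind {self.kind!r}; expected one of {KINDS}")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        _check_unique(self.data.index, "row")
        _check_unique(self.data.columns, "column")
        values = self.data.to_numpy(dtype=float)
        if self.kind in ("gene", "microbe"):
            if np.isnan(values).any():
                r, c = np.argwhere(np.isnan(values))[0]
                raise TableError(
                    f"missing value at row {self.data.index[r]!r}, "
                    f"column {self.data.columns[c]!r} in {self.kind} table"
                )
            if not np.isfinite(values).all():
                raise TableError(f"non-finite value in {self.kind} table")
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise TableError(
                    f"negative value at row {self.data.index[r]!r}, "
                    f"column {self.data.columns[c]!r} in {self.kind} table"
                )
        else:
            finite_or_nan = np.isfinite(values) | np.isnan(values)
            if not finite_or_nan.all():
                raise TableError(f"non-finite value in {self.kind} table")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise TableError(f"duplicate {what} id {dup!r}")


def load_table(path, kind: str, unit: str | None = None) -> AbundanceTable:
    """Read a TSV matrix (header row of entity ids, first column patient id)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for col in header:  # pandas silently mangles duplicate header ids
        if col in seen:
            raise TableError(f"duplicate column id {col!r} in {path}")
        seen.add(col)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:  # pragma: no cover - pandas message passthrough
        raise TableError(f"cannot parse {path}: {exc}") from exc
    frame.index.name = None
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = frame.index[bad][0]
            raise TableError(
                f"malformed numeric cell at row {row!r}, column {col!r} in {path}"
            )
        frame[col] = coerced
    return AbundanceTable(frame, kind=kind, unit=unit)


def write_table(table: AbundanceTable, path) -> None:
    """Write the table as UTF-8 TSV, mirroring the input dialect."""
    table.data.to_csv(path, sep="\t", index_label="patient")


def harmonize(tables: list[AbundanceTable]) -> list[AbundanceTable]:
    """Restrict all tables to the shared patients, in sorted order.

    Column sets are untouched.  Raises :class:`TableError` when the
    patient intersection is empty.
    """
    if len(tables) < 2:
        raise TableError("harmonize needs at least two tables")
    shared = set(tables[0].row_ids)
    for t in tables[1:]:
        shared &= set(t.row_ids)
    if not shared:
        raise TableError("no shared patients across tables")
    order = sorted(shared)
    return [AbundanceTable(t.data.loc[order], kind=t.kind, unit=t.unit) for t in tables]


@dataclass
class LineageMap:
    """Leaf taxon -> taxonomy map with named ranks.

    ``ranks`` lists the rank names available (e.g. ``["phylum"]``);
    ``lineage[leaf][rank]`` gives the taxon at that rank.  Leaves missing
    from the map, or mapped to an empty name, are routed to the
    ``"unclassified"`` bucket on rollup so per-patient totals are conserved.
    """

    lineage: dict[str, dict[str, str]]
    ranks: list[str] = field(default_factory=list)

    @classmethod
    def from_tsv(cls, path) -> "LineageMap":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        leaf_col = frame.columns[0]
        ranks = list(frame.columns[1:])
        lineage = {
            str(row[leaf_col]): {r: row[r] for r in ranks if pd.notna(row[r])}
            for _, row in frame.iterrows()
        }
        return cls(lineage=lineage, ranks=ranks)

    def at_rank(self, leaf: str, rank: str) -> str:
        entry = self.lineage.get(leaf, {})
        name = entry.get(rank)
        return name if name else "unclassified"


def rollup_taxa(M: AbundanceTable, lineage: LineageMap, rank: str) -> AbundanceTable:
    """Sum microbe columns to a coarser taxonomic rank.

    Per-patient total abundance is conserved exactly: leaves without a
    mapping at ``rank`` are pooled into an ``"unclassified"`` column.
    """
    if M.kind != "microbe":
        raise TableError("rollup_taxa expects a microbe table")
    if rank not in lineage.ranks:
        raise TableError(f"unknown rank {rank!r}; map provides {lineage.ranks}")
    groups = [lineage.at_rank(leaf, rank) for leaf in M.col_ids]
    rolled = M.data.T.groupby(pd.Index(groups, name=rank)).sum().T
    return AbundanceTable(rolled, kind="microbe", unit=M.unit)


@dataclass
class ScaledCounts:
    """Integer word counts for the Gibbs sampler, entries in [0, cap]."""

    data: pd.DataFrame
    cap: int = 1000

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise TableError("scaled counts must be integers")
        if (values < 0).any() or (values > self.cap).any():
            raise TableError(f"scaled counts must lie in [0, {self.cap}]")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)


def scale_counts(
    X: AbundanceTable | pd.DataFrame,
    divisor: float = 10.0,
    cap: int = 1000,
) -> ScaledCounts:
    """Convert abundances to capped integer counts.

    Each value is rounded to the nearest integer (round-half-to-even),
    divided by ``divisor``, floored, and capped at ``cap``.  This tames
    the token count of the Gibbs sampler while preserving the relative
    magnitudes of abundant entities.
    """
    if divisor <= 0:
        raise TableError("divisor must be positive")
    frame = X.data if isinstance(X, AbundanceTable) else X
    values = frame.to_numpy(dtype=float)
    if (values < 0).any():
        raise TableError("scale_counts requires non-negative input")
    scaled = np.minimum(np.floor(np.rint(values) / divisor), cap).astype(np.int64)
    return ScaledCounts(pd.DataFrame(scaled, index=frame.index, columns=frame.columns), cap=cap)


def cluster_patients_by_taxa(Mrank: AbundanceTable, n_clusters: int) -> pd.Series:
    """Agglomerative (Ward) clustering of patients on relative taxon profiles.

    Rows are renormalized to sum to one before clustering so the grouping
    reflects composition, not sequencing depth.  Returns a patient-indexed
    Series of integer cluster labels.
    """
    if n_clusters < 1:
        raise TableError("n_clusters must be >= 1")
    if Mrank.shape[0] < n_clusters:
        raise TableError("fewer patients than requested clusters")
    values = Mrank.values
    totals = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        profiles = np.where(totals > 0, values / totals, 0.0)
    if n_clusters == 1:
        labels = np.zeros(len(profiles), dtype=int)
    else:
        model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = model.fit_predict(profiles)
    return pd.Series(labels, index=Mrank.row_ids, name="cluster")
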