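"""Loading, validation and filtering of site-by-taxa incidence data.

The universal input of the package is an :class:`IncidenceStudy`: a binary
site (rows) x taxa (columns) presence/absence matrix together with per-site
metadata (assemblage, palaeoenvironment, ordinal depth index, lithology,
time index, geographic region).  All downstream stages (ordination, EMS
metrics, co-occurrence, gradient tests, robustness) consume this object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ASSEMBLAGES",
    "IncidenceError",
    "IncidenceStudy",
    "load_incidence",
    "subset_study",
    "drop_singletons",
    "drop_degenerate",
]

#: Closed assemblage vocabulary (canonical spellings).
ASSEMBLAGES = ("Avalon", "White Sea", "Nama", "Doushantuo", "indeterminate")

_METADATA_FIELDS = (
    "assemblage",
    "palaeoenvironment",
    "depth_index",
    "lithology",
    "time_index",
    "region",
)


class IncidenceError(ValueError):
    """Raised when incidence data violates the package's contracts."""


def _canonical_assemblage(raw: object) -> str:
    """Map a free-form assemblage string onto the closed vocabulary.

    Matching is case-insensitive and ignores surrounding whitespace.
    Unknown strings map to ``indeterminate`` with a warning rather than
    failing the load: site reclassification between published datasets is
    common and silent loss of sites would be worse.
    """
    text = str(raw).strip()
    for canon in ASSEMBLAGES:
        if text.lower() == canon.lower():
            return canon
    warnings.warn(
        f"unknown assemblage {text!r}: recorded as 'indeterminate'",
        stacklevel=3,
    )
    return "indeterminate"


@dataclass(frozen=True)
class IncidenceStudy:
    """A validated binary incidence matrix with aligned site metadata.

    Attributes
    ----------
    matrix:
        ``pandas.DataFrame`` of 0/1 integers; index = site labels,
        columns = taxon labels.
    sites:
        ``pandas.DataFrame`` of per-site metadata, same index and order as
        ``matrix``; columns include at least ``assemblage``,
        ``palaeoenvironment``, ``depth_index``, ``lithology``,
        ``time_index`` and ``region``.  Extra columns are preserved.
    provenance:
        Free-text log of the filters applied so far.
    """

    matrix: pd.DataFrame
    sites: pd.DataFrame
    provenance: str = "loaded"

    def __post_init__(self) -> None:
        validate_study(self)

    # -- basic descriptors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_occurrences(self) -> int:
        return int(self.matrix.to_numpy().sum())

    @property
    def site_labels(self) -> list:
        return list(self.matrix.index)

    @property
    def taxon_labels(self) -> list:
        return list(self.matrix.columns)

    @property
    def empty_sites(self) -> list:
        """Sites with no recorded taxa (kept for bookkeeping)."""
        sums = self.matrix.sum(axis=1)
        return list(sums.index[sums == 0])

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=np.int8)

    def assemblage_counts(self) -> dict:
        counts = self.sites["assemblage"].value_counts()
        return {a: int(counts.get(a, 0)) for a in ASSEMBLAGES}

    # -- filters (thin wrappers over the module functions) -----------------
    def subset(self, by=None, *, name: str | None = None, **field_filters):
        return subset_study(self, by, name=name, **field_filters)

    def drop_singletons(self) -> "IncidenceStudy":
        return drop_singletons(self)

    def drop_degenerate(self) -> "IncidenceStudy":
        return drop_degenerate(self)

    def with_provenance(self, note: str) -> "IncidenceStudy":
        return replace(self, provenance=f"{self.provenance}; {note}")

    def to_csv(self, matrix_path, metadata_path) -> None:
        """Write the matrix/metadata CSV pair that :func:`load_incidence` reads."""
        self.matrix.to_csv(matrix_path, index_label="site")
        self.sites.to_csv(metadata_path, index_label="site")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"IncidenceStudy({self.n_sites} sites x {self.n_taxa} taxa, "
            f"{self.n_occurrences} occurrences)"
        )


def validate_study(study: IncidenceStudy) -> None:
    """Check the IncidenceStudy invariants, raising :class:`IncidenceError`."""
    matrix, sites = study.matrix, study.sites
    if matrix.index.duplicated().any():
        dupes = sorted(set(matrix.index[matrix.index.duplicated()]))
        raise IncidenceError(f"duplicate site labels: {dupes}")
    if matrix.columns.duplicated().any():
        dupes = sorted(set(matrix.columns[matrix.columns.duplicated()]))
        raise IncidenceError(f"duplicate taxon labels: {dupes}")
    values = matrix.to_numpy()
    bad = ~np.isin(values, (0, 1))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise IncidenceError(
            f"non-binary cell at site {matrix.index[i]!r}, "
            f"taxon {matrix.columns[j]!r}: {matrix.iat[i, j]!r}"
        )
    if len(sites) != len(matrix) or list(sites.index) != list(matrix.index):
        missing = [s for s in matrix.index if s not in set(sites.index)]
        if missing:
            raise IncidenceError(f"sites without metadata: {missing}")
        raise IncidenceError("metadata rows do not align with matrix rows")
    for name in _METADATA_FIELDS:
        if name not in sites.columns:
            raise IncidenceError(f"metadata missing required column {name!r}")
    bad_assem = set(sites["assemblage"]) - set(ASSEMBLAGES)
    if bad_assem:
        raise IncidenceError(f"assemblage outside vocabulary: {sorted(bad_assem)}")
    depth = sites["depth_index"].to_numpy()
    if ((depth < 1) | (depth > 11)).any():
        raise IncidenceError("depth_index outside [1, 11]")
    time = sites["time_index"].to_numpy()
    if ((time < 1) | (time > 3)).any():
        raise IncidenceError("time_index outside [1, 3]")


def load_incidence(matrix_source, metadata_source) -> IncidenceStudy:
    """Load and validate a matrix/metadata CSV pair.

    ``matrix_source``: CSV whose first column is the site label and whose
    remaining columns are taxon labels with 0/1 cells.  ``metadata_source``:
    CSV keyed by site label with columns ``assemblage``,
    ``palaeoenvironment``, ``depth_index``, ``lithology``, ``time_index``,
    ``region``.  Metadata for sites absent from the matrix is ignored;
    matrix sites without metadata are an error.
    """
    matrix = pd.read_csv(matrix_source, index_col=0)
    matrix.index = matrix.index.astype(str).str.strip()
    matrix.columns = matrix.columns.astype(str).str.strip()
    numeric = matrix.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~numeric.isin([0, 1])
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise IncidenceError(
            f"non-binary cell at site {matrix.index[i]!r}, "
            f"taxon {matrix.columns[j]!r}: {matrix.iat[i, j]!r}"
        )
    matrix = numeric.astype(np.int8)

    meta = pd.read_csv(metadata_source, index_col=0)
    meta.index = meta.index.astype(str).str.strip()
    meta.columns = [str(c).strip().lower() for c in meta.columns]
    for name in _METADATA_FIELDS:
        if name not in meta.columns:
            raise IncidenceError(f"metadata missing required column {name!r}")
    if meta.index.duplicated().any():
        dupes = sorted(set(meta.index[meta.index.duplicated()]))
        raise IncidenceError(f"duplicate metadata site labels: {dupes}")
    orphans = [s for s in matrix.index if s not in set(meta.index)]
    if orphans:
        raise IncidenceError(f"sites without metadata: {orphans}")
    meta = meta.loc[matrix.index].copy()
    meta["assemblage"] = [_canonical_assemblage(a) for a in meta["assemblage"]]
    for col in ("palaeoenvironment", "lithology", "region"):
        meta[col] = meta[col].astype(str).str.strip()
    meta["depth_index"] = pd.to_numeric(meta["depth_index"]).astype(int)
    meta["time_index"] = pd.to_numeric(meta["time_index"]).astype(int)

    study = IncidenceStudy(matrix=matrix, sites=meta, provenance="loaded")
    return study


def _predicate_from_filters(filters: Mapping[str, object]) -> Callable:
    for name in filters:
        if name not in _METADATA_FIELDS:
            raise IncidenceError(f"unknown metadata field {name!r}")

    def pred(row: pd.Series) -> bool:
        for name, wanted in filters.items():
            value = row[name]
            if isinstance(wanted, (list, tuple, set, frozenset)):
                if value not in wanted:
                    return False
            elif value != wanted:
                return False
        return True

    return pred


def subset_study(
    study: IncidenceStudy,
    by: Callable[[pd.Series], bool] | Mapping[str, object] | None = None,
    *,
    name: str | None = None,
    **field_filters,
) -> IncidenceStudy:
    """Keep the sites matched by a metadata predicate.

    ``by`` is either a callable over a metadata row, or a mapping
    ``{field: value-or-collection}``; keyword arguments are shorthand for
    the mapping form (``assemblage="Nama"``).  Taxa left with zero
    occurrences in the subset are removed.  An empty result is an error —
    an empty study cannot be analysed.
    """
    if by is None:
        filters = dict(field_filters)
        if not filters:
            raise IncidenceError("subset_study needs a predicate")
        pred = _predicate_from_filters(filters)
        label = name or ", ".join(f"{k}={v}" for k, v in filters.items())
    elif callable(by):
        pred = by
        label = name or getattr(by, "__name__", "predicate")
    else:
        pred = _predicate_from_filters(dict(by))
        label = name or ", ".join(f"{k}={v}" for k, v in dict(by).items())

    keep = study.sites.apply(pred, axis=1).to_numpy(dtype=bool)
    if not keep.any():
        raise IncidenceError(f"subset {label!r} matches no sites")
    matrix = study.matrix.loc[keep]
    occupied = matrix.sum(axis=0) > 0
    dropped = int((~occupied).sum())
    matrix = matrix.loc[:, occupied]
    return IncidenceStudy(
        matrix=matrix,
        sites=study.sites.loc[keep],
        provenance=(
            f"{study.provenance}; subset[{label}] -> {int(keep.sum())} sites"
            f" ({dropped} absent taxa dropped)"
        ),
    )


def drop_singletons(study: IncidenceStudy) -> IncidenceStudy:
    """Remove taxa occurring at fewer than 2 sites.

    Singleton taxa disproportionately influence co-occurrence analyses.
    Sites left with no taxa are retained (see
    :attr:`IncidenceStudy.empty_sites`) so that "analysed sites" stays
    explicit bookkeeping; ordination later excludes them via
    :func:`drop_degenerate`.
    """
    occ = study.matrix.sum(axis=0)
    keep = occ >= 2
    dropped = list(occ.index[~keep])
    if not dropped:
        return study
    matrix = study.matrix.loc[:, keep]
    emptied = list(matrix.index[matrix.sum(axis=1) == 0])
    note = f"drop_singletons: removed {len(dropped)} taxa"
    if emptied:
        note += f"; {len(emptied)} sites now empty (retained): {emptied}"
    return IncidenceStudy(
        matrix=matrix, sites=study.sites, provenance=f"{study.provenance}; {note}"
    )


def drop_degenerate(study: IncidenceStudy) -> IncidenceStudy:
    """Remove all-zero rows and columns, iterating to a fixed point.

    Ordination is undefined for empty lines.  Raises if fewer than two
    rows or columns survive.
    """
    matrix = study.matrix
    removed_sites: list = []
    removed_taxa: list = []
    while True:
        row_ok = matrix.sum(axis=1) > 0
        col_ok = matrix.sum(axis=0) > 0
        if row_ok.all() and col_ok.all():
            break
        removed_sites.extend(matrix.index[~row_ok])
        removed_taxa.extend(matrix.columns[~col_ok])
        matrix = matrix.loc[row_ok, col_ok]
        if matrix.shape[0] == 0 or matrix.shape[1] == 0:
            break
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise IncidenceError("matrix too small to ordinate")
    if not removed_sites and not removed_taxa:
        return study
    note = (
        f"drop_degenerate: removed {len(removed_sites)} empty sites "
        f"and {len(removed_taxa)} empty taxa"
    )
    return IncidenceStudy(
        matrix=matrix,
        sites=study.sites.loc[matrix.index],
        provenance=f"{study.provenance}; {note}",
    )


def study_from_arrays(
    values: np.ndarray,
    site_labels: Sequence | None = None,
    taxon_labels: Sequence | None = None,
    metadata: pd.DataFrame | None = None,
    provenance: str = "constructed",
) -> IncidenceStudy:
    """Build a study from a raw 0/1 array, stubbing metadata if absent."""
    values = np.asarray(values)
    n, m = values.shape
    site_labels = list(site_labels) if site_labels is not None else [
        f"s{i+1:02d}" for i in range(n)
    ]
    taxon_labels = list(taxon_labels) if taxon_labels is not None else [
        f"t{j+1:02d}" for j in range(m)
    ]
    matrix = pd.DataFrame(values.astype(np.int8), index=site_labels, columns=taxon_labels)
    if metadata is None:
        metadata = stub_metadata(site_labels)
    return IncidenceStudy(matrix=matrix, sites=metadata, provenance=provenance)


def stub_metadata(site_labels: Iterable) -> pd.DataFrame:
    """Minimal valid metadata for toy matrices."""
    site_labels = list(site_labels)
    n = len(site_labels)
    return pd.DataFrame(
        {
            "assemblage": ["indeterminate"] * n,
            "palaeoenvironment": ["unknown"] * n,
            "depth_index": [1 + (i * 10) // max(n - 1, 1) for i in range(n)],
            "lithology": ["unknown"] * n,
            "time_index": [1] * n,
            "region": ["unknown"] * n,
        },
        index=site_labels,
    )
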