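"""Domain types, readers/writers and validation shared by every analysis stage.

The central container is :class:`CountTable`, a dense samples × ASVs matrix of
non-negative integer read counts with stable id registries.  Sample and island
metadata travel as validated :class:`pandas.DataFrame` objects;
:func:`join_metadata` ties the three together into an :class:`AnalysisBundle`
that downstream stages consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("detritus", "water", "invertebrate", "negative_control")
LOCI = ("16S", "18S")

SAMPLE_COLUMNS = ("sample_id", "island_id", "compartment", "locus", "replicate_index")
ISLAND_SIZE_FIELDS = ("detritus_weight_mg", "water_volume_ml")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant.

    ``ids`` carries every offending identifier, not just the first.
    """

    def __init__(self, message: str, ids: Sequence[str] = ()):
        self.ids = list(ids)
        if self.ids:
            message = f"{message}: {', '.join(map(str, self.ids))}"
        super().__init__(message)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dupes = []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen[i] = 1
    if dupes:
        raise ValidationError(f"duplicate {what} ids", sorted(set(dupes)))


class CountTable:
    """Samples × ASVs matrix of non-negative integer read counts."""

    def __init__(
        self,
        counts: np.ndarray | Sequence[Sequence[int]],
        sample_ids: Sequence[str],
        asv_ids: Sequence[str],
    ):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(sample_ids), len(asv_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(sample_ids)} samples x {len(asv_ids)} ASVs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                bad = np.unique(np.asarray(asv_ids)[np.where(counts != np.floor(counts))[1]])
                raise ValidationError("non-integer counts in columns", bad)
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            bad = np.unique(np.asarray(asv_ids)[np.where(counts < 0)[1]])
            raise ValidationError("negative counts in columns", bad)
        _check_unique(sample_ids, "sample")
        _check_unique(asv_ids, "ASV")
        self.counts = np.ascontiguousarray(counts, dtype=np.int64)
        self.sample_ids = list(map(str, sample_ids))
        self.asv_ids = list(map(str, asv_ids))

    # -- basic protocol -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"CountTable({len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs)"

    # -- conversions --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountTable":
        return cls(frame.to_numpy(), list(frame.index), list(frame.columns))

    # -- selections ---------------------------------------------------------
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def asv_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def select_samples(self, keep: Iterable[str] | np.ndarray) -> "CountTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            missing = [s for s in keep if s not in pos]
            if missing:
                raise ValidationError("unknown sample ids", missing)
            idx = np.array([pos[s] for s in keep], dtype=int)
        return CountTable(
            self.counts[idx], [self.sample_ids[i] for i in idx], self.asv_ids
        )

    def select_asvs(self, keep: Iterable[str] | np.ndarray) -> "CountTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {a: i for i, a in enumerate(self.asv_ids)}
            missing = [a for a in keep if a not in pos]
            if missing:
                raise ValidationError("unknown ASV ids", missing)
            idx = np.array([pos[a] for a in keep], dtype=int)
        return CountTable(
            self.counts[:, idx], self.sample_ids, [self.asv_ids[i] for i in idx]
        )

    def drop_empty(self) -> "CountTable":
        """Remove all-zero samples and ASVs."""
        t = self
        if t.shape[0]:
            t = t.select_samples(t.sample_totals() > 0)
        if t.shape[1]:
            t = t.select_asvs(t.asv_totals() > 0)
        return t


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.ids = list(map(str, self.ids))
        _check_unique(self.ids, "object")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, rtol=0, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > 0):
            raise ValidationError("distance matrix diagonal is not zero")
        # exact symmetry and zero diagonal after validation
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    def condensed(self) -> np.ndarray:
        """Upper triangle, unfolded row-major (scipy ``squareform`` order)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ValidationError("unknown ids in reorder", missing)
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# metadata validation
# ---------------------------------------------------------------------------

def validate_sample_metadata(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError("sample metadata missing columns", missing)
    bad_comp = sorted(set(samples["compartment"]) - set(COMPARTMENTS))
    if bad_comp:
        raise ValidationError("unknown compartment values", bad_comp)
    bad_locus = sorted(set(samples["locus"]) - set(LOCI))
    if bad_locus:
        raise ValidationError("unknown locus values", bad_locus)
    _check_unique(list(samples["sample_id"]), "sample")
    controls = samples["compartment"] == "negative_control"
    no_island = samples["island_id"].isna() | (samples["island_id"] == "")
    orphans = samples.loc[~controls & no_island, "sample_id"].tolist()
    if orphans:
        raise ValidationError("non-control samples without island_id", orphans)
    if (samples["replicate_index"] < 1).any():
        bad = samples.loc[samples["replicate_index"] < 1, "sample_id"].tolist()
        raise ValidationError("replicate_index must be >= 1", bad)
    return samples


def validate_island_metadata(islands: pd.DataFrame) -> pd.DataFrame:
    if "island_id" not in islands.columns:
        raise ValidationError("island metadata missing columns", ["island_id"])
    _check_unique(list(islands["island_id"]), "island")
    for col in ISLAND_SIZE_FIELDS:
        if col in islands.columns and (islands[col] <= 0).any():
            bad = islands.loc[islands[col] <= 0, "island_id"].tolist()
            raise ValidationError(f"{col} must be positive", bad)
    if "complexity" in islands.columns and (islands["complexity"] < 1).any():
        bad = islands.loc[islands["complexity"] < 1, "island_id"].tolist()
        raise ValidationError("complexity (leaf count) must be >= 1", bad)
    return islands


@dataclass
class AnalysisBundle:
    """A count table joined with validated sample and island metadata."""

    table: CountTable
    samples: pd.DataFrame
    islands: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def samples_for(self, compartment: str | None = None, locus: str | None = None) -> pd.DataFrame:
        sel = self.samples
        if compartment is not None:
            sel = sel[sel["compartment"] == compartment]
        if locus is not None:
            sel = sel[sel["locus"] == locus]
        return sel


def join_metadata(
    table: CountTable, samples: pd.DataFrame, islands: pd.DataFrame
) -> AnalysisBundle:
    """Join a count table with its sample and island metadata.

    Every table sample must have metadata; metadata rows without a table
    sample (and islands without samples) are reported as warnings only.
    """
    samples = validate_sample_metadata(samples)
    islands = validate_island_metadata(islands)
    meta_ids = set(samples["sample_id"])
    missing = [s for s in table.sample_ids if s not in meta_ids]
    if missing:
        raise ValidationError("table samples without metadata", missing)
    known_islands = set(islands["island_id"])
    controls = samples["compartment"] == "negative_control"
    bad_islands = sorted(
        set(samples.loc[~controls, "island_id"]) - known_islands
    )
    if bad_islands:
        raise ValidationError("samples reference unknown islands", bad_islands)
    notes = []
    unused_samples = sorted(meta_ids - set(table.sample_ids))
    if unused_samples:
        notes.append(f"metadata rows without table samples: {', '.join(unused_samples)}")
    used_islands = set(samples.loc[~controls, "island_id"])
    unused_islands = sorted(known_islands - used_islands)
    if unused_islands:
        notes.append(f"islands without samples: {', '.join(unused_islands)}")
    for n in notes:
        warnings.warn(n, stacklevel=2)
    ordered = samples.set_index("sample_id").loc[table.sample_ids].reset_index()
    return AnalysisBundle(table, ordered, islands.reset_index(drop=True), notes)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv", transpose: bool = False) -> CountTable:
    """Read a count table.

    TSV dialect: first column sample ids, header row ASV ids; ``transpose``
    accepts the ASVs-as-rows dialect.  ``format="biom"`` reads minimal
    BIOM v2.1 (HDF5).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "biom":
        return _read_biom(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise ValidationError(f"malformed count TSV {path}: {exc}") from exc
    if frame.columns.size == 0:
        raise ValidationError(f"count TSV {path} has no ASV columns (malformed header)")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        # name the offending row/column
        for col in frame.columns:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            if coerced.isna().any():
                row = frame.index[coerced.isna()][0]
                raise ValidationError(
                    f"non-numeric count at row {row!r}, column {col!r}"
                ) from exc
        raise
    if transpose:
        values = values.T
        return CountTable(values, list(frame.columns), list(frame.index))
    return CountTable(values, list(frame.index), list(frame.columns))


def write_count_table(table: CountTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "biom":
        _write_biom(table, path)
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}")
    table.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "island_id": str})
    return validate_sample_metadata(frame)


def read_island_metadata(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"island_id": str})
    return validate_island_metadata(frame)


# ---------------------------------------------------------------------------
# minimal BIOM v2.1 (HDF5) support
# ---------------------------------------------------------------------------
# The BIOM 2.1 layout stores the matrix twice, CSR by observation (ASV) and
# CSR by sample.  We write both plus the required root attributes; reading
# uses the sample-major group.  Only the count matrix and id registries are
# carried (no per-axis metadata).

def _write_biom(table: CountTable, path: Path) -> None:
    import h5py
    from scipy import sparse

    mat = sparse.csr_matrix(table.counts.astype(np.float64))
    obs = sparse.csr_matrix(table.counts.T.astype(np.float64))
    with h5py.File(path, "w") as h5:
        h5.attrs["id"] = "No Table ID"
        h5.attrs["type"] = "OTU table"
        h5.attrs["format-url"] = "http://biom-format.org"
        h5.attrs["format-version"] = (2, 1)
        h5.attrs["generated-by"] = "islesar"
        h5.attrs["creation-date"] = "1970-01-01T00:00:00"
        h5.attrs["shape"] = (len(table.asv_ids), len(table.sample_ids))
        h5.attrs["nnz"] = int(mat.nnz)
        enc = h5py.string_dtype(encoding="utf-8")
        h5.create_dataset("observation/ids", data=np.array(table.asv_ids, dtype=enc))
        h5.create_dataset("sample/ids", data=np.array(table.sample_ids, dtype=enc))
        for grp, m in (("observation", obs), ("sample", mat)):
            h5.create_dataset(f"{grp}/matrix/data", data=m.data)
            h5.create_dataset(f"{grp}/matrix/indices", data=m.indices.astype(np.int32))
            h5.create_dataset(f"{grp}/matrix/indptr", data=m.indptr.astype(np.int32))
            for sub in ("metadata", "group-metadata"):
                h5.create_group(f"{grp}/{sub}")


def _read_biom(path: Path) -> CountTable:
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as h5:
        sample_ids = [s.decode() if isinstance(s, bytes) else s for s in h5["sample/ids"][:]]
        asv_ids = [s.decode() if isinstance(s, bytes) else s for s in h5["observation/ids"][:]]
        data = h5["sample/matrix/data"][:]
        indices = h5["sample/matrix/indices"][:]
        indptr = h5["sample/matrix/indptr"][:]
    mat = sparse.csr_matrix((data, indices, indptr), shape=(len(sample_ids), len(asv_ids)))
    return CountTable(np.asarray(mat.todense()), sample_ids, asv_ids)
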