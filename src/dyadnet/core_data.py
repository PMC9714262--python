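"""Data model and I/O for count tables, sample metadata, and distance matrices.

Count tables are oriented taxa-rows x sample-columns. Transposed input is
never guessed: the first column must hold taxon labels and the header row
sample ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KINGDOMS = ("bacteria", "fungi")
SAMPLE_TYPES = ("milk", "feces_1mo", "feces_6mo")
BIRTH_MODES = ("vaginal", "cesarean")
ABX_FLAGS = (
    "prenatal_abx",
    "perinatal_abx",
    "maternal_postpartum_abx",
    "infant_postnatal_abx",
)
REQUIRED_META_COLUMNS = (
    "sample_id",
    "subject_id",
    "dyad_id",
    "sample_type",
    "birth_mode",
) + ABX_FLAGS

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise DataError(f"duplicate {what}: {', '.join(sorted(dups))}")


@dataclass
class TaxaTable:
    """A taxa x samples abundance matrix for one kingdom.

    ``scale`` is ``"counts"`` for raw (non-negative) read counts and
    ``"relative"`` for per-sample proportions summing to 1.
    """

    kingdom: str
    taxa_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise DataError(f"unknown kingdom {self.kingdom!r}; expected one of {KINGDOMS}")
        if self.scale not in ("counts", "relative"):
            raise DataError(f"unknown scale {self.scale!r}")
        self.taxa_ids = list(self.taxa_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.taxa_ids, "taxa ids")
        _check_unique(self.sample_ids, "sample ids")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if self.n_taxa < 1 or self.n_samples < 2:
            raise DataError("need at least 1 taxon and 2 samples")
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            i, j = neg[0]
            raise DataError(
                f"negative value at taxon {self.taxa_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        if self.scale == "relative":
            sums = self.counts.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
                raise DataError(f"relative-scale column {bad!r} does not sum to 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def select_samples(self, sample_ids: Iterable[str]) -> "TaxaTable":
        """Return a new table restricted to ``sample_ids`` in the given order."""
        ids = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise DataError(f"samples not in table: {', '.join(missing)}")
        idx = [pos[s] for s in ids]
        return replace(self, sample_ids=ids, counts=self.counts[:, idx])

    def select_taxa(self, taxa_ids: Iterable[str]) -> "TaxaTable":
        ids = list(taxa_ids)
        pos = {t: i for i, t in enumerate(self.taxa_ids)}
        missing = [t for t in ids if t not in pos]
        if missing:
            raise DataError(f"taxa not in table: {', '.join(missing)}")
        idx = [pos[t] for t in ids]
        return replace(self, taxa_ids=ids, counts=self.counts[idx, :])


@dataclass
class SampleMetadata:
    """Per-sample design variables, including dyad linkage.

    Backed by a DataFrame indexed by sample_id; free covariates beyond the
    mandatory columns are carried through untouched.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if "sample_id" in df.columns:
            df = df.set_index("sample_id")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids in metadata: {dups}")
        for col in REQUIRED_META_COLUMNS:
            if col != "sample_id" and col not in df.columns:
                raise DataError(f"metadata missing required column {col!r}")
        bad_types = set(df["sample_type"]) - set(SAMPLE_TYPES)
        if bad_types:
            raise DataError(
                f"invalid sample_type values {sorted(bad_types)}; expected {SAMPLE_TYPES}"
            )
        bad_modes = set(df["birth_mode"]) - set(BIRTH_MODES)
        if bad_modes:
            raise DataError(
                f"invalid birth_mode values {sorted(bad_modes)}; expected {BIRTH_MODES}"
            )
        for col in ABX_FLAGS:
            df[col] = [_parse_bool(v, col) for v in df[col]]
        self.frame = df

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].copy())

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.frame.index

    def column(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise DataError(f"metadata has no column {name!r}")
        return self.frame[name]


def _parse_bool(value, col: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise DataError(f"cannot parse boolean {value!r} in column {col!r}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities under a named metric."""

    sample_ids: list[str]
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.sample_ids, "sample ids")
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise DataError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-8):
            raise DataError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-8):
            raise DataError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise DataError("distance matrix has negative entries")
        self.values = v

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise DataError(f"samples not in distance matrix: {', '.join(missing)}")
        idx = np.array([pos[s] for s in ids])
        return DistanceMatrix(ids, self.metric, self.values[np.ix_(idx, idx)])

    def between(self, a: str, b: str) -> float:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return float(self.values[pos[a], pos[b]])


# ---------------------------------------------------------------------------
# readers / writers


def read_taxa_table(path, kingdom: str) -> TaxaTable:
    """Read a tab-separated taxa x samples count table.

    First column: taxon label. Header row: sample ids. Values may be
    integers or decimals; negatives, ragged rows, and duplicate ids are
    hard errors.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise DataError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        _check_unique(sample_ids, "sample ids")
        taxa: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise DataError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {len(cols)})"
                )
            taxa.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as e:
                raise DataError(f"{path}:{lineno}: non-numeric value ({e})") from None
    _check_unique(taxa, "taxa ids")
    return TaxaTable(kingdom=kingdom, taxa_ids=taxa, sample_ids=sample_ids,
                     counts=np.array(rows, dtype=float))


def write_taxa_table(table: TaxaTable, path) -> None:
    """Write a table as TSV; integer-valued counts are written without decimals."""
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(table.sample_ids) + "\n")
        integral = table.scale == "counts" and np.allclose(
            table.counts, np.round(table.counts)
        )
        for t, row in zip(table.taxa_ids, table.counts):
            if integral:
                cells = [str(int(round(x))) for x in row]
            else:
                cells = [repr(float(x)) for x in row]
            fh.write(t + "\t" + "\t".join(cells) + "\n")


def read_biom_json(path, kingdom: str) -> TaxaTable:
    """Read a BIOM format 1.0 (JSON) observation table.

    Supports dense and sparse matrix_type; observation ids become taxa ids.
    """
    import json

    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    counts = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "dense":
        counts[:] = np.asarray(doc["data"], dtype=float)
    else:
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    return TaxaTable(kingdom=kingdom, taxa_ids=taxa, sample_ids=samples,
                     counts=counts)


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str,
                                            "dyad_id": str})
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.frame.copy()
    for col in ABX_FLAGS:
        df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", index_label="sample_id")


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dist.values, index=dist.sample_ids, columns=dist.sample_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path, metric: str = "unknown") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), metric, df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# transforms


def to_relative(table: TaxaTable) -> TaxaTable:
    """Convert counts to within-sample proportions (columns sum to 1)."""
    if table.scale != "counts":
        raise DataError("to_relative expects a counts-scale table")
    sums = table.counts.sum(axis=0)
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        names = [table.sample_ids[i] for i in zero]
        raise DataError(f"all-zero sample column(s): {', '.join(names)}")
    return replace(table, counts=table.counts / sums, scale="relative")


def drop_zero_samples(table: TaxaTable) -> TaxaTable:
    """Drop all-zero sample columns with a logged warning."""
    sums = table.counts.sum(axis=0)
    keep = [s for s, tot in zip(table.sample_ids, sums) if tot > 0]
    dropped = table.n_samples - len(keep)
    if dropped:
        logger.warning("dropping %d zero-count sample(s) from %s table",
                       dropped, table.kingdom)
        return table.select_samples(keep)
    return table


def align_paired(
    bact: TaxaTable, fung: TaxaTable, meta: SampleMetadata
) -> tuple[TaxaTable, TaxaTable, SampleMetadata]:
    """Restrict paired tables and metadata to the shared sample set.

    Samples missing from either kingdom or from the metadata are dropped
    and counted per reason; the returned tables share one sample ordering
    (bacterial-table order of the intersection).
    """
    bact_set = set(bact.sample_ids)
    fung_set = set(fung.sample_ids)
    meta_set = set(meta.sample_ids)
    shared = [s for s in bact.sample_ids if s in fung_set and s in meta_set]
    n_no_fung = len(bact_set - fung_set)
    n_no_bact = len(fung_set - bact_set)
    n_no_meta = len((bact_set & fung_set) - meta_set)
    if n_no_fung or n_no_bact or n_no_meta:
        logger.info(
            "align_paired dropped samples: %d lacking fungal data, "
            "%d lacking bacterial data, %d lacking metadata",
            n_no_fung, n_no_bact, n_no_meta,
        )
    if not shared:
        raise DataError("no samples shared between the two kingdoms and metadata")
    return (
        bact.select_samples(shared),
        fung.select_samples(shared),
        meta.subset(shared),
    )
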