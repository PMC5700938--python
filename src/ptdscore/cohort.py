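"""Cohort containers, count-table IO, inclusion filtering and gestational-age grouping.

A cohort is an OTU-level count table (taxa x samples) optionally bound to
per-sample metadata (subject, study, gestational week at sampling, delivery
outcome).  The canonical on-disk format is a BIOM-classic-compatible TSV
(taxa as rows, first header cell ``#OTU_ID``); BIOM v1 JSON is supported at
the interface but never required.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Delivery-outcome labels. PTD (preterm delivery) is the positive class
#: everywhere in this package.
TERM = "TERM"
PTD = "PTD"

_OUTCOME_ALIASES = {
    "term": TERM,
    "full-term": TERM,
    "full_term": TERM,
    "fullterm": TERM,
    "td": TERM,
    "ptd": PTD,
    "preterm": PTD,
    "pre-term": PTD,
    "pre_term": PTD,
}

METADATA_COLUMNS = ("sample_id", "subject_id", "study_id", "gestation_week", "outcome")

MAX_GESTATION_WEEK = 45.0


def normalize_outcome(value: object) -> str:
    """Map a free-form outcome label onto {TERM, PTD}, case-insensitively."""
    key = str(value).strip().lower()
    if key not in _OUTCOME_ALIASES:
        raise ValueError(
            f"unrecognized outcome label {value!r}; expected one of "
            f"{sorted(set(_OUTCOME_ALIASES))}"
        )
    return _OUTCOME_ALIASES[key]


@dataclass(frozen=True)
class TaxonomicProfile:
    """One sample's OTU counts over the cohort taxon universe."""

    sample_id: str
    counts: np.ndarray
    taxon_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or len(counts) != len(self.taxon_ids):
            raise ValueError("counts must be a vector aligned with taxon_ids")
        if np.any(counts < 0):
            raise ValueError(f"sample {self.sample_id!r} has negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def depth(self) -> int:
        """Total taxonomically assigned reads."""
        return int(self.counts.sum())

    @property
    def rel_abundance(self) -> np.ndarray:
        """Relative abundances (sum to 1); zero-depth profiles yield zeros."""
        depth = self.counts.sum()
        if depth == 0:
            return np.zeros(len(self.counts), dtype=float)
        return self.counts / depth

    @property
    def observed_richness(self) -> int:
        return int((self.counts > 0).sum())


@dataclass(frozen=True)
class SampleRecord:
    """Metadata binding one profile to subject, study, week and outcome."""

    sample_id: str
    subject_id: str
    study_id: str
    gestation_week: float
    outcome: str

    def __post_init__(self) -> None:
        if not 0 < self.gestation_week <= MAX_GESTATION_WEEK:
            raise ValueError(
                f"sample {self.sample_id!r}: gestation_week must be in "
                f"(0, {MAX_GESTATION_WEEK}], got {self.gestation_week}"
            )
        object.__setattr__(self, "outcome", normalize_outcome(self.outcome))


@dataclass(frozen=True)
class WeekGroup:
    """A named set of sample ids defined by gestational age at sampling."""

    label: str
    members: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.members)


class Cohort:
    """A count table plus (optionally) aligned per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, taxa as rows (index = OTU ids),
        samples as columns.
    metadata
        Optional DataFrame indexed by sample_id with columns subject_id,
        study_id, gestation_week, outcome.  When present it must match the
        count table's samples one-to-one.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame | None = None):
        if counts.columns.duplicated().any():
            dupes = sorted(counts.columns[counts.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids in count table: {dupes}")
        if counts.index.duplicated().any():
            dupes = sorted(counts.index[counts.index.duplicated()].unique())
            raise ValueError(f"duplicate OTU ids in count table: {dupes}")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("count table contains non-numeric entries")
        if arr.size and (arr < 0).any():
            row, col = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at OTU {counts.index[row]!r}, "
                f"sample {counts.columns[col]!r}"
            )
        self.counts = counts.astype(np.int64, copy=False)
        if metadata is not None:
            metadata = _conform_metadata(metadata, list(counts.columns))
        self.metadata = metadata

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxon_universe(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def outcomes(self) -> pd.Series:
        self._require_metadata()
        return self.metadata["outcome"]

    @property
    def weeks(self) -> pd.Series:
        self._require_metadata()
        return self.metadata["gestation_week"]

    def _require_metadata(self) -> None:
        if self.metadata is None:
            raise ValueError("cohort has no attached metadata")

    def profile(self, sample_id: str) -> TaxonomicProfile:
        return TaxonomicProfile(
            sample_id=sample_id,
            counts=self.counts[sample_id].to_numpy(),
            taxon_ids=tuple(self.counts.index),
        )

    def profiles(self) -> Iterator[TaxonomicProfile]:
        taxa = tuple(self.counts.index)
        for sid in self.counts.columns:
            yield TaxonomicProfile(sid, self.counts[sid].to_numpy(), taxa)

    def records(self) -> Iterator[SampleRecord]:
        self._require_metadata()
        for sid, row in self.metadata.iterrows():
            yield SampleRecord(
                sample_id=str(sid),
                subject_id=str(row["subject_id"]),
                study_id=str(row["study_id"]),
                gestation_week=float(row["gestation_week"]),
                outcome=str(row["outcome"]),
            )

    def subset(self, sample_ids: Sequence[str]) -> "Cohort":
        ids = list(sample_ids)
        missing = sorted(set(ids) - set(self.counts.columns))
        if missing:
            raise KeyError(f"sample ids not in cohort: {missing}")
        meta = self.metadata.loc[ids] if self.metadata is not None else None
        return Cohort(self.counts[ids], meta)

    def __len__(self) -> int:
        return self.n_samples

    def __repr__(self) -> str:
        meta = "with" if self.metadata is not None else "without"
        return (
            f"<Cohort: {self.n_samples} samples x {self.n_taxa} taxa, "
            f"{meta} metadata>"
        )


def _conform_metadata(metadata: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    meta = metadata.copy()
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    required = {"subject_id", "study_id", "gestation_week", "outcome"}
    missing_cols = sorted(required - set(meta.columns))
    if missing_cols:
        raise ValueError(f"metadata missing required columns: {missing_cols}")
    orphans = sorted(set(sample_ids) - set(meta.index))
    if orphans:
        raise ValueError(
            f"{len(orphans)} profile(s) have no metadata row: {orphans[:10]}"
        )
    extra = sorted(set(meta.index) - set(sample_ids))
    if extra:
        logger.warning(
            "metadata has %d row(s) with no matching profile "
            "(first few: %s); dropping them", len(extra), extra[:5],
        )
    meta = meta.loc[sample_ids]
    week = pd.to_numeric(meta["gestation_week"], errors="coerce")
    bad = meta.index[week.isna()]
    if len(bad):
        raise ValueError(f"non-numeric gestation_week for samples: {list(bad[:10])}")
    if ((week <= 0) | (week > MAX_GESTATION_WEEK)).any():
        bad = meta.index[(week <= 0) | (week > MAX_GESTATION_WEEK)]
        raise ValueError(
            f"gestation_week outside (0, {MAX_GESTATION_WEEK}] for samples: "
            f"{list(bad[:10])}"
        )
    meta["gestation_week"] = week.astype(float)
    meta["outcome"] = meta["outcome"].map(normalize_outcome)
    meta["subject_id"] = meta["subject_id"].astype(str)
    meta["study_id"] = meta["study_id"].astype(str)
    return meta[["subject_id", "study_id", "gestation_week", "outcome"]]


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv") -> Cohort:
    """Read a taxa-x-samples count table (TSV or BIOM v1 JSON) into a Cohort.

    The TSV dialect is taxa as rows, samples as columns, first column the
    OTU id (header cell ``#OTU_ID`` by convention), header row the sample
    ids.  Unparseable numeric cells raise an error naming the offending
    row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom":
        return _read_biom_v1(path)
    raise ValueError(f"unknown count-table format {format!r}")


def _read_tsv(path: Path) -> Cohort:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    dupes = sorted({sid for sid in header if sid in seen or seen.add(sid)})
    if dupes:
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"unparseable count {raw.iat[bad[0], bad[1]]!r} at "
            f"OTU {raw.index[bad[0]]!r}, sample {raw.columns[bad[1]]!r} in {path}"
        )
    counts = numeric
    counts.index = counts.index.astype(str)
    counts.index.name = "#OTU_ID"
    counts.columns = counts.columns.astype(str)
    return Cohort(counts)


def _read_biom_v1(path: Path) -> Cohort:
    with open(path) as fh:
        doc = json.load(fh)
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    n_rows, n_cols = doc["shape"]
    mat = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    counts = pd.DataFrame(mat, index=rows, columns=cols)
    counts.index.name = "#OTU_ID"
    return Cohort(counts)


def write_count_table(cohort: Cohort, path: str | Path, format: str = "tsv") -> None:
    """Write the cohort's counts; inverse of :func:`read_count_table`."""
    path = Path(path)
    if format == "tsv":
        out = cohort.counts.copy()
        out.index.name = "#OTU_ID"
        out.to_csv(path, sep="\t")
    elif format == "biom":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "ptdscore",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [cohort.n_taxa, cohort.n_samples],
            "rows": [{"id": t, "metadata": None} for t in cohort.taxon_universe],
            "columns": [{"id": s, "metadata": None} for s in cohort.sample_ids],
            "data": cohort.counts.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown count-table format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata CSV (sample_id, subject_id, study_id,
    gestation_week, outcome)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    meta = pd.read_csv(path, dtype=str)
    missing = sorted(set(METADATA_COLUMNS) - set(meta.columns))
    if missing:
        raise ValueError(f"metadata {path} missing columns: {missing}")
    return meta


def attach_metadata(cohort: Cohort, metadata: str | Path | pd.DataFrame) -> Cohort:
    """Bind a metadata table (path or DataFrame) to a cohort's profiles."""
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    return Cohort(cohort.counts, metadata)


def write_metadata(cohort: Cohort, path: str | Path) -> None:
    cohort._require_metadata()
    out = cohort.metadata.reset_index(names="sample_id")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inclusion filter and gestational-age grouping
# ---------------------------------------------------------------------------

def filter_min_depth(cohort: Cohort, min_reads: int = 500) -> Cohort:
    """Retain samples with at least ``min_reads`` taxonomically assigned reads.

    The boundary is inclusive: a sample with exactly ``min_reads`` reads is
    kept.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    keep = cohort.depths >= min_reads
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "filter_min_depth(%d): removed %d of %d samples",
            min_reads, removed, cohort.n_samples,
        )
    return cohort.subset(list(cohort.counts.columns[keep]))


def cumulative_week_groups(
    cohort: Cohort,
    n_min: int = 8,
    n_max: int = 40,
    per_subject: bool = False,
) -> list[WeekGroup]:
    """Form cumulative Week_N groups: all samples taken on or before week N.

    Groups are nested (Week_N is a subset of Week_{N+1}) and membership is
    per sample.  With ``per_subject=True`` only each subject's latest sample
    at or before week N is kept (a leakage-averse alternative).
    """
    if n_min > n_max:
        raise ValueError("n_min must not exceed n_max")
    cohort._require_metadata()
    meta = cohort.metadata
    groups = []
    for n in range(n_min, n_max + 1):
        in_group = meta[meta["gestation_week"] <= n]
        if per_subject:
            in_group = (
                in_group.sort_values("gestation_week")
                .groupby("subject_id", sort=False)
                .tail(1)
            )
        members = tuple(in_group.index)
        if not members:
            logger.info("Week_%d group is empty", n)
        groups.append(WeekGroup(label=f"Week_{n}", members=members))
    return groups


def sliding_week_windows(
    cohort: Cohort,
    n_windows: int = 15,
    width: float = 6.0,
    step: float = 2.5,
    start: float = 1.0,
) -> list[WeekGroup]:
    """Form overlapping gestational-age windows [lo, lo + width).

    Used for week-resolved trend summaries; a sample may fall in several
    windows.  The default (15 windows of width 6 starting at week 1, step
    2.5) covers weeks 1-40 with ~58% overlap between neighbours.
    """
    if not width > step > 0:
        raise ValueError("need width > step > 0 for overlapping windows")
    cohort._require_metadata()
    weeks = cohort.metadata["gestation_week"]
    last_end = start + (n_windows - 1) * step + width
    if len(weeks) and last_end < weeks.max():
        raise ValueError(
            f"{n_windows} windows of width {width} (step {step}) starting at "
            f"week {start} end at {last_end}, before the latest sample "
            f"(week {weeks.max()})"
        )
    groups = []
    for i in range(n_windows):
        lo = start + i * step
        hi = lo + width
        members = tuple(weeks.index[(weeks >= lo) & (weeks < hi)])
        groups.append(WeekGroup(label=f"Weeks_{lo:g}-{hi:g}", members=members))
    return groups
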