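"""Domain types, validation and delimited-text I/O for bioactivity records.

An activity record is one compound--target--assay measurement carrying the
confidence attributes (assay relationship type, assay confidence score,
target type, organism), the measurement descriptors (type, relation, value,
free-text comment) and the release year of the record.  Tables are plain
delimited text (TSV by default) with a header row; the empty string encodes
a missing value.  Release dates finer than a year are truncated to the
calendar year, the resolution at which all downstream statistics operate.
"""

from __future__ import annotations

import datetime
import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical column order for activity tables.
CANONICAL_COLUMNS = [
    "compound_id",
    "target_id",
    "target_type",
    "organism",
    "assay_id",
    "relationship_type",
    "confidence_score",
    "measurement_type",
    "measurement_relation",
    "activity_comment",
    "release_year",
    "measurement_value",
]

_ID_COLUMNS = ["compound_id", "target_id", "assay_id"]
_CURRENT_YEAR = datetime.date.today().year
#: Default plausible range for release years.
DEFAULT_YEAR_RANGE = (1900, _CURRENT_YEAR)

_YEAR_RE = re.compile(r"^(\d{4})(\D.*)?$")


class SchemaError(ValueError):
    """The input table violates the expected schema (missing/empty columns)."""


@dataclass(frozen=True)
class ActivityRecord:
    """One compound--target--assay measurement with confidence attributes.

    ``None`` encodes a missing value for the optional fields.  Identifiers
    are opaque strings (ChEMBL-ID role); ``confidence_score`` is the 0--9
    assay-to-target confidence rating, 9 meaning a direct single-protein
    assignment.
    """

    compound_id: str
    target_id: str
    assay_id: str
    target_type: str = ""
    organism: str = ""
    relationship_type: str = ""
    confidence_score: int | None = None
    measurement_type: str = ""
    measurement_relation: str = ""
    activity_comment: str = ""
    release_year: int | None = None
    measurement_value: float | None = None

    def __post_init__(self) -> None:
        for name in _ID_COLUMNS:
            if not getattr(self, name):
                raise ValueError(f"{name} must be a non-empty string")
        if self.confidence_score is not None and not (
            0 <= int(self.confidence_score) <= 9
        ):
            raise ValueError(
                f"confidence_score must be in [0, 9], got {self.confidence_score}"
            )
        if self.measurement_value is not None and self.measurement_value < 0:
            raise ValueError("measurement_value must be non-negative")


@dataclass
class ValidationReport:
    """Accounting of a table read: rows read, retained, rejected and why.

    Conservation: ``n_records_read == n_retained + n_rejected``, where
    rejected rows include exact duplicates (reason ``"duplicate_record"``).
    """

    n_records_read: int = 0
    n_retained: int = 0
    n_rejected: int = 0
    rejection_reasons: dict[str, int] = field(default_factory=dict)
    n_missing_release_year: int = 0

    @property
    def n_duplicates_removed(self) -> int:
        return self.rejection_reasons.get("duplicate_record", 0)


class Dataset:
    """A validated, deduplicated collection of activity records.

    Thin wrapper around a :class:`pandas.DataFrame` with the canonical
    columns; rows are records.  Lookups by compound, target, assay and year
    are exposed as lazily built row-position indices.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = "", *, validate: bool = True):
        self._frame = _coerce_frame(frame)
        self.provenance = provenance
        self._indices: dict[str, dict] = {}
        if validate:
            self._check_invariants()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[ActivityRecord], provenance: str = "") -> "Dataset":
        rows = [
            {
                "compound_id": r.compound_id,
                "target_id": r.target_id,
                "target_type": r.target_type,
                "organism": r.organism,
                "assay_id": r.assay_id,
                "relationship_type": r.relationship_type,
                "confidence_score": r.confidence_score,
                "measurement_type": r.measurement_type,
                "measurement_relation": r.measurement_relation,
                "activity_comment": r.activity_comment,
                "release_year": r.release_year,
                "measurement_value": (
                    np.nan if r.measurement_value is None else r.measurement_value
                ),
            }
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return cls(frame, provenance)

    # -- invariants --------------------------------------------------------

    def _check_invariants(self) -> None:
        f = self._frame
        for name in _ID_COLUMNS:
            if (f[name].astype(str).str.len() == 0).any():
                raise ValueError(f"Dataset contains empty {name}")
        score = f["confidence_score"].dropna()
        if len(score) and not score.between(0, 9).all():
            raise ValueError("confidence_score outside [0, 9]")
        value = f["measurement_value"].dropna()
        if len(value) and (value < 0).any():
            raise ValueError("negative measurement_value")

    # -- container protocol ------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying table (treat as read-only)."""
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[ActivityRecord]:
        return self.records()

    def records(self) -> Iterator[ActivityRecord]:
        for row in self._frame.itertuples(index=False):
            yield ActivityRecord(
                compound_id=row.compound_id,
                target_id=row.target_id,
                assay_id=row.assay_id,
                target_type=row.target_type,
                organism=row.organism,
                relationship_type=row.relationship_type,
                confidence_score=(
                    None if pd.isna(row.confidence_score) else int(row.confidence_score)
                ),
                measurement_type=row.measurement_type,
                measurement_relation=row.measurement_relation,
                activity_comment=row.activity_comment,
                release_year=(
                    None if pd.isna(row.release_year) else int(row.release_year)
                ),
                measurement_value=(
                    None if pd.isna(row.measurement_value) else float(row.measurement_value)
                ),
            )

    # -- derived views -----------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self._frame)

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self._frame["compound_id"].unique())

    @property
    def target_ids(self) -> list[str]:
        return sorted(self._frame["target_id"].unique())

    @property
    def assay_ids(self) -> list[str]:
        return sorted(self._frame["assay_id"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self._frame["release_year"].dropna().unique())

    def index_by(self, column: str) -> Mapping:
        """Row positions grouped by ``column`` value (cached)."""
        if column not in self._indices:
            self._indices[column] = dict(
                self._frame.groupby(column, dropna=True, observed=True).indices
            )
        return self._indices[column]

    def subset(self, mask, provenance: str | None = None) -> "Dataset":
        """New Dataset from a boolean row mask; the input is unmodified."""
        sub = self._frame.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return Dataset(sub, provenance if provenance is not None else self.provenance,
                       validate=False)

    def same_records(self, other: "Dataset") -> bool:
        """Record-for-record equality, ignoring provenance and row order metadata."""
        a = self._frame.reset_index(drop=True)
        b = other._frame.reset_index(drop=True)
        return a.equals(b)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Dataset(n_records={self.n_records}, "
            f"n_compounds={self._frame['compound_id'].nunique()}, "
            f"provenance={self.provenance!r})"
        )


def _coerce_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    f = frame[CANONICAL_COLUMNS].copy().reset_index(drop=True)
    for col in ("compound_id", "target_id", "target_type", "organism", "assay_id",
                "relationship_type", "measurement_type", "measurement_relation",
                "activity_comment"):
        f[col] = f[col].fillna("").astype(str)
    f["confidence_score"] = f["confidence_score"].astype("Int64")
    f["release_year"] = f["release_year"].astype("Int64")
    f["measurement_value"] = pd.to_numeric(f["measurement_value"], errors="raise").astype(float)
    return f


def _parse_years(raw: pd.Series, year_range: tuple[int, int]) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Parse a string column of release dates to integer years.

    Returns ``(years, missing_mask, bad_mask)``: years is Int64 (NA where
    missing or bad); bad marks non-empty values that do not resolve to a
    year inside ``year_range``.
    """
    stripped = raw.fillna("").astype(str).str.strip()
    missing = stripped == ""
    extracted = stripped.str.extract(_YEAR_RE, expand=True)[0]
    years = pd.to_numeric(extracted, errors="coerce")
    # fall back to full date parsing for formats not led by a 4-digit year
    needs_fallback = years.isna() & ~missing
    if needs_fallback.any():
        parsed = pd.to_datetime(stripped[needs_fallback], errors="coerce", format="mixed")
        years.loc[needs_fallback] = parsed.dt.year
    bad = (~missing) & (years.isna() | ~years.between(*year_range))
    years = years.where(~(missing | bad)).astype("Int64")
    return years, missing, bad


def read_activity_table(
    path: str | Path,
    *,
    delimiter: str = "\t",
    column_map: Mapping[str, str] | None = None,
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE,
    provenance: str | None = None,
) -> tuple[Dataset, ValidationReport]:
    """Read a delimited activity table, validating and deduplicating rows.

    Parameters
    ----------
    path
        Delimited text file with a header row naming all canonical columns
        (possibly via ``column_map``).
    delimiter
        Field separator; tab by default.
    column_map
        Mapping from column names as they appear in the file to canonical
        names, for loading foreign exports without rewriting them.
    year_range
        Inclusive plausible range for release years; out-of-range or
        unparseable non-empty dates are rejected with a counted reason.

    Returns
    -------
    (Dataset, ValidationReport)
        Every parseable row becomes a record; rows failing validation are
        counted per reason, never silently dropped.  Byte-identical
        duplicate rows are removed and counted under ``duplicate_record``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                          na_values=[], skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty (no header row)") from exc
    if column_map:
        raw = raw.rename(columns=dict(column_map))
    missing_cols = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing required column(s): {', '.join(missing_cols)}")
    raw = raw[CANONICAL_COLUMNS]

    report = ValidationReport(n_records_read=len(raw))
    reasons = pd.Series("", index=raw.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons.loc[fresh] = reason

    for name in _ID_COLUMNS:
        flag(raw[name].str.strip() == "", f"missing_{name}")

    score = pd.to_numeric(raw["confidence_score"].str.strip(), errors="coerce")
    score_missing = raw["confidence_score"].str.strip() == ""
    bad_score = (~score_missing) & (
        score.isna() | (score % 1 != 0) | ~score.between(0, 9)
    )
    flag(bad_score, "bad_confidence_score")

    years, year_missing, bad_year = _parse_years(raw["release_year"], year_range)
    flag(bad_year, "bad_release_year")

    value_str = raw["measurement_value"].str.strip()
    value = pd.to_numeric(value_str, errors="coerce")
    value_missing = value_str == ""
    flag((~value_missing) & (value.isna() | (value < 0)), "bad_measurement_value")
    # re-parse through numpy's correctly rounded strtod so values round-trip
    parsed_ok = (~value_missing) & value.notna()
    if parsed_ok.any():
        value.loc[parsed_ok] = np.asarray(value_str[parsed_ok], dtype=float)

    ok = reasons == ""
    typed = raw.loc[ok].copy()
    typed["confidence_score"] = score.loc[ok].astype("Int64")
    typed["release_year"] = years.loc[ok]
    typed["measurement_value"] = value.loc[ok].astype(float)
    for col in ("compound_id", "target_id", "assay_id"):
        typed[col] = typed[col].str.strip()

    dup = typed.duplicated(keep="first")
    n_dup = int(dup.sum())
    typed = typed.loc[~dup].reset_index(drop=True)

    for reason, count in reasons[~ok].value_counts().items():
        report.rejection_reasons[reason] = int(count)
    if n_dup:
        report.rejection_reasons["duplicate_record"] = n_dup
    report.n_rejected = int((~ok).sum()) + n_dup
    report.n_retained = len(typed)
    report.n_missing_release_year = int((year_missing & ok).sum())

    dataset = Dataset(typed, provenance if provenance is not None else str(path))
    return dataset, report


def write_activity_table(dataset: Dataset, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a Dataset as delimited text; missing values become empty strings.

    Round-trip property: reading the written file reproduces the Dataset
    record for record.
    """
    out = dataset.frame.copy()
    out["confidence_score"] = out["confidence_score"].astype(object)
    out["release_year"] = out["release_year"].astype(object)
    out.to_csv(path, sep=delimiter, index=False, na_rep="")


def exclude_missing_release_year(dataset: Dataset) -> Dataset:
    """Records whose release year is present; the input is unmodified.

    The downstream time-course statistics require a release year on every
    record, so undated records are split off explicitly rather than dropped
    inside the analysis.
    """
    return dataset.subset(dataset.frame["release_year"].notna().to_numpy())
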