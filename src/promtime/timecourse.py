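"""Annual growth statistics and per-compound cumulative promiscuity.

Records are assigned to calendar years by release date.  Growth tables
count, per year, the new and cumulative entities of one kind (compounds,
targets, assays, activity records); a compound/target/assay is "new" in the
earliest year any of its records appears and is counted once over the whole
table.  A compound's promiscuity degree at year *y* is the number of
distinct targets over all of its records released in or before *y* -- a
target contributes from its first year onward regardless of later
re-measurement -- so the degree is non-decreasing in time.  Delta
(promiscuity gain) is the final degree minus the degree in the compound's
first recorded year; 0 means the degree never changed.
"""

from __future__ import annotations

import bisect
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from promtime.records import Dataset

ENTITY_KINDS = ("compounds", "targets", "assays", "activities")
_ENTITY_COLUMN = {"compounds": "compound_id", "targets": "target_id", "assays": "assay_id"}

#: Bin labels for the promiscuity-gain histogram, in order.
DELTA_BINS = ("0", "1", "2", "3", "4", "5", "6–10", "11–20", "21–50", ">50")
_BIN_EDGES = (
    (0, 0), (1, 1), (2, 2), (3, 3), (4, 4), (5, 5),
    (6, 10), (11, 20), (21, 50), (51, None),
)


def delta_bin_label(delta: int) -> str:
    """The histogram bin containing a non-negative promiscuity gain."""
    if delta < 0:
        raise ValueError(f"delta must be non-negative, got {delta}")
    for label, (lo, hi) in zip(DELTA_BINS, _BIN_EDGES):
        if delta >= lo and (hi is None or delta <= hi):
            return label
    raise AssertionError("bins are exhaustive")  # pragma: no cover


@dataclass(frozen=True)
class GrowthTable:
    """Per-year new and cumulative counts for one entity kind.

    Rows cover every year from the first to the last observed year; years
    with no new entities appear with ``n_new = 0``.  The cumulative column
    is the running sum of the new column.
    """

    entity_kind: str
    frame: pd.DataFrame  # columns: year, n_new, n_cumulative

    @classmethod
    def from_new_counts(cls, entity_kind: str, new_counts: Mapping[int, int]) -> "GrowthTable":
        """Build a table from per-year new-entity counts, filling gap years."""
        if entity_kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {entity_kind!r}")
        if not new_counts:
            return cls(entity_kind, pd.DataFrame(columns=["year", "n_new", "n_cumulative"]))
        years = range(min(new_counts), max(new_counts) + 1)
        n_new = [int(new_counts.get(y, 0)) for y in years]
        frame = pd.DataFrame({"year": list(years), "n_new": n_new})
        frame["n_cumulative"] = frame["n_new"].cumsum()
        return cls(entity_kind, frame)

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self.frame["year"]]

    def new(self, year: int) -> int:
        return self._lookup(year, "n_new")

    def cumulative(self, year: int) -> int:
        return self._lookup(year, "n_cumulative")

    def _lookup(self, year: int, column: str) -> int:
        row = self.frame.loc[self.frame["year"] == year, column]
        if row.empty:
            raise KeyError(f"year {year} not present in {self.entity_kind} growth table")
        return int(row.iloc[0])


@dataclass(frozen=True)
class PromiscuityProfile:
    """One compound's cumulative distinct-target count by year.

    ``degree_by_year`` is defined for every year from ``first_year`` (the
    earliest release year of any of the compound's records) to ``horizon``,
    and is non-decreasing.  ``delta`` is the gain from the first year to the
    horizon; it is 0 for a compound whose degree never changed, even if it
    debuted with several targets at once.
    """

    compound_id: str
    first_year: int
    horizon: int
    degree_by_year: Mapping[int, int]

    def degree(self, year: int) -> int:
        return self.degree_by_year[year]

    @property
    def final_degree(self) -> int:
        return self.degree_by_year[self.horizon]

    @property
    def delta(self) -> int:
        return self.final_degree - self.degree_by_year[self.first_year]


@dataclass(frozen=True)
class DeltaHistogram:
    """Compound counts binned by promiscuity gain."""

    counts: Mapping[str, int]
    total: int

    bins = DELTA_BINS

    @property
    def constant_fraction(self) -> float:
        """Fraction of compounds whose promiscuity degree never changed."""
        if self.total == 0:
            raise ValueError("empty histogram has no constant fraction")
        return self.counts["0"] / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": list(self.bins), "count": [self.counts[b] for b in self.bins]}
        )


def _require_years(dataset: Dataset) -> pd.DataFrame:
    frame = dataset.frame
    if frame["release_year"].isna().any():
        raise ValueError(
            "dataset contains records without a release year; "
            "apply exclude_missing_release_year first"
        )
    return frame


def growth_table(dataset: Dataset, entity_kind: str) -> GrowthTable:
    """Annual new and cumulative counts for one entity kind.

    For compounds, targets and assays an entity is new in the earliest year
    of any of its records; for activities every record counts in its own
    release year.  An empty dataset gives an empty table.
    """
    if entity_kind not in ENTITY_KINDS:
        raise ValueError(f"unknown entity kind {entity_kind!r}; expected one of {ENTITY_KINDS}")
    frame = _require_years(dataset)
    if frame.empty:
        return GrowthTable.from_new_counts(entity_kind, {})
    if entity_kind == "activities":
        per_year = frame["release_year"].astype(int).value_counts()
    else:
        column = _ENTITY_COLUMN[entity_kind]
        first = frame.groupby(column, observed=True)["release_year"].min().astype(int)
        per_year = first.value_counts()
    new_counts = per_year.to_dict()
    # table rows span the dataset's full year range, not just debut years
    new_counts.setdefault(int(frame["release_year"].min()), 0)
    new_counts.setdefault(int(frame["release_year"].max()), 0)
    return GrowthTable.from_new_counts(entity_kind, new_counts)


def fold_increase(table: GrowthTable, year_from: int, year_to: int) -> float:
    """Ratio of cumulative counts between two years of a growth table.

    Full precision is returned; reporting layers round to one decimal.
    """
    denom = table.cumulative(year_from)
    if denom == 0:
        raise ValueError(f"cumulative count at {year_from} is zero")
    return table.cumulative(year_to) / denom


def promiscuity_series(dataset: Dataset, horizon: int | None = None) -> list[PromiscuityProfile]:
    """Cumulative distinct-target degree by year, one profile per compound.

    ``horizon`` defaults to the latest release year in the dataset; every
    record must carry a release year no later than the horizon.  Profiles
    are returned sorted by compound id.
    """
    frame = _require_years(dataset)
    if frame.empty:
        return []
    max_year = int(frame["release_year"].max())
    if horizon is None:
        horizon = max_year
    elif max_year > horizon:
        raise ValueError(f"records extend to {max_year}, beyond horizon {horizon}")

    pair_first = (
        frame.assign(release_year=frame["release_year"].astype(int))
        .groupby(["compound_id", "target_id"], observed=True)["release_year"]
        .min()
    )
    profiles = []
    for cid, target_years in pair_first.groupby(level=0, observed=True):
        years = np.sort(target_years.to_numpy())
        first_year = int(years[0])
        span = np.arange(first_year, horizon + 1)
        degrees = np.searchsorted(years, span, side="right")
        profiles.append(
            PromiscuityProfile(
                compound_id=str(cid),
                first_year=first_year,
                horizon=int(horizon),
                degree_by_year=dict(zip(span.tolist(), degrees.tolist())),
            )
        )
    profiles.sort(key=lambda p: p.compound_id)
    return profiles


def annual_mean_promiscuity(
    profiles: Iterable[PromiscuityProfile], years: Sequence[int] | None = None
) -> dict[int, float]:
    """Mean promiscuity degree per year over the compounds already seen.

    A compound qualifies for year *y* once ``first_year <= y``; its
    cumulative degree then enters every later annual mean, whether or not
    new data appeared for it that year.  Years with no qualifying compounds
    are absent from the result.
    """
    profiles = list(profiles)
    if not profiles:
        return {}
    if years is None:
        start = min(p.first_year for p in profiles)
        stop = max(p.horizon for p in profiles)
        years = range(start, stop + 1)
    # profiles sorted by debut year: compounds qualifying at y form a prefix
    by_debut = sorted(profiles, key=lambda p: p.first_year)
    debuts = [p.first_year for p in by_debut]
    out: dict[int, float] = {}
    for year in years:
        n = bisect.bisect_right(debuts, year)
        if n == 0:
            continue
        qualifying = by_debut[:n]
        if any(year > p.horizon for p in qualifying):
            raise ValueError(f"year {year} beyond profile horizon")
        out[int(year)] = sum(p.degree(year) for p in qualifying) / n
    return out


def annual_summary(
    profiles: Iterable[PromiscuityProfile], years: Sequence[int] | None = None
) -> pd.DataFrame:
    """Annual mean promiscuity with the qualifying-compound denominator.

    Columns: year, n_qualifying_compounds, mean_promiscuity.
    """
    profiles = list(profiles)
    means = annual_mean_promiscuity(profiles, years)
    debuts = sorted(p.first_year for p in profiles)
    rows = [
        {
            "year": year,
            "n_qualifying_compounds": bisect.bisect_right(debuts, year),
            "mean_promiscuity": mean,
        }
        for year, mean in sorted(means.items())
    ]
    return pd.DataFrame(rows, columns=["year", "n_qualifying_compounds", "mean_promiscuity"])


def delta_histogram(profiles: Iterable[PromiscuityProfile]) -> DeltaHistogram:
    """Bin compounds by promiscuity gain (final minus first-year degree).

    All profiles must share one horizon so the gains are comparable.  Each
    compound lands in exactly one bin; the counts sum to the number of
    profiles.
    """
    profiles = list(profiles)
    horizons = {p.horizon for p in profiles}
    if len(horizons) > 1:
        raise ValueError(f"profiles span multiple horizons: {sorted(horizons)}")
    counts = {label: 0 for label in DELTA_BINS}
    for p in profiles:
        counts[delta_bin_label(p.delta)] += 1
    return DeltaHistogram(counts=counts, total=len(profiles))


def cohort_subset(dataset: Dataset, first_year: int) -> Dataset:
    """All records of the compounds whose earliest release year is ``first_year``.

    Later records of a cohort compound are retained; a compound with any
    earlier record is excluded entirely.
    """
    frame = _require_years(dataset)
    if frame.empty:
        return dataset.subset(np.zeros(0, dtype=bool))
    earliest = frame.groupby("compound_id", observed=True)["release_year"].min()
    cohort_ids = set(earliest.index[earliest == first_year])
    return dataset.subset(
        frame["compound_id"].isin(cohort_ids).to_numpy(),
        provenance=f"{dataset.provenance}|cohort{first_year}",
    )


def current_mean_promiscuity(dataset: Dataset, horizon: int | None = None) -> float:
    """Mean promiscuity degree at the horizon over all compounds in the dataset.

    Full precision; reporting layers round to one decimal.  Raises on an
    empty dataset (the mean is undefined).
    """
    if len(dataset) == 0:
        raise ValueError("cannot compute mean promiscuity of an empty dataset")
    profiles = promiscuity_series(dataset, horizon)
    return sum(p.final_degree for p in profiles) / len(profiles)
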