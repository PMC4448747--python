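"""End-to-end analysis run: filter tiers, growth tables, promiscuity statistics.

One call (or one CLI invocation) reads a record table, drops undated
records, applies the requested confidence tier(s) and writes, per tier, the
filter audit report, growth tables for all four entity kinds, the annual
mean-promiscuity series, the per-compound profile table, the
promiscuity-gain histogram and the cohort means for configurable debut
years, plus a manifest capturing every parameter of the run.  Tables are
CSV files; logs go to standard error.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from promtime.filters import apply_tier, filter_report
from promtime.records import Dataset, exclude_missing_release_year, read_activity_table
from promtime.timecourse import (
    ENTITY_KINDS,
    annual_summary,
    cohort_subset,
    current_mean_promiscuity,
    delta_histogram,
    growth_table,
    promiscuity_series,
)

logger = logging.getLogger("promtime")

DEFAULT_COHORT_YEARS = (1994, 2004)
TOOL_VERSION = "0.1.0"


@dataclass
class RunManifest:
    """Everything needed to reproduce one analysis run."""

    input_path: str
    tiers: list[str]
    horizon: int
    cohort_years: list[int]
    out_dir: str
    outputs: list[str] = field(default_factory=list)
    seed: int | None = None
    tool_version: str = TOOL_VERSION
    timestamp: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


def _write(frame: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    frame.to_csv(path, index=False)
    manifest.outputs.append(str(path))


def _profiles_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": p.compound_id,
                "first_year": p.first_year,
                "final_degree": p.final_degree,
                "delta": p.delta,
            }
            for p in profiles
        ],
        columns=["compound_id", "first_year", "final_degree", "delta"],
    )


def _cohort_means(dataset: Dataset, horizon: int, cohort_years) -> pd.DataFrame:
    rows = []

    def add(label: str, subset: Dataset) -> None:
        n = subset.frame["compound_id"].nunique()
        mean = current_mean_promiscuity(subset, horizon) if n else float("nan")
        rows.append(
            {
                "cohort": label,
                "n_compounds": int(n),
                "mean_promiscuity": mean,
                "mean_promiscuity_1dp": round(mean, 1) if n else float("nan"),
            }
        )

    add("all", dataset)
    for year in cohort_years:
        add(str(year), cohort_subset(dataset, year))
    return pd.DataFrame(rows, columns=["cohort", "n_compounds", "mean_promiscuity",
                                       "mean_promiscuity_1dp"])


def run_full_analysis(
    records: str | Path,
    tier: str = "both",
    horizon: int | None = None,
    out_dir: str | Path = "results",
    cohort_years=DEFAULT_COHORT_YEARS,
    delimiter: str = "\t",
    seed: int | None = None,
) -> RunManifest:
    """Run the full filtering and time-course workflow on one record table.

    Parameters
    ----------
    records
        Delimited activity table (see :func:`promtime.read_activity_table`).
    tier
        ``"high"``, ``"low"`` or ``"both"``.
    horizon
        Final year of the analysis; defaults to the latest release year
        among the dated records.
    cohort_years
        Debut years for which cohort means are reported alongside the
        all-compound mean.

    Returns
    -------
    RunManifest
        Paths of every table written, plus the run parameters.
    """
    if tier not in ("high", "low", "both"):
        raise ValueError(f"tier must be 'high', 'low' or 'both', got {tier!r}")
    tiers = ["high", "low"] if tier == "both" else [tier]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("reading %s", records)
    dataset, report = read_activity_table(records, delimiter=delimiter)
    logger.info(
        "read %d rows: %d retained, %d rejected, %d without release year",
        report.n_records_read, report.n_retained, report.n_rejected,
        report.n_missing_release_year,
    )
    dated = exclude_missing_release_year(dataset)
    if len(dated) == 0:
        raise ValueError("no records with release years; nothing to analyse")
    if horizon is None:
        horizon = max(dated.years)
    logger.info("%d dated records, horizon %d", len(dated), horizon)

    manifest = RunManifest(
        input_path=str(records),
        tiers=tiers,
        horizon=int(horizon),
        cohort_years=[int(y) for y in cohort_years],
        out_dir=str(out),
        seed=seed,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )

    for t in tiers:
        logger.info("tier %s: filtering", t)
        filtered = apply_tier(dated, t)
        _write(filter_report(filtered, t).to_frame(), out / f"filter_report_{t}.csv", manifest)

        for kind in ENTITY_KINDS:
            table = growth_table(filtered, kind)
            _write(table.frame, out / f"growth_{t}_{kind}.csv", manifest)

        logger.info("tier %s: %d records, computing promiscuity", t, len(filtered))
        profiles = promiscuity_series(filtered, horizon) if len(filtered) else []
        _write(_profiles_frame(profiles), out / f"profiles_{t}.csv", manifest)
        _write(annual_summary(profiles), out / f"mean_promiscuity_{t}.csv", manifest)
        hist = delta_histogram(profiles)
        _write(hist.to_frame(), out / f"delta_histogram_{t}.csv", manifest)
        if len(filtered):
            _write(_cohort_means(filtered, horizon, cohort_years),
                   out / f"cohort_means_{t}.csv", manifest)
        else:
            _write(pd.DataFrame(columns=["cohort", "n_compounds", "mean_promiscuity",
                                         "mean_promiscuity_1dp"]),
                   out / f"cohort_means_{t}.csv", manifest)

    manifest.to_json(out / "manifest.json")
    manifest.outputs.append(str(out / "manifest.json"))
    logger.info("wrote %d output files to %s", len(manifest.outputs), out)
    return manifest
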