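"""Data model and CSV readers/writers for long-format assemblage time series.

An assemblage time series records, for one monitored location, the abundance
of every species observed in every sampling occasion of every monitored year.
The long CSV layout has one row per (assemblage, year, sampling occasion,
species) with an integer abundance; the default column names follow public
BioTIME-style exports but any mapping can be supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical internal column names.
COLUMNS = ["assemblage_id", "year", "sample_id", "species_id", "abundance"]

#: Default column mapping for BioTIME-style public exports
#: (CSV column name -> canonical name).
DEFAULT_SCHEMA = {
    "STUDY_ID": "assemblage_id",
    "YEAR": "year",
    "SAMPLE_DESC": "sample_id",
    "GENUS_SPECIES": "species_id",
    "sum.allrawdata.ABUNDANCE": "abundance",
}


class SchemaError(ValueError):
    """A required column is missing from the input file."""


class InputError(ValueError):
    """The input file is unusable (empty, no valid rows, ...)."""


@dataclass(frozen=True)
class AbundanceRecord:
    """One species' count in one sampling occasion of one assemblage-year."""

    assemblage_id: str
    year: int
    sample_id: str
    species_id: str
    abundance: int


@dataclass
class AssemblageTimeSeries:
    """All abundance records of one assemblage, held as a tidy DataFrame.

    Parameters
    ----------
    assemblage_id
        Opaque identifier shared by every record.
    records
        DataFrame with columns ``year, sample_id, species_id, abundance``;
        one row per (year, sample, species), abundances >= 1.
    is_aggregable
        True when within-year samples may be summed after rarefaction (the
        default; appropriate for non-sessile faunal surveys where multiple
        within-year samples capture seasonality rather than distinct plots).
    """

    assemblage_id: str
    records: pd.DataFrame
    is_aggregable: bool = True

    def __post_init__(self) -> None:
        missing = [c for c in ("year", "sample_id", "species_id", "abundance") if c not in self.records.columns]
        if missing:
            raise SchemaError(f"records missing columns: {missing}")

    @property
    def years(self) -> np.ndarray:
        """Sorted distinct years present."""
        return np.sort(self.records["year"].unique())

    @property
    def n_years(self) -> int:
        return self.records["year"].nunique()

    def samples_per_year(self) -> dict[int, int]:
        """Number of distinct sampling occasions in each year."""
        g = self.records.groupby("year")["sample_id"].nunique()
        return {int(y): int(n) for y, n in g.items()}

    def total_abundance(self) -> int:
        return int(self.records["abundance"].sum())

    def to_records(self) -> list[AbundanceRecord]:
        return [
            AbundanceRecord(self.assemblage_id, int(r.year), str(r.sample_id), str(r.species_id), int(r.abundance))
            for r in self.records.itertuples(index=False)
        ]


@dataclass
class ValidationResult:
    """Outcome of :func:`validate_series` with structured reasons."""

    assemblage_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)
    n_years: int = 0
    years: list[int] = field(default_factory=list)
    samples_per_year: dict[int, int] = field(default_factory=dict)


def _ingest_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Clean a canonical-column frame: drop non-positive rows, floor
    non-integer counts, sum duplicates."""
    n_raw = len(df)
    df = df.copy()
    df["abundance"] = pd.to_numeric(df["abundance"], errors="raise")
    nonpos = df["abundance"] <= 0
    if nonpos.any():
        logger.warning("dropping %d rows with abundance <= 0 (implicit absences)", int(nonpos.sum()))
        df = df[~nonpos]
    if len(df) == 0:
        raise InputError(f"no rows with positive abundance among {n_raw} input rows")
    frac = df["abundance"] != np.floor(df["abundance"])
    if frac.any():
        logger.warning("flooring %d non-integer abundances to integer counts", int(frac.sum()))
        df["abundance"] = np.floor(df["abundance"])
        df = df[df["abundance"] >= 1]
    df["abundance"] = df["abundance"].astype(np.int64)
    df["year"] = df["year"].astype(int)
    key = ["assemblage_id", "year", "sample_id", "species_id"]
    grouped = df.groupby(key, as_index=False, sort=False)["abundance"].sum()
    n_merged = len(df) - len(grouped)
    if n_merged > 0:
        logger.warning("summed %d duplicated (assemblage, year, sample, species) rows", n_merged)
    return grouped


def read_long_csv(
    path,
    schema: dict[str, str] | None = None,
    aggregable: dict[str, bool] | None = None,
) -> list[AssemblageTimeSeries]:
    """Read a long-format CSV into one :class:`AssemblageTimeSeries` per assemblage.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Mapping from CSV column names to the canonical names
        ``assemblage_id, year, sample_id, species_id, abundance``.
        Defaults to BioTIME-style export names.
    aggregable
        Optional per-assemblage override of the ``is_aggregable`` flag
        (default: every assemblage is aggregable).

    Rows with abundance <= 0 are dropped (they encode absence), non-integer
    abundances are floored, and duplicated (assemblage, year, sample, species)
    rows are summed; each cleaning step logs a count.
    """
    schema = dict(schema) if schema else dict(DEFAULT_SCHEMA)
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty input file: {path}") from exc
    missing = [c for c in schema if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}; found {list(raw.columns)}")
    df = raw[list(schema)].rename(columns=schema)
    if len(df) == 0:
        raise InputError(f"no data rows in {path}")
    df["assemblage_id"] = df["assemblage_id"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    df["species_id"] = df["species_id"].astype(str)
    clean = _ingest_frame(df)
    out = []
    for aid, sub in clean.groupby("assemblage_id", sort=True):
        flag = True if aggregable is None else bool(aggregable.get(str(aid), True))
        out.append(
            AssemblageTimeSeries(
                assemblage_id=str(aid),
                records=sub.drop(columns=["assemblage_id"]).reset_index(drop=True),
                is_aggregable=flag,
            )
        )
    return out


def write_long_csv(series_list: list[AssemblageTimeSeries], path, schema: dict[str, str] | None = None) -> None:
    """Write assemblages back to a long CSV (inverse of :func:`read_long_csv`)."""
    schema = dict(schema) if schema else dict(DEFAULT_SCHEMA)
    inv = {v: k for k, v in schema.items()}
    frames = []
    for s in series_list:
        df = s.records.copy()
        df.insert(0, "assemblage_id", s.assemblage_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)[COLUMNS].rename(columns=inv)
    out.to_csv(path, index=False)


def validate_series(series: AssemblageTimeSeries, min_years: int = 10) -> ValidationResult:
    """Check a series against the minimum-duration requirement.

    Trend fitting needs at least 2 distinct years; the headline analyses of
    multi-decadal monitoring data require 10. Returns a structured result
    rather than raising, so callers can report exclusions.
    """
    spy = series.samples_per_year()
    years = sorted(spy)
    reasons = []
    if len(years) < min_years:
        reasons.append(f"too few years: {len(years)} < {min_years}")
    return ValidationResult(
        assemblage_id=series.assemblage_id,
        passed=not reasons,
        reasons=reasons,
        n_years=len(years),
        years=years,
        samples_per_year=spy,
    )


def from_records(records: list[AbundanceRecord], is_aggregable: bool = True) -> list[AssemblageTimeSeries]:
    """Group a flat record list into per-assemblage series (duplicates summed)."""
    if not records:
        raise InputError("no records supplied")
    df = pd.DataFrame(
        {
            "assemblage_id": [r.assemblage_id for r in records],
            "year": [r.year for r in records],
            "sample_id": [r.sample_id for r in records],
            "species_id": [r.species_id for r in records],
            "abundance": [r.abundance for r in records],
        }
    )
    clean = _ingest_frame(df)
    return [
        AssemblageTimeSeries(str(aid), sub.drop(columns=["assemblage_id"]).reset_index(drop=True), is_aggregable)
        for aid, sub in clean.groupby("assemblage_id", sort=True)
    ]
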