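"""Domain types, ingestion and data preparation for monitoring time series.

The analysis substrate is a :class:`CommunityTable`: monthly cell-abundance
records per (station, year, month, taxon) with one environment record per
station-month.  Raw monitoring data arrive as long-format CSVs with one row
per taxon per sampling date; this module averages them to the monthly scale,
pools undetermined congeneric morphotypes into single taxon units, and applies
the station-inclusion filter (stations need more than ``min_years`` years in
which at least ``min_months_per_year`` months were sampled).

Months are indexed 0 = January ... 11 = December throughout the package.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("saltgrad")

#: The four phytoplankton groups used for carbon-biomass composition.
GROUPS = ("cyanobacteria", "diatoms", "dinoflagellates", "other_autotrophs")

#: Environment variables attached to each station-month.
ENV_VARS = ("salinity", "sst", "din", "dip", "silicate")


class TaxonRank(str, Enum):
    """Identification level of a taxon record.

    ``species`` is a determined species; ``genus`` an undetermined morphotype
    identified only to genus (e.g. "Chaetoceros sp.1"); ``higher`` anything
    coarser.
    """

    SPECIES = "species"
    GENUS = "genus"
    HIGHER = "higher"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class SaltgradError(Exception):
    """Base class for package errors."""


class SchemaError(SaltgradError):
    """A required column is missing or the header cannot be interpreted."""


class ValidationError(SaltgradError):
    """Too many malformed rows; carries the collected row-level errors."""

    def __init__(self, message: str, row_errors: list["RowError"]):
        super().__init__(message)
        self.row_errors = row_errors


class EmptyResultError(SaltgradError):
    """A filtering step removed every record."""


class ConfigError(SaltgradError):
    """Invalid configuration value."""


class DomainError(SaltgradError):
    """An input is outside a function's mathematical domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MonitoringRecord:
    """One taxon's abundance on one sampling date at one station."""

    station_id: str
    sample_date: _dt.date
    taxon_id: str
    taxon_rank: TaxonRank
    group: str
    abundance: float  # cells L^-1, >= 0
    biovolume: float | None = None  # um^3 cell^-1, > 0 if given
    carbon: float | None = None  # ug C L^-1, optional direct measurement

    def __post_init__(self):
        if not np.isfinite(self.abundance) or self.abundance < 0:
            raise DomainError(
                f"abundance must be finite and >= 0, got {self.abundance!r}"
            )
        if self.group not in GROUPS:
            raise DomainError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.biovolume is not None and not self.biovolume > 0:
            raise DomainError(f"biovolume must be > 0, got {self.biovolume!r}")


@dataclass(frozen=True)
class EnvironmentRecord:
    """Physio-chemical water properties on one sampling date at one station.

    Concentrations are in umol L^-1, salinity in PSU (0-10 m mean), SST in
    degrees C.  Missing values are ``None``.
    """

    station_id: str
    sample_date: _dt.date
    salinity: float | None = None
    sst: float | None = None
    din: float | None = None
    dip: float | None = None
    silicate: float | None = None

    def __post_init__(self):
        if self.salinity is not None and self.salinity < 0:
            raise DomainError(f"salinity must be >= 0, got {self.salinity!r}")
        for name in ("din", "dip", "silicate"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be >= 0 or missing, got {v!r}")


@dataclass(frozen=True)
class StationProfile:
    """Per-station summary after filtering."""

    station_id: str
    mean_salinity: float
    n_monthly_samples: int
    years_retained: tuple[int, ...]


@dataclass(frozen=True)
class RowError:
    """A malformed input row, reported with its 1-based line number."""

    line: int
    message: str


@dataclass
class CommunityTable:
    """Monthly community and environment data.

    ``counts`` has columns station_id, year, month (0-11), taxon_id,
    taxon_rank, group, abundance (cells L^-1) and optionally biovolume
    (um^3 cell^-1) and carbon (ug C L^-1), with at most one row per
    (station, year, month, taxon).  ``env`` has one row per (station, year,
    month) with the ENV_VARS columns (NaN where unmeasured).
    """

    counts: pd.DataFrame
    env: pd.DataFrame

    SAMPLE_KEY = ["station_id", "year", "month"]
    ROW_KEY = SAMPLE_KEY + ["taxon_id"]

    def __post_init__(self):
        if self.counts.duplicated(self.ROW_KEY).any():
            raise DomainError("duplicate (station, year, month, taxon) rows")
        if len(self.env) and self.env.duplicated(self.SAMPLE_KEY).any():
            raise DomainError("duplicate (station, year, month) environment rows")

    def samples(self) -> pd.DataFrame:
        """Distinct (station_id, year, month) community samples."""
        return self.counts[self.SAMPLE_KEY].drop_duplicates().reset_index(drop=True)

    def stations(self) -> list[str]:
        return sorted(self.counts["station_id"].unique())

    def with_env(self) -> pd.DataFrame:
        """Counts left-joined with environment per station-month."""
        return self.counts.merge(self.env, on=self.SAMPLE_KEY, how="left")


# ---------------------------------------------------------------------------
# Ingestion
# ---------------------------------------------------------------------------

COMMUNITY_SCHEMA = {
    "station_id": "station_id",
    "date": "date",
    "taxon_id": "taxon_id",
    "taxon_rank": "taxon_rank",
    "group": "group",
    "abundance_cells_per_l": "abundance",
    "biovolume_um3": "biovolume",  # optional column
    "carbon_ug_l": "carbon",  # optional column
}

ENVIRONMENT_SCHEMA = {
    "station_id": "station_id",
    "date": "date",
    "salinity": "salinity",
    "sst_c": "sst",
    "din_umol_l": "din",
    "dip_umol_l": "dip",
    "silicate_umol_l": "silicate",
}

_OPTIONAL_COMMUNITY_COLUMNS = frozenset({"biovolume_um3", "carbon_ug_l"})


def _parse_date(raw: str) -> _dt.date:
    return _dt.date.fromisoformat(raw.strip())


def _parse_optional_float(raw: str) -> float | None:
    raw = raw.strip()
    return None if raw == "" else float(raw)


def read_monitoring_csv(
    community_path: str | Path,
    environment_path: str | Path,
    *,
    community_schema: dict[str, str] | None = None,
    environment_schema: dict[str, str] | None = None,
    max_error_fraction: float = 0.05,
) -> tuple[list[MonitoringRecord], list[EnvironmentRecord], list[RowError]]:
    """Read the two long-format monitoring CSVs.

    Malformed rows are collected as :class:`RowError` with their line numbers;
    the run aborts with :class:`ValidationError` if they exceed
    ``max_error_fraction`` of rows in either file.  When the environment file
    contains two rows for the same (station, date), the later row wins and a
    warning is logged.
    """
    records, rec_errors = _read_community(
        community_path, community_schema or COMMUNITY_SCHEMA
    )
    env_records, env_errors = _read_environment(
        environment_path, environment_schema or ENVIRONMENT_SCHEMA
    )
    all_errors = rec_errors + env_errors
    for n_err, n_rows, path in (
        (len(rec_errors), max(len(records) + len(rec_errors), 1), community_path),
        (len(env_errors), max(len(env_records) + len(env_errors), 1), environment_path),
    ):
        if n_err / n_rows > max_error_fraction:
            raise ValidationError(
                f"{n_err}/{n_rows} malformed rows in {path} exceeds "
                f"max_error_fraction={max_error_fraction}",
                all_errors,
            )
    logger.info(
        "ingested %d community records, %d environment records (%d row errors)",
        len(records),
        len(env_records),
        len(all_errors),
    )
    return records, env_records, all_errors


def _read_csv_rows(path: Path, required: Sequence[str], optional: frozenset[str]):
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _read_community(path: Path, schema: dict[str, str]):
    required = [c for c in schema if c not in _OPTIONAL_COMMUNITY_COLUMNS]
    df = _read_csv_rows(path, required, _OPTIONAL_COMMUNITY_COLUMNS)
    records: list[MonitoringRecord] = []
    errors: list[RowError] = []
    has_biovol = "biovolume_um3" in df.columns
    has_carbon = "carbon_ug_l" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            records.append(
                MonitoringRecord(
                    station_id=getattr(row, "station_id").strip(),
                    sample_date=_parse_date(getattr(row, "date")),
                    taxon_id=getattr(row, "taxon_id").strip(),
                    taxon_rank=TaxonRank(getattr(row, "taxon_rank").strip()),
                    group=getattr(row, "group").strip(),
                    abundance=float(getattr(row, "abundance_cells_per_l")),
                    biovolume=_parse_optional_float(getattr(row, "biovolume_um3"))
                    if has_biovol
                    else None,
                    carbon=_parse_optional_float(getattr(row, "carbon_ug_l"))
                    if has_carbon
                    else None,
                )
            )
        except (ValueError, DomainError) as exc:
            errors.append(RowError(line=i, message=str(exc)))
    return records, errors


def _read_environment(path: Path, schema: dict[str, str]):
    df = _read_csv_rows(path, list(schema), frozenset())
    by_key: dict[tuple[str, _dt.date], EnvironmentRecord] = {}
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = EnvironmentRecord(
                station_id=getattr(row, "station_id").strip(),
                sample_date=_parse_date(getattr(row, "date")),
                salinity=_parse_optional_float(getattr(row, "salinity")),
                sst=_parse_optional_float(getattr(row, "sst_c")),
                din=_parse_optional_float(getattr(row, "din_umol_l")),
                dip=_parse_optional_float(getattr(row, "dip_umol_l")),
                silicate=_parse_optional_float(getattr(row, "silicate_umol_l")),
            )
        except (ValueError, DomainError) as exc:
            errors.append(RowError(line=i, message=str(exc)))
            continue
        key = (rec.station_id, rec.sample_date)
        if key in by_key:
            logger.warning(
                "%s line %d: duplicate environment row for %s %s; later row wins",
                path,
                i,
                rec.station_id,
                rec.sample_date,
            )
        by_key[key] = rec
    return list(by_key.values()), errors


# ---------------------------------------------------------------------------
# Aggregation to the monthly scale
# ---------------------------------------------------------------------------


def aggregate_monthly(
    records: Iterable[MonitoringRecord],
    env_records: Iterable[EnvironmentRecord] = (),
) -> CommunityTable:
    """Average within-month sampling dates to one record per station-month.

    A taxon counted on one date of a month but absent from another date's
    count list contributes 0 for the absent date: counts are censuses of the
    whole community, so the monthly mean of a taxon is its summed abundance
    over the month's dates divided by the number of dates sampled that month.
    Environment variables are means over the month's environment records,
    ignoring missing values.  Months with no sample are simply absent.
    """
    rows = [
        (
            r.station_id,
            r.sample_date,
            r.taxon_id,
            r.taxon_rank.value,
            r.group,
            r.abundance,
            np.nan if r.biovolume is None else r.biovolume,
            np.nan if r.carbon is None else r.carbon,
        )
        for r in records
    ]
    if not rows:
        raise EmptyResultError("no monitoring records to aggregate")
    comm = pd.DataFrame(
        rows,
        columns=[
            "station_id",
            "date",
            "taxon_id",
            "taxon_rank",
            "group",
            "abundance",
            "biovolume",
            "carbon",
        ],
    )
    env_rows = [
        (
            r.station_id,
            r.sample_date,
            *(np.nan if getattr(r, v) is None else getattr(r, v) for v in ENV_VARS),
        )
        for r in env_records
    ]
    env = pd.DataFrame(env_rows, columns=["station_id", "date", *ENV_VARS])
    return aggregate_monthly_frames(comm, env)


def aggregate_monthly_frames(
    comm: pd.DataFrame, env: pd.DataFrame | None = None
) -> CommunityTable:
    """Vectorised monthly aggregation from date-level long frames.

    ``comm`` needs columns station_id, date, taxon_id, taxon_rank, group,
    abundance and optionally biovolume / carbon; ``env`` needs station_id,
    date and the ENV_VARS columns.  Same semantics as
    :func:`aggregate_monthly`.
    """
    df = comm.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    df["month"] = dates.dt.month - 1
    df["date"] = dates
    for col in ("biovolume", "carbon"):
        if col not in df.columns:
            df[col] = np.nan
    key = CommunityTable.SAMPLE_KEY
    n_dates = df.groupby(key)["date"].nunique().rename("n_dates")
    agg = (
        df.groupby(key + ["taxon_id"])
        .agg(
            taxon_rank=("taxon_rank", "first"),
            group=("group", "first"),
            abundance=("abundance", "sum"),
            biovolume=("biovolume", "mean"),
            carbon_sum=("carbon", "sum"),
            carbon_n=("carbon", "count"),
        )
        .reset_index()
        .merge(n_dates, on=key)
    )
    agg["abundance"] = agg["abundance"] / agg["n_dates"]
    # carbon, like abundance, is per-litre: absence on a date counts as zero
    agg["carbon"] = np.where(
        agg["carbon_n"] > 0, agg["carbon_sum"] / agg["n_dates"], np.nan
    )
    agg = agg.drop(columns=["n_dates", "carbon_sum", "carbon_n"])
    agg = agg[agg["abundance"] > 0].reset_index(drop=True)

    env_monthly = _aggregate_env_monthly(env)
    logger.info(
        "aggregated to %d monthly rows over %d station-months",
        len(agg),
        agg[key].drop_duplicates().shape[0],
    )
    return CommunityTable(counts=agg, env=env_monthly)


def _aggregate_env_monthly(env: pd.DataFrame | None) -> pd.DataFrame:
    cols = CommunityTable.SAMPLE_KEY + list(ENV_VARS)
    if env is None or not len(env):
        return pd.DataFrame(columns=cols)
    df = env.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    df["month"] = dates.dt.month - 1
    return (
        df.groupby(CommunityTable.SAMPLE_KEY)[list(ENV_VARS)].mean().reset_index()
    )


# ---------------------------------------------------------------------------
# Genus pooling
# ---------------------------------------------------------------------------


def genus_of(taxon_id: str) -> str:
    """Genus-level identifier: the first whitespace-separated token."""
    return taxon_id.split()[0]


def pool_to_taxon_units(table: CommunityTable) -> CommunityTable:
    """Pool undetermined congeneric morphotypes into one taxon unit per genus.

    Taxa identified only to genus (rank ``genus``, e.g. "Chaetoceros sp.1" and
    "Chaetoceros sp.2") are summed into a single "<Genus> spp." unit per
    station-month.  Determined species stay separate.  Total abundance per
    sample is conserved; biovolume of a pooled unit is the abundance-weighted
    mean of its members.
    """
    df = table.counts.copy()
    is_morph = df["taxon_rank"] == TaxonRank.GENUS.value
    df.loc[is_morph, "taxon_id"] = (
        df.loc[is_morph, "taxon_id"].map(genus_of) + " spp."
    )
    df["_bv_w"] = df["biovolume"] * df["abundance"]
    pooled = (
        df.groupby(CommunityTable.ROW_KEY, sort=False)
        .agg(
            taxon_rank=("taxon_rank", "first"),
            group=("group", "first"),
            abundance=("abundance", "sum"),
            carbon=("carbon", "sum"),
            _carbon_n=("carbon", "count"),
            _bv_w=("_bv_w", "sum"),
            _bv_n=("_bv_w", "count"),
        )
        .reset_index()
    )
    pooled["carbon"] = pooled["carbon"].where(pooled["_carbon_n"] > 0)
    pooled["biovolume"] = (pooled["_bv_w"] / pooled["abundance"]).where(
        pooled["_bv_n"] > 0
    )
    pooled = pooled.drop(columns=["_bv_w", "_bv_n", "_carbon_n"]).sort_values(
        CommunityTable.ROW_KEY, kind="stable"
    ).reset_index(drop=True)
    n_pooled = len(table.counts) - len(pooled)
    if n_pooled:
        logger.info("pooled %d morphotype rows into genus units", n_pooled)
    return CommunityTable(counts=pooled, env=table.env)


# ---------------------------------------------------------------------------
# Station filtering
# ---------------------------------------------------------------------------


def filter_stations(
    table: CommunityTable,
    min_years: int = 10,
    min_months_per_year: int = 8,
) -> tuple[CommunityTable, list[StationProfile]]:
    """Keep stations with more than ``min_years`` adequately sampled years.

    A year qualifies when at least ``min_months_per_year`` distinct months
    were sampled.  Mean station salinity is computed over environment values
    of the retained months that have community samples.
    """
    samples = table.samples()
    months_per_year = (
        samples.groupby(["station_id", "year"])["month"].nunique().reset_index()
    )
    qualifying = months_per_year[months_per_year["month"] >= min_months_per_year]
    years_per_station = qualifying.groupby("station_id")["year"].agg(list)
    keep = years_per_station[years_per_station.map(len) > min_years]
    if keep.empty:
        raise EmptyResultError(
            f"no station has > {min_years} years with >= {min_months_per_year} "
            "sampled months"
        )
    kept_ids = set(keep.index)
    counts = table.counts[table.counts["station_id"].isin(kept_ids)].reset_index(
        drop=True
    )
    env = table.env[table.env["station_id"].isin(kept_ids)].reset_index(drop=True)
    out = CommunityTable(counts=counts, env=env)

    sample_env = out.samples().merge(env, on=CommunityTable.SAMPLE_KEY, how="left")
    profiles = []
    for sid in sorted(kept_ids):
        sal = sample_env.loc[sample_env["station_id"] == sid, "salinity"]
        n_samp = int((out.samples()["station_id"] == sid).sum())
        profiles.append(
            StationProfile(
                station_id=sid,
                mean_salinity=float(sal.mean()),
                n_monthly_samples=n_samp,
                years_retained=tuple(sorted(keep[sid])),
            )
        )
    logger.info(
        "station filter: retained %d of %d stations",
        len(kept_ids),
        samples["station_id"].nunique(),
    )
    return out, profiles


# ---------------------------------------------------------------------------
# Variable transforms
# ---------------------------------------------------------------------------

_TRANSFORMS = ("ln", "ln1p", "log10", "sqrt")


def transform(value, kind: str, floor: float | None = None):
    """Apply a named variance-stabilising transform.

    ``ln``/``log10`` of values at or below ``floor`` return the transform of
    the floor (a detection-limit convention for zero concentrations, default
    floor 0.01 umol L^-1 when used on nutrients); without a floor they raise
    :class:`DomainError` on non-positive input.  ``sqrt`` and ``ln1p`` require
    non-negative input.
    """
    if kind not in _TRANSFORMS:
        raise ConfigError(f"unknown transform {kind!r}; expected one of {_TRANSFORMS}")
    x = np.asarray(value, dtype=float)
    if kind in ("sqrt", "ln1p"):
        if np.any(x[np.isfinite(x)] < 0):
            raise DomainError(f"{kind} requires non-negative values")
        out = np.sqrt(x) if kind == "sqrt" else np.log1p(x)
    else:
        if floor is not None:
            n_floored = int(np.sum(x[np.isfinite(x)] <= floor))
            if n_floored:
                logger.info(
                    "transform %s: flooring %d value(s) at %g", kind, n_floored, floor
                )
            x = np.maximum(x, floor)
        if np.any(x[np.isfinite(x)] <= 0):
            raise DomainError(f"{kind} of non-positive value with no configured floor")
        out = np.log(x) if kind == "ln" else np.log10(x)
    return float(out) if np.isscalar(value) else out
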