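"""Carbon biomass by phytoplankton group.

Per-cell carbon is estimated from cell biovolume with the power law
``C = a * V^b`` (pg C cell^-1, V in um^3), the standard allometric form for
protist plankton; coefficients are supplied per group via configuration and
may switch to a second pair above a volume threshold (large diatoms are the
usual case).  Carbon concentration (ug C L^-1) is then abundance times
per-cell carbon, summed into the four groups (cyanobacteria, diatoms,
dinoflagellates, other autotrophs), with per-sample group proportions.

Directly measured carbon (a ``carbon`` column) bypasses the conversion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CommunityTable, ConfigError, DomainError, GROUPS
from . import inference

logger = logging.getLogger("saltgrad")

#: pg -> ug
_PG_TO_UG = 1e-6


@dataclass(frozen=True)
class CarbonCoefficients:
    """Power-law coefficients ``C = a * V^b`` for one group.

    ``a`` is in pg C cell^-1 at V = 1 um^3; an optional second pair
    (``a_large``, ``b_large``) applies at volumes >= ``volume_threshold``.
    """

    a: float
    b: float
    volume_threshold: float | None = None
    a_large: float | None = None
    b_large: float | None = None

    def __post_init__(self):
        if not self.a > 0:
            raise ConfigError(f"coefficient a must be > 0, got {self.a}")
        if self.volume_threshold is not None and (
            self.a_large is None or self.b_large is None
        ):
            raise ConfigError("volume_threshold requires a_large and b_large")

    def per_cell_pg(self, biovolume) -> np.ndarray:
        v = np.asarray(biovolume, dtype=float)
        c = self.a * v**self.b
        if self.volume_threshold is not None:
            large = v >= self.volume_threshold
            c = np.where(large, self.a_large * v**self.b_large, c)
        return c


#: Generic protist power law as a sensible default for all four groups.
DEFAULT_COEFFICIENTS = {g: CarbonCoefficients(a=0.216, b=0.939) for g in GROUPS}


def carbon_from_volume(
    biovolume, abundance, coeffs: CarbonCoefficients
) -> np.ndarray:
    """Carbon concentration, ug C L^-1, from per-cell volume and abundance."""
    v = np.asarray(biovolume, dtype=float)
    if np.any(v[np.isfinite(v)] <= 0):
        raise DomainError("biovolume must be > 0")
    return coeffs.per_cell_pg(v) * np.asarray(abundance, dtype=float) * _PG_TO_UG


def add_carbon(
    table: CommunityTable,
    coefficients: dict[str, CarbonCoefficients] | None = None,
) -> CommunityTable:
    """Fill the carbon column where missing, from biovolume and abundance.

    Rows that already carry measured carbon keep it; rows with neither
    carbon nor biovolume are left missing with a logged warning.
    """
    coefficients = coefficients or DEFAULT_COEFFICIENTS
    missing_groups = set(GROUPS) - set(coefficients)
    if missing_groups:
        raise ConfigError(f"no carbon coefficients for group(s) {sorted(missing_groups)}")
    df = table.counts.copy()
    if "carbon" not in df.columns:
        df["carbon"] = np.nan
    need = df["carbon"].isna() & df["biovolume"].notna()
    for g in GROUPS:
        mask = need & (df["group"] == g)
        if mask.any():
            df.loc[mask, "carbon"] = carbon_from_volume(
                df.loc[mask, "biovolume"], df.loc[mask, "abundance"], coefficients[g]
            )
    n_skipped = int((df["carbon"].isna()).sum())
    if n_skipped:
        logger.warning(
            "carbon conversion: %d row(s) lack both carbon and biovolume", n_skipped
        )
    return CommunityTable(counts=df, env=table.env)


def group_totals(table: CommunityTable) -> pd.DataFrame:
    """Carbon summed per (station, year, month, group), with proportions.

    Raises on taxa mapped to no known group.  Samples whose total carbon is
    zero (or entirely missing) get missing proportions.
    """
    df = table.counts
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise DomainError(f"unmapped group label(s): {bad}")
    key = CommunityTable.SAMPLE_KEY
    sums = (
        df.groupby(key + ["group"])["carbon"].sum(min_count=1).rename("carbon").reset_index()
    )
    # complete the grid so every sample reports all four groups
    grid = (
        sums[key]
        .drop_duplicates()
        .merge(pd.DataFrame({"group": list(GROUPS)}), how="cross")
    )
    out = grid.merge(sums, on=key + ["group"], how="left")
    measured = out["carbon"].notna()
    out.loc[measured & (out["carbon"] < 0), "carbon"] = 0.0
    # a group absent from a measured sample has zero carbon, not missing
    sample_has_carbon = out.groupby(key)["carbon"].transform(lambda s: s.notna().any())
    out.loc[sample_has_carbon & out["carbon"].isna(), "carbon"] = 0.0
    totals = out.groupby(key)["carbon"].transform("sum")
    with np.errstate(invalid="ignore"):
        out["proportion"] = np.where(totals > 0, out["carbon"] / totals, np.nan)
    return out


def station_mean_proportions(groups: pd.DataFrame) -> pd.DataFrame:
    """Mean per-sample group proportion per station (ignoring missing)."""
    return (
        groups.dropna(subset=["proportion"])
        .groupby(["station_id", "group"])["proportion"]
        .mean()
        .rename("mean_proportion")
        .reset_index()
    )


def group_proportion_vs_salinity(
    groups: pd.DataFrame, profiles
) -> dict[str, "inference.ModelFit"]:
    """OLS of station-mean group proportion on station mean salinity.

    One fit per group; needs at least three stations with carbon data.
    """
    sal = {p.station_id: p.mean_salinity for p in profiles}
    means = station_mean_proportions(groups)
    means["salinity"] = means["station_id"].map(sal)
    means = means.dropna(subset=["salinity"])
    fits = {}
    for g in GROUPS:
        sub = means[means["group"] == g]
        if len(sub) < 3:
            raise DomainError(
                f"group {g}: need >= 3 stations with carbon data, have {len(sub)}"
            )
        fits[g] = inference.fit_ols(
            sub["salinity"].values, sub["mean_proportion"].values, x_name="salinity"
        )
    return fits


def seasonal_group_profile(groups: pd.DataFrame) -> pd.DataFrame:
    """Mean ln(1 + carbon) per (station, month, group) across years."""
    g = groups.dropna(subset=["carbon"]).copy()
    g["ln1p_carbon"] = np.log1p(g["carbon"])
    return (
        g.groupby(["station_id", "month", "group"])["ln1p_carbon"]
        .mean()
        .reset_index()
    )
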