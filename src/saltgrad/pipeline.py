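"""End-to-end orchestration of the two analysis questions.

Question 1 (spatial): how do station-scale (gamma) and monthly-scale (alpha)
diversity, cell abundance and group biomass composition vary along the
salinity gradient?  Question 2 (seasonal): when do abundance and diversity
peak within the year, does peak timing and amplitude shift with salinity,
and which environmental covariates explain monthly variation?

`prepare` ingests (or generates) the data and applies the preparation rules;
`run_question1` / `run_question2` produce report objects whose tables can be
written as tidy CSVs.  A single top-level seed drives every stochastic stage
through stable per-stage hashes, so reruns with the same config and seed are
bit-identical.
"""

from __future__ import annotations

import contextlib
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomass, diversity, inference, seasonality, synth
from .core import (
    CommunityTable,
    StationProfile,
    aggregate_monthly,
    aggregate_monthly_frames,
    filter_stations,
    pool_to_taxon_units,
    read_monitoring_csv,
    transform,
)
from .diversity import _stable_seed

logger = logging.getLogger("saltgrad")

#: Monthly metrics analysed at the alpha scale throughout Question 2.
ALPHA_METRICS = ("log10_abundance", "alpha_richness", "alpha_ens")


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    community_csv: str | None = None
    environment_csv: str | None = None
    synthetic: synth.SyntheticConfig | None = None
    min_years: int = 10
    min_months_per_year: int = 8
    unit: float = 1.0  # cells L^-1 per counted individual
    alpha_reps: int = 500
    gamma_depth: int | str = "auto"  # "auto" = fewest monthly samples
    gamma_reps: int = 500
    min_months_seasonal: int = 8
    lag: int = 1
    ln_floor: float = 0.01  # detection-limit floor for ln of nutrients
    outlier_station: str | None = "auto"  # "auto" = freshest station
    carbon_coefficients: dict = field(
        default_factory=lambda: dict(biomass.DEFAULT_COEFFICIENTS)
    )
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(enc(self), sort_keys=False))


@dataclass
class PreparedData:
    table: CommunityTable
    profiles: list[StationProfile]

    @property
    def salinity_by_station(self) -> dict[str, float]:
        return {p.station_id: p.mean_salinity for p in self.profiles}


def prepare(config: RunConfig) -> PreparedData:
    """Ingest or generate, aggregate monthly, pool genera, filter stations."""
    if config.synthetic is not None:
        ds = synth.generate(config.synthetic)
        comm = ds.community.rename(
            columns={"abundance_cells_per_l": "abundance", "biovolume_um3": "biovolume"}
        )
        env = ds.environment.rename(
            columns={
                "sst_c": "sst",
                "din_umol_l": "din",
                "dip_umol_l": "dip",
                "silicate_umol_l": "silicate",
            }
        )
        table = aggregate_monthly_frames(comm, env)
    else:
        if config.community_csv is None or config.environment_csv is None:
            raise ValueError("config needs either synthetic or CSV inputs")
        records, env_records, _ = read_monitoring_csv(
            config.community_csv, config.environment_csv
        )
        table = aggregate_monthly(records, env_records)
    table = pool_to_taxon_units(table)
    table, profiles = filter_stations(
        table,
        min_years=config.min_years,
        min_months_per_year=config.min_months_per_year,
    )
    return PreparedData(table=table, profiles=profiles)


# ---------------------------------------------------------------------------
# Shared monthly metric table
# ---------------------------------------------------------------------------


def monthly_metrics(prep: PreparedData, config: RunConfig) -> pd.DataFrame:
    """Per-(station, year, month): log10 abundance and rarefied alpha metrics."""
    table = prep.table
    alpha = diversity.alpha_table(
        table,
        depth=None,
        reps=config.alpha_reps,
        seed=_stable_seed(config.seed, "alpha"),
        unit=config.unit,
    )
    totals = (
        table.counts.groupby(CommunityTable.SAMPLE_KEY)["abundance"]
        .sum()
        .rename("total_cells_all")
        .reset_index()
    )
    out = totals.merge(alpha, on=CommunityTable.SAMPLE_KEY, how="left")
    out["log10_abundance"] = transform(out["total_cells_all"].values, "log10")
    return out.merge(table.env, on=CommunityTable.SAMPLE_KEY, how="left")


def _station_means(monthly: pd.DataFrame, cols) -> pd.DataFrame:
    return monthly.groupby("station_id")[list(cols)].mean().reset_index()


def _pick_outlier(config: RunConfig, prep: PreparedData) -> str | None:
    if config.outlier_station == "auto":
        if not prep.profiles:
            return None
        return min(prep.profiles, key=lambda p: p.mean_salinity).station_id
    return config.outlier_station


def _salinity_regressions(
    station_table: pd.DataFrame,
    responses,
    outlier: str | None,
) -> tuple[dict, dict, dict]:
    """OLS of each response on mean salinity, with outlier refit and
    polynomial check; regressions are skipped (with a message) below 3
    stations."""
    fits, refits, polys = {}, {}, {}
    if len(station_table) < 3:
        logger.warning(
            "only %d station(s): salinity regressions skipped", len(station_table)
        )
        return fits, refits, polys
    x = station_table["mean_salinity"].values
    ids = station_table["station_id"].tolist()
    for resp in responses:
        y = station_table[resp].values
        ok = np.isfinite(y)
        if ok.sum() < 3:
            logger.warning("response %s: fewer than 3 stations with data", resp)
            continue
        fits[resp] = inference.fit_ols(
            x[ok], y[ok], x_name="salinity", response=resp
        )
        if ok.sum() >= 4:
            polys[resp] = inference.compare_polynomial(x[ok], y[ok])
        if outlier is not None and outlier in ids:
            idx = [i for i, (sid, o) in enumerate(zip(ids, ok)) if o and sid == outlier]
            kept_ids = [sid for sid, o in zip(ids, ok) if o]
            excl = [kept_ids.index(outlier)] if outlier in kept_ids else []
            if excl and ok.sum() - len(excl) >= 3:
                refits[resp] = inference.refit_excluding(
                    x[ok], y[ok], excl, x_name="salinity"
                )
    return fits, refits, polys


# ---------------------------------------------------------------------------
# Question 1
# ---------------------------------------------------------------------------


@dataclass
class Question1Report:
    station_table: pd.DataFrame  # per-station metric means + salinity
    gamma: pd.DataFrame
    regressions: dict[str, inference.ModelFit]
    outlier_refits: dict[str, tuple[inference.ModelFit, inference.ModelFit]]
    polynomial_checks: dict[str, inference.PolynomialCheck]
    group_fits: dict[str, inference.ModelFit]
    group_means: pd.DataFrame
    outlier_station: str | None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.station_table.to_csv(out / "station_metrics.csv", index=False)
        self.gamma.to_csv(out / "gamma_diversity.csv", index=False)
        _fits_to_csv(self.regressions, out / "q1_regressions.csv")
        if self.group_fits:
            _fits_to_csv(self.group_fits, out / "group_proportion_regressions.csv")
        if len(self.group_means):
            self.group_means.to_csv(out / "group_mean_proportions.csv", index=False)


def _fits_to_csv(fits: dict[str, inference.ModelFit], path: Path) -> None:
    rows = []
    for name, fit in fits.items():
        for term, c in fit.coefficients.items():
            rows.append(
                {
                    "model": name,
                    "term": term,
                    "estimate": c.estimate,
                    "lower_ci95": c.lower,
                    "upper_ci95": c.upper,
                    "r2": fit.r2,
                    "aic": fit.aic,
                    "n_obs": fit.n_obs,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def run_question1(
    config: RunConfig,
    prep: PreparedData | None = None,
    monthly: pd.DataFrame | None = None,
) -> Question1Report:
    """Gamma/alpha diversity and biomass composition along the gradient."""
    prep = prep or prepare(config)
    monthly = monthly if monthly is not None else monthly_metrics(prep, config)
    table = prep.table

    if config.gamma_depth == "auto":
        m = int(table.samples().groupby("station_id").size().min())
    else:
        m = int(config.gamma_depth)
    gamma = diversity.gamma_table(
        table,
        m=m,
        reps=config.gamma_reps,
        seed=_stable_seed(config.seed, "gamma"),
        unit=config.unit,
    )

    sal = prep.salinity_by_station
    station = _station_means(monthly, ALPHA_METRICS)
    station["mean_salinity"] = station["station_id"].map(sal)
    for metric in ("richness", "ens"):
        g = gamma[gamma["metric"] == metric][["station_id", "value"]]
        station = station.merge(
            g.rename(columns={"value": f"gamma_{metric}"}), on="station_id", how="left"
        )

    outlier = _pick_outlier(config, prep)
    responses = ["gamma_richness", "gamma_ens"] + list(ALPHA_METRICS)
    fits, refits, polys = _salinity_regressions(station, responses, outlier)

    group_fits: dict[str, inference.ModelFit] = {}
    group_means = pd.DataFrame()
    try:
        carbon_table = biomass.add_carbon(table, config.carbon_coefficients)
        groups = biomass.group_totals(carbon_table)
        group_means = biomass.station_mean_proportions(groups)
        group_fits = biomass.group_proportion_vs_salinity(groups, prep.profiles)
    except Exception as exc:
        logger.warning("group biomass analysis skipped: %s", exc)

    return Question1Report(
        station_table=station,
        gamma=gamma,
        regressions=fits,
        outlier_refits=refits,
        polynomial_checks=polys,
        group_fits=group_fits,
        group_means=group_means,
        outlier_station=outlier,
    )


# ---------------------------------------------------------------------------
# Question 2
# ---------------------------------------------------------------------------


@dataclass
class Question2Report:
    zscores: pd.DataFrame
    peaks: pd.DataFrame
    ranges: pd.DataFrame
    peak_regressions: dict[str, inference.ModelFit]
    range_regressions: dict[str, inference.ModelFit]
    correlations: dict[str, tuple[float, float, float]]
    vif: pd.Series | None
    random_structure: dict[str, inference.RandomStructureChoice]
    selections: dict[str, list[inference.ModelFit]]
    selections_lagged: dict[str, list[inference.ModelFit]]
    group_profile: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.zscores.to_csv(out / "zscores.csv", index=False)
        self.peaks.to_csv(out / "peaks.csv", index=False)
        self.ranges.to_csv(out / "ranges.csv", index=False)
        _fits_to_csv(self.peak_regressions, out / "peak_regressions.csv")
        _fits_to_csv(self.range_regressions, out / "range_regressions.csv")
        if len(self.group_profile):
            self.group_profile.to_csv(out / "group_seasonal_profile.csv", index=False)
        rows = []
        for resp, fits in {**self.selections}.items():
            for f in fits:
                rows.append(
                    {
                        "response": resp,
                        "model": f.spec.formula,
                        "r2_marginal": f.r2_marginal,
                        "r2_conditional": f.r2_conditional,
                        "aic": f.aic,
                        "aic_weight": f.aic_weight,
                    }
                )
        if rows:
            pd.DataFrame(rows).to_csv(out / "model_table.csv", index=False)
            crows = []
            for resp, fits in self.selections.items():
                best = fits[0]
                for term, c in best.coefficients.items():
                    crows.append(
                        {
                            "response": resp,
                            "term": term,
                            "estimate": c.estimate,
                            "lower_ci95": c.lower,
                            "upper_ci95": c.upper,
                        }
                    )
            pd.DataFrame(crows).to_csv(out / "coefficients.csv", index=False)


def inference_frame(monthly: pd.DataFrame, prep: PreparedData, config: RunConfig):
    """Monthly modelling frame: transformed responses and covariates.

    Mean *station-level* salinity (not the monthly value) enters as the
    spatial covariate; rows with incomplete covariates are dropped by the
    model layer.
    """
    df = monthly.copy()
    sal = prep.salinity_by_station
    df["salinity"] = df["station_id"].map(sal)
    for col, name in (("din", "ln_din"), ("dip", "ln_dip")):
        if col in df.columns and df[col].notna().any():
            df[name] = transform(df[col].values, "ln", floor=config.ln_floor)
    if "silicate" in df.columns and df["silicate"].notna().any():
        df["sqrt_silicate"] = transform(df["silicate"].values, "sqrt")
    for col in ("alpha_richness", "alpha_ens"):
        if col in df.columns:
            df[f"sqrt_{col}"] = transform(df[col].fillna(np.nan).values, "sqrt")
    return df


def run_question2(
    config: RunConfig,
    prep: PreparedData | None = None,
    monthly: pd.DataFrame | None = None,
) -> Question2Report:
    """Seasonality, peak timing vs salinity, and mixed-model inference."""
    prep = prep or prepare(config)
    monthly = monthly if monthly is not None else monthly_metrics(prep, config)
    sal = prep.salinity_by_station

    zscores, peaks, ranges = seasonality.seasonal_tables(
        monthly, list(ALPHA_METRICS), min_months=config.min_months_seasonal
    )

    peak_fits: dict[str, inference.ModelFit] = {}
    range_fits: dict[str, inference.ModelFit] = {}
    for metric in ALPHA_METRICS:
        p = peaks[peaks["metric"] == metric].copy()
        if len(p) >= 3:
            p["mean_salinity"] = p["station_id"].map(sal)
            peak_fits[metric] = inference.fit_ols(
                p["mean_salinity"].values,
                p["circular_mean_peak"].values,
                x_name="salinity",
                response=f"peak_month_{metric}",
            )
        r = ranges[ranges["metric"] == metric].copy()
        if len(r) >= 3:
            r["mean_salinity"] = r["station_id"].map(sal)
            range_fits[metric] = inference.fit_ols(
                r["mean_salinity"].values,
                r["mean_within_year_range"].values,
                x_name="salinity",
                response=f"range_{metric}",
            )

    frame = inference_frame(monthly, prep, config)
    correlations: dict[str, tuple[float, float, float]] = {}
    vif_table = None
    random_structure: dict[str, inference.RandomStructureChoice] = {}
    selections: dict[str, list[inference.ModelFit]] = {}
    selections_lagged: dict[str, list[inference.ModelFit]] = {}

    have_covariates = {"ln_din", "sqrt_silicate", "salinity"} <= set(frame.columns)
    if have_covariates:
        screen_cols = [
            c for c in ("ln_din", "sst", "ln_dip", "sqrt_silicate", "salinity")
            if c in frame.columns
        ]
        screen = frame[screen_cols].dropna()
        if "sst" in screen.columns and len(screen) >= 4:
            correlations["ln_din~sst"] = inference.pearson_ci(
                screen["ln_din"], screen["sst"]
            )
        if "ln_dip" in screen.columns and len(screen) >= 4:
            correlations["ln_din~ln_dip"] = inference.pearson_ci(
                screen["ln_din"], screen["ln_dip"]
            )
        if len(screen) > len(screen_cols) and len(screen_cols) >= 2:
            vif_table = inference.vif(screen[screen_cols])

        responses = {
            "log10_abundance": "log10_abundance",
            "sqrt_alpha_richness": "sqrt_alpha_richness",
            "sqrt_alpha_ens": "sqrt_alpha_ens",
        }
        global_terms = ("salinity", "ln_din", "sqrt_silicate", "ln_din:salinity")
        lagged, unlagged = inference.lag_covariates(
            frame, ["ln_din", "sqrt_silicate"], lag=config.lag
        )
        for resp in responses.values():
            if resp not in frame.columns:
                continue
            spec = inference.ModelSpec(
                response=resp,
                fixed_terms=global_terms,
                random_intercept="station_id",
            )
            try:
                random_structure[resp] = inference.random_structure_choice(spec, frame)
                selections[resp] = inference.model_selection(
                    unlagged, resp, random_intercept="station_id"
                )
                if config.lag:
                    selections_lagged[resp] = inference.model_selection(
                        lagged, resp, random_intercept="station_id"
                    )
            except inference.SaltgradError as exc:
                logger.warning("inference for %s skipped: %s", resp, exc)
    else:
        logger.warning(
            "environmental covariates incomplete: question 2 inference skipped"
        )

    group_profile = pd.DataFrame()
    try:
        carbon_table = biomass.add_carbon(prep.table, config.carbon_coefficients)
        group_profile = biomass.seasonal_group_profile(
            biomass.group_totals(carbon_table)
        )
    except Exception as exc:
        logger.warning("seasonal group profile skipped: %s", exc)

    return Question2Report(
        zscores=zscores,
        peaks=peaks,
        ranges=ranges,
        peak_regressions=peak_fits,
        range_regressions=range_fits,
        correlations=correlations,
        vif=vif_table,
        random_structure=random_structure,
        selections=selections,
        selections_lagged=selections_lagged,
        group_profile=group_profile,
    )


@contextlib.contextmanager
def run_log(out_dir: str | Path):
    """Tee the package logger into ``<out_dir>/run.log``.

    The log records ingestion counts, every filter count, floor applications
    and skipped stages — the provenance trail of a run.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    old_level = logger.level
    if logger.level > logging.INFO or logger.level == logging.NOTSET:
        logger.setLevel(logging.INFO)
    try:
        yield
    finally:
        logger.setLevel(old_level)
        logger.removeHandler(handler)
        handler.close()


def run_all(config: RunConfig, out_dir: str | Path | None = None):
    """Prepare once, run both questions, optionally write everything."""
    if out_dir is not None:
        with run_log(out_dir):
            prep = prepare(config)
            monthly = monthly_metrics(prep, config)
            q1 = run_question1(config, prep=prep, monthly=monthly)
            q2 = run_question2(config, prep=prep, monthly=monthly)
        out = Path(out_dir)
        config.to_yaml(out / "run_config.yaml")
        q1.write(out)
        q2.write(out)
        return q1, q2
    prep = prepare(config)
    monthly = monthly_metrics(prep, config)
    q1 = run_question1(config, prep=prep, monthly=monthly)
    q2 = run_question2(config, prep=prep, monthly=monthly)
    return q1, q2
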