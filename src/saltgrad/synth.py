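"""Synthetic monitoring-data generator with known ground truth.

Emulates a coastal monitoring programme sampling nano-/microphytoplankton
monthly at stations spanning a strong salinity gradient (brackish ~3 PSU to
marine ~35 PSU): a species pool whose group composition shifts with salinity
(cyanobacteria decline, diatoms rise), seasonal bloom dynamics whose peak
month moves earlier with increasing salinity, and seasonally cycling
temperature and nutrient covariates.  Every structural parameter is recorded
in a :class:`GroundTruth` object so that pipeline outputs can be checked
against what was simulated.

Model, per station s with mean salinity ``sal_s`` and month m:

* group share  ``share_g(sal) = L_g(sal) / sum_h L_h(sal)`` with logistic
  ``L_g(sal) = 1 / (1 + exp(-slope_g (sal - mid_g)))``;
* station species pool per group: the top ``k_g(sal)`` ranks of the group
  pool, ``k_g = max(1, round(pool_g * (0.15 + 0.85 L_g(sal))))`` — richness
  tracks the same logistic response as abundance share;
* within-group relative abundance: geometric rank-abundance profile;
* seasonal factor ``exp(A cos(2 pi (m - mu_s) / 12))`` with bloom peak month
  ``mu_s = (peak_intercept + peak_slope * sal_s) mod 12``;
* an environmental coupling multiplying expected abundance by
  ``10 ** (b_DIN c + b_DINxSAL c (sal_s - sal_mean))`` where c is the
  *seasonal anomaly* of ln DIN (observed minus the noise-free annual cycle),
  so the true DIN effect and DIN-by-salinity interaction on log10 abundance
  are known while bloom timing stays governed by the peak-month parameters
  alone;
* per-taxon counts lognormal around the expectation (mean-preserving), with
  a detection limit below which a taxon is unrecorded.

Counts are cells per litre; environment variables follow sinusoidal annual
cycles plus Gaussian noise, clipped at zero for concentrations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigError, GROUPS

logger = logging.getLogger("saltgrad")


@dataclass(frozen=True)
class GroupResponse:
    """Logistic salinity response of one group: midpoint (PSU) and slope."""

    midpoint: float
    slope: float

    def __call__(self, salinity):
        return 1.0 / (1.0 + np.exp(-self.slope * (np.asarray(salinity) - self.midpoint)))


@dataclass(frozen=True)
class EnvCycle:
    """Annual sinusoid for an environment variable.

    ``peak_month`` is the (0-based, fractional) month of the maximum;
    values are ``mean + amplitude * cos(2 pi (m - peak_month)/12) + noise``.
    """

    mean: float
    amplitude: float
    peak_month: float
    noise_sd: float
    floor: float | None = 0.0  # clip at this value; None = unclipped (SST)

    def sample(self, months: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = self.mean + self.amplitude * np.cos(
            2 * np.pi * (months - self.peak_month) / 12.0
        )
        x = x + rng.normal(0.0, self.noise_sd, size=months.shape)
        if self.floor is not None:
            x = np.maximum(x, self.floor)
        return x


DEFAULT_GROUP_RESPONSES = {
    "cyanobacteria": GroupResponse(midpoint=10.0, slope=-0.30),
    "diatoms": GroupResponse(midpoint=15.0, slope=0.20),
    # dinoflagellates favour marine water but less steeply than diatoms, so
    # their (large-celled) carbon share does not swamp the diatom gradient
    "dinoflagellates": GroupResponse(midpoint=18.0, slope=0.08),
    "other_autotrophs": GroupResponse(midpoint=10.0, slope=0.05),
}

DEFAULT_POOL_SIZES = {
    "cyanobacteria": 30,
    "diatoms": 120,
    "dinoflagellates": 60,
    "other_autotrophs": 50,
}

DEFAULT_ENV_CYCLES = {
    # DIN/DIP/silicate peak in winter, SST in late summer: DIN and SST are
    # strongly negatively correlated, as in temperate coastal seas.
    "sst": EnvCycle(mean=10.0, amplitude=7.0, peak_month=7.0, noise_sd=1.0, floor=None),
    "din": EnvCycle(mean=6.0, amplitude=4.0, peak_month=0.5, noise_sd=0.8, floor=0.05),
    "dip": EnvCycle(mean=0.55, amplitude=0.35, peak_month=0.5, noise_sd=0.08, floor=0.01),
    "silicate": EnvCycle(mean=12.0, amplitude=6.0, peak_month=0.5, noise_sd=1.5, floor=0.1),
}

#: Group-typical per-cell biovolumes (um^3) used as lognormal medians.
GROUP_BIOVOLUME_MEDIAN = {
    "cyanobacteria": 50.0,
    "diatoms": 2000.0,
    "dinoflagellates": 8000.0,
    "other_autotrophs": 300.0,
}


@dataclass
class SyntheticConfig:
    """All structural parameters of a synthetic monitoring dataset.

    Defaults emulate the study design the package targets: 19 stations
    spanning salinity 2.8-35 PSU sampled monthly for 19 years.
    """

    n_stations: int = 19
    salinity_range: tuple[float, float] = (2.8, 35.0)
    n_years: int = 19
    months_per_year: int = 12
    start_year: int = 1999
    pool_size_by_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POOL_SIZES)
    )
    group_salinity_response: dict[str, GroupResponse] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_RESPONSES)
    )
    # Bloom timing: peak month mu(s) = (peak_intercept + peak_slope * sal) mod 12.
    peak_slope: float = -0.15  # months per PSU
    peak_intercept: float = 8.0  # late-summer peak at the freshest stations
    bloom_amplitude: float = 1.0  # ln-scale seasonal amplitude
    env_cycles: dict[str, EnvCycle] = field(
        default_factory=lambda: dict(DEFAULT_ENV_CYCLES)
    )
    total_abundance: float = 5e5  # cells L^-1 community total at season mean
    rank_abundance_theta: float = 0.85  # geometric profile parameter
    detection_limit: float = 0.5  # cells L^-1
    abundance_noise_sigma: float = 0.8  # lognormal sigma on counts
    salinity_noise_sd: float = 0.3  # month-to-month salinity jitter
    din_effect: float = 0.25  # log10-abundance per centred ln-DIN unit
    din_x_salinity: float = -0.010  # interaction with (sal - mean sal)
    bothnia_outlier: bool = False  # enlarge the freshest station's pool
    bothnia_pool_boost: float = 1.6
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.salinity_range
        if not lo < hi:
            raise ConfigError(f"salinity_range must increase, got {self.salinity_range}")
        for name, v in (
            ("n_stations", self.n_stations),
            ("n_years", self.n_years),
            ("months_per_year", self.months_per_year),
        ):
            if v <= 0:
                raise ConfigError(f"{name} must be > 0, got {v}")
        if self.months_per_year > 12:
            raise ConfigError("months_per_year cannot exceed 12")
        if not 0 < self.rank_abundance_theta < 1:
            raise ConfigError("rank_abundance_theta must be in (0, 1)")
        if set(self.pool_size_by_group) != set(GROUPS):
            raise ConfigError(f"pool_size_by_group must cover exactly {GROUPS}")
        if any(v <= 0 for v in self.pool_size_by_group.values()):
            raise ConfigError("pool sizes must be > 0")

    # -- deterministic expectation helpers (no noise), used by ground truth --

    def station_salinities(self) -> np.ndarray:
        lo, hi = self.salinity_range
        return np.linspace(lo, hi, self.n_stations)

    def group_shares(self, salinity) -> dict[str, np.ndarray]:
        raw = {g: self.group_salinity_response[g](salinity) for g in GROUPS}
        total = sum(raw.values())
        return {g: raw[g] / total for g in GROUPS}

    def station_pool_sizes(self, salinity) -> dict[str, np.ndarray]:
        out = {}
        for g in GROUPS:
            frac = 0.15 + 0.85 * self.group_salinity_response[g](salinity)
            out[g] = np.maximum(
                1, np.round(self.pool_size_by_group[g] * frac)
            ).astype(int)
        return out

    def expected_peak_month(self, salinity) -> np.ndarray:
        return np.mod(self.peak_intercept + self.peak_slope * np.asarray(salinity), 12.0)

    def seasonal_factor(self, month, salinity) -> np.ndarray:
        mu = self.expected_peak_month(salinity)
        return np.exp(
            self.bloom_amplitude * np.cos(2 * np.pi * (np.asarray(month) - mu) / 12.0)
        )


@dataclass
class GroundTruth:
    """True structural parameters recorded alongside a generated dataset."""

    station_ids: list[str]
    station_salinity: dict[str, float]
    group_share_by_station: dict[str, dict[str, float]]
    #: expected biovolume-weighted (~carbon) group shares, using the drawn
    #: per-taxon cell volumes — the reference for biomass-composition checks
    biovolume_share_by_station: dict[str, dict[str, float]]
    pool_size_by_station: dict[str, int]
    peak_slope: float
    peak_intercept: float
    expected_peak_month: dict[str, float]
    din_effect: float
    din_x_salinity: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticDataset:
    """A generated dataset: date-level long tables plus the ground truth."""

    community: pd.DataFrame  # station_id, date, taxon_id, taxon_rank, group,
    #                          abundance_cells_per_l, biovolume_um3
    environment: pd.DataFrame  # station_id, date, salinity, sst_c, din_umol_l,
    #                            dip_umol_l, silicate_umol_l
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> tuple[Path, Path, Path]:
        """Write community.csv, environment.csv and ground_truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cpath, epath, tpath = (
            out / "community.csv",
            out / "environment.csv",
            out / "ground_truth.json",
        )
        self.community.to_csv(cpath, index=False, float_format="%.6g")
        self.environment.to_csv(epath, index=False, float_format="%.6g")
        self.truth.to_json(tpath)
        return cpath, epath, tpath


def _taxon_names(group: str, n: int) -> list[str]:
    prefix = {
        "cyanobacteria": "Cyanophyra",
        "diatoms": "Bacillaria",
        "dinoflagellates": "Dinophysa",
        "other_autotrophs": "Flagellaria",
    }[group]
    return [f"{prefix} taxon{r:03d}" for r in range(n)]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sal_means = config.station_salinities()
    station_ids = [f"ST{i + 1:02d}" for i in range(config.n_stations)]
    years = np.arange(config.start_year, config.start_year + config.n_years)
    if config.months_per_year == 12:
        months = np.arange(12)
    else:
        # spread sampled months evenly over the year (e.g. ice-free season)
        months = np.round(np.linspace(0, 11, config.months_per_year)).astype(int)

    pool_sizes = config.station_pool_sizes(sal_means)
    shares = config.group_shares(sal_means)
    mean_sal = float(np.mean(sal_means))

    # Fixed per-taxon biovolumes, drawn once per group pool.
    taxa_by_group = {
        g: _taxon_names(g, config.pool_size_by_group[g]) for g in GROUPS
    }
    biovol_by_taxon: dict[str, float] = {}
    for g in GROUPS:
        draws = GROUP_BIOVOLUME_MEDIAN[g] * np.exp(
            rng.normal(0.0, 0.8, size=len(taxa_by_group[g]))
        )
        biovol_by_taxon.update(zip(taxa_by_group[g], draws))

    n_months = len(years) * len(months)
    ym = [(int(y), int(m)) for y in years for m in months]
    month_arr = np.array([m for _, m in ym], dtype=float)

    din_cycle = config.env_cycles["din"]
    din_expected = din_cycle.mean + din_cycle.amplitude * np.cos(
        2 * np.pi * (month_arr - din_cycle.peak_month) / 12.0
    )
    if din_cycle.floor is not None:
        din_expected = np.maximum(din_expected, max(din_cycle.floor, 1e-6))
    ln_din_expected = np.log(din_expected)

    comm_rows: list[pd.DataFrame] = []
    env_rows: list[pd.DataFrame] = []
    truth_share: dict[str, dict[str, float]] = {}
    truth_bv_share: dict[str, dict[str, float]] = {}
    truth_pool: dict[str, int] = {}

    for si, sid in enumerate(station_ids):
        sal_s = sal_means[si]
        # environment series
        sal_obs = np.maximum(
            sal_s + rng.normal(0.0, config.salinity_noise_sd, size=n_months), 0.0
        )
        env = {
            name: cyc.sample(month_arr, rng)
            for name, cyc in config.env_cycles.items()
        }
        dates = [f"{y}-{m + 1:02d}-15" for y, m in ym]
        env_rows.append(
            pd.DataFrame(
                {
                    "station_id": sid,
                    "date": dates,
                    "salinity": sal_obs,
                    "sst_c": env["sst"],
                    "din_umol_l": env["din"],
                    "dip_umol_l": env["dip"],
                    "silicate_umol_l": env["silicate"],
                }
            )
        )

        seasonal = config.seasonal_factor(month_arr, sal_s)
        ln_din_c = np.log(np.maximum(env["din"], 1e-6)) - ln_din_expected
        env_mult = 10.0 ** (
            config.din_effect * ln_din_c
            + config.din_x_salinity * ln_din_c * (sal_s - mean_sal)
        )

        boost = (
            config.bothnia_pool_boost
            if (config.bothnia_outlier and si == 0)
            else 1.0
        )
        station_taxa: list[str] = []
        station_groups: list[str] = []
        station_p: list[np.ndarray] = []
        bv_weight: dict[str, float] = {}
        for g in GROUPS:
            k = int(min(round(pool_sizes[g][si] * boost), config.pool_size_by_group[g]))
            ranks = np.arange(k)
            p = config.rank_abundance_theta**ranks
            p = p / p.sum()
            station_taxa.extend(taxa_by_group[g][:k])
            station_groups.extend([g] * k)
            station_p.append(p * shares[g][si] * config.total_abundance)
            vols = np.array([biovol_by_taxon[t] for t in taxa_by_group[g][:k]])
            bv_weight[g] = float(shares[g][si] * np.sum(p * vols))
        expect = np.concatenate(station_p)  # cells/L at seasonal factor 1

        truth_share[sid] = {g: float(shares[g][si]) for g in GROUPS}
        bv_total = sum(bv_weight.values())
        truth_bv_share[sid] = {g: bv_weight[g] / bv_total for g in GROUPS}
        truth_pool[sid] = len(station_taxa)

        # counts: lognormal mean-preserving noise around the expectation
        sig = config.abundance_noise_sigma
        z = rng.normal(0.0, 1.0, size=(n_months, len(station_taxa)))
        counts = (
            expect[None, :]
            * (seasonal * env_mult)[:, None]
            * np.exp(sig * z - 0.5 * sig**2)
        )
        detected = counts >= config.detection_limit
        t_idx, x_idx = np.nonzero(detected)
        taxa_arr = np.array(station_taxa)
        groups_arr = np.array(station_groups)
        comm_rows.append(
            pd.DataFrame(
                {
                    "station_id": sid,
                    "date": np.array(dates)[t_idx],
                    "taxon_id": taxa_arr[x_idx],
                    "taxon_rank": "species",
                    "group": groups_arr[x_idx],
                    "abundance_cells_per_l": counts[t_idx, x_idx],
                    "biovolume_um3": np.array(
                        [biovol_by_taxon[t] for t in taxa_arr]
                    )[x_idx],
                }
            )
        )

    community = pd.concat(comm_rows, ignore_index=True)
    environment = pd.concat(env_rows, ignore_index=True)
    truth = GroundTruth(
        station_ids=station_ids,
        station_salinity={sid: float(s) for sid, s in zip(station_ids, sal_means)},
        group_share_by_station=truth_share,
        biovolume_share_by_station=truth_bv_share,
        pool_size_by_station=truth_pool,
        peak_slope=config.peak_slope,
        peak_intercept=config.peak_intercept,
        expected_peak_month={
            sid: float(config.expected_peak_month(s))
            for sid, s in zip(station_ids, sal_means)
        },
        din_effect=config.din_effect,
        din_x_salinity=config.din_x_salinity,
    )
    logger.info(
        "generated %d community rows at %d stations x %d station-months",
        len(community),
        config.n_stations,
        n_months,
    )
    return SyntheticDataset(community=community, environment=environment, truth=truth)


def degrade(
    dataset: SyntheticDataset,
    missing_month_rate: float,
    seed: int,
    warn_threshold: float = 0.8,
) -> SyntheticDataset:
    """Remove station-months at the given rate (reproducible given seed).

    Emulates the varying completeness of real monitoring series.  Rates at or
    above ``warn_threshold`` trigger a warning: the default station filter may
    then retain no stations.
    """
    if not 0 <= missing_month_rate < 1:
        raise ConfigError(f"missing_month_rate must be in [0, 1), got {missing_month_rate}")
    if missing_month_rate == 0:
        return dataset
    if missing_month_rate >= warn_threshold:
        warnings.warn(
            f"missing_month_rate={missing_month_rate} may leave no station "
            "passing the default completeness filter",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    key = dataset.community[["station_id", "date"]].drop_duplicates()
    keep_mask = rng.random(len(key)) >= missing_month_rate
    kept = key[keep_mask]
    community = dataset.community.merge(kept, on=["station_id", "date"])
    environment = dataset.environment.merge(kept, on=["station_id", "date"])
    return SyntheticDataset(
        community=community.reset_index(drop=True),
        environment=environment.reset_index(drop=True),
        truth=dataset.truth,
    )


def simulate_mixed_model_data(
    beta: dict[str, float],
    n_stations: int = 19,
    n_obs_per_station: int = 105,
    sigma_station: float = 0.5,
    sigma_resid: float = 0.5,
    salinity_range: tuple[float, float] = (2.8, 35.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate monthly observations directly from the random-intercept model.

    The linear predictor uses terms named as in the inference layer:
    ``intercept``, ``salinity`` (station mean), ``ln_din``, ``sqrt_silicate``
    and ``ln_din:salinity``.  Covariates follow the synthetic environment
    cycles.  Used for selection-consistency and coverage checks against known
    coefficients.
    """
    rng = np.random.default_rng(seed)
    sal = np.linspace(*salinity_range, n_stations)
    months = rng.integers(0, 12, size=(n_stations, n_obs_per_station)).astype(float)
    din = DEFAULT_ENV_CYCLES["din"].sample(months.ravel(), rng).reshape(months.shape)
    sil = DEFAULT_ENV_CYCLES["silicate"].sample(months.ravel(), rng).reshape(months.shape)
    ln_din = np.log(np.maximum(din, 1e-6))
    sqrt_sil = np.sqrt(sil)
    station_eff = rng.normal(0.0, sigma_station, size=n_stations)
    rows = []
    for i in range(n_stations):
        eta = (
            beta.get("intercept", 0.0)
            + beta.get("salinity", 0.0) * sal[i]
            + beta.get("ln_din", 0.0) * ln_din[i]
            + beta.get("sqrt_silicate", 0.0) * sqrt_sil[i]
            + beta.get("ln_din:salinity", 0.0) * ln_din[i] * sal[i]
        )
        y = eta + station_eff[i] + rng.normal(0.0, sigma_resid, size=n_obs_per_station)
        rows.append(
            pd.DataFrame(
                {
                    "station_id": f"ST{i + 1:02d}",
                    "salinity": sal[i],
                    "ln_din": ln_din[i],
                    "sqrt_silicate": sqrt_sil[i],
                    "response": y,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
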