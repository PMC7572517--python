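import datetime as dt

import pandas as pd
import pytest

from saltgrad import core, synth


def rec(station, date, taxon, abundance, rank="species", group="diatoms", **kw):
    return core.MonitoringRecord(
        station_id=station,
        sample_date=dt.date.fromisoformat(date),
        taxon_id=taxon,
        taxon_rank=core.TaxonRank(rank),
        group=group,
        abundance=abundance,
        **kw,
    )


def env(station, date, **kw):
    return core.EnvironmentRecord(
        station_id=station, sample_date=dt.date.fromisoformat(date), **kw
    )


@pytest.fixture
def two_date_month():
    """One station-month sampled on two dates; taxon B absent on date 2."""
    records = [
        rec("S1", "2010-05-03", "Taxon alpha", 100.0),
        rec("S1", "2010-05-03", "Taxon beta", 100.0),
        rec("S1", "2010-05-20", "Taxon alpha", 300.0),
    ]
    envs = [
        env("S1", "2010-05-03", salinity=7.0, din=5.0),
        env("S1", "2010-05-20", salinity=9.0, din=3.0),
    ]
    return records, envs


@pytest.fixture
def small_config():
    """A fast-but-structured synthetic config for pipeline-level tests."""
    return synth.SyntheticConfig(
        n_stations=8,
        salinity_range=(3.0, 35.0),
        n_years=6,
        pool_size_by_group={
            "cyanobacteria": 12,
            "diatoms": 40,
            "dinoflagellates": 20,
            "other_autotrophs": 16,
        },
        total_abundance=2e4,
        seed=42,
    )


@pytest.fixture
def small_dataset(small_config):
    return synth.generate(small_config)


def write_csvs(tmp_path, community_rows, environment_rows):
    """Write raw CSV text fixtures and return their paths."""
    cpath = tmp_path / "community.csv"
    epath = tmp_path / "environment.csv"
    cpath.write_text("\n".join(community_rows) + "\n")
    epath.write_text("\n".join(environment_rows) + "\n")
    return cpath, epath


COMM_HEADER = (
    "station_id,date,taxon_id,taxon_rank,group,abundance_cells_per_l,biovolume_um3"
)
ENV_HEADER = "station_id,date,salinity,sst_c,din_umol_l,dip_umol_l,silicate_umol_l"
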