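import math

import numpy as np
import pytest

from saltgrad import core

from conftest import COMM_HEADER, ENV_HEADER, env, rec, write_csvs


class TestIngestion:
    def test_valid_rows_become_records(self, tmp_path):
        cpath, epath = write_csvs(
            tmp_path,
            [
                COMM_HEADER,
                "S1,2010-05-03,Skeletonema marinoi,species,diatoms,1200,800",
                "S1,2010-05-03,Nodularia spumigena,species,cyanobacteria,300,",
                "S2,2010-06-11,Chaetoceros sp.1,genus,diatoms,50,400",
            ],
            [ENV_HEADER, "S1,2010-05-03,7.2,12.1,4.5,0.4,11"],
        )
        records, envs, errors = core.read_monitoring_csv(cpath, epath)
        assert len(records) == 3 and len(envs) == 1 and errors == []
        assert records[0].abundance == 1200
        assert records[1].biovolume is None
        assert records[2].taxon_rank is core.TaxonRank.GENUS
        assert envs[0].salinity == 7.2

    def test_negative_abundance_is_a_row_error(self, tmp_path):
        cpath, epath = write_csvs(
            tmp_path,
            [
                COMM_HEADER,
                "S1,2010-05-03,Taxon a,species,diatoms,-5,",
            ],
            [ENV_HEADER, "S1,2010-05-03,7.2,,,,"],
        )
        with pytest.raises(core.ValidationError) as exc:
            core.read_monitoring_csv(cpath, epath)
        assert exc.value.row_errors[0].line == 2

    def test_error_fraction_tolerated_when_configured(self, tmp_path):
        rows = [COMM_HEADER] + [
            f"S1,2010-0{m}-03,Taxon a,species,diatoms,10," for m in range(1, 9)
        ]
        rows.append("S1,2010-09-03,Taxon a,species,diatoms,not-a-number,")
        cpath, epath = write_csvs(tmp_path, rows, [ENV_HEADER, "S1,2010-05-03,7,,,,"])
        records, _, errors = core.read_monitoring_csv(
            cpath, epath, max_error_fraction=0.5
        )
        assert len(records) == 8
        assert len(errors) == 1 and errors[0].line == 10

    def test_missing_column_is_schema_error(self, tmp_path):
        cpath, epath = write_csvs(
            tmp_path,
            ["station_id,date,taxon_id", "S1,2010-05-03,x"],
            [ENV_HEADER, "S1,2010-05-03,7,,,,"],
        )
        with pytest.raises(core.SchemaError):
            core.read_monitoring_csv(cpath, epath)

    def test_duplicate_environment_row_later_wins(self, tmp_path):
        cpath, epath = write_csvs(
            tmp_path,
            [COMM_HEADER, "S1,2010-05-03,Taxon a,species,diatoms,10,"],
            [
                ENV_HEADER,
                "S1,2010-05-03,7.0,,,,",
                "S1,2010-05-03,9.0,,,,",
            ],
        )
        _, envs, _ = core.read_monitoring_csv(cpath, epath)
        assert len(envs) == 1 and envs[0].salinity == 9.0


class TestAggregateMonthly:
    def test_mean_over_dates(self, two_date_month):
        records, envs = two_date_month
        table = core.aggregate_monthly(records, envs)
        row = table.counts.set_index("taxon_id")
        assert row.loc["Taxon alpha", "abundance"] == 200.0

    def test_absence_on_one_date_counts_as_zero(self, two_date_month):
        records, envs = two_date_month
        table = core.aggregate_monthly(records, envs)
        row = table.counts.set_index("taxon_id")
        assert row.loc["Taxon beta", "abundance"] == 50.0  # (100 + 0) / 2

    def test_environment_is_monthly_mean(self, two_date_month):
        records, envs = two_date_month
        table = core.aggregate_monthly(records, envs)
        assert table.env.loc[0, "salinity"] == pytest.approx(8.0)
        assert table.env.loc[0, "din"] == pytest.approx(4.0)

    def test_single_sample_month_unchanged(self):
        table = core.aggregate_monthly(
            [rec("S1", "2011-07-09", "Taxon a", 123.0)], []
        )
        assert table.counts.loc[0, "abundance"] == 123.0
        assert table.counts.loc[0, "month"] == 6  # July is month 6

    def test_idempotent_on_monthly_data(self, two_date_month):
        records, envs = two_date_month
        once = core.aggregate_monthly(records, envs)
        again = core.aggregate_monthly_frames(
            once.counts.assign(
                date=[f"{y}-{m + 1:02d}-01" for y, m in zip(once.counts.year, once.counts.month)]
            ),
            None,
        )
        left = once.counts.sort_values("taxon_id").reset_index(drop=True)
        right = again.counts.sort_values("taxon_id").reset_index(drop=True)
        assert np.allclose(left["abundance"], right["abundance"])


class TestPooling:
    def _table(self, *recs):
        return core.aggregate_monthly(list(recs), [])

    def test_morphotypes_pool_to_genus_unit(self):
        table = self._table(
            rec("S1", "2010-05-03", "Chaetoceros sp.1", 10.0, rank="genus"),
            rec("S1", "2010-05-03", "Chaetoceros sp.2", 20.0, rank="genus"),
        )
        pooled = core.pool_to_taxon_units(table)
        assert pooled.counts["taxon_id"].tolist() == ["Chaetoceros spp."]
        assert pooled.counts["abundance"].iloc[0] == 30.0

    def test_determined_species_stay_separate(self):
        table = self._table(
            rec("S1", "2010-05-03", "Chaetoceros danicus", 10.0),
            rec("S1", "2010-05-03", "Chaetoceros decipiens", 20.0),
        )
        pooled = core.pool_to_taxon_units(table)
        assert len(pooled.counts) == 2

    def test_single_taxon_unchanged(self):
        table = self._table(rec("S1", "2010-05-03", "Chaetoceros sp.1", 10.0, rank="genus"))
        pooled = core.pool_to_taxon_units(table)
        assert pooled.counts["abundance"].iloc[0] == 10.0

    def test_total_abundance_conserved_per_sample(self, small_dataset):
        comm = small_dataset.community.rename(
            columns={"abundance_cells_per_l": "abundance", "biovolume_um3": "biovolume"}
        )
        table = core.aggregate_monthly_frames(comm, None)
        pooled = core.pool_to_taxon_units(table)
        key = core.CommunityTable.SAMPLE_KEY
        before = table.counts.groupby(key)["abundance"].sum()
        after = pooled.counts.groupby(key)["abundance"].sum()
        assert np.allclose(before.values, after.values)


class TestFilterStations:
    def _station(self, sid, years, months_per_year):
        return [
            rec(sid, f"{y}-{m + 1:02d}-10", "Taxon a", 10.0)
            for y in years
            for m in range(months_per_year)
        ]

    def test_complete_station_retained(self):
        table = core.aggregate_monthly(
            self._station("S1", range(2000, 2012), 12), []
        )
        out, profiles = core.filter_stations(table)
        assert profiles[0].station_id == "S1"
        assert profiles[0].n_monthly_samples == 144

    def test_exactly_min_years_dropped(self):
        # 10 qualifying years is not *more than* 10
        records = self._station("S1", range(2000, 2010), 12) + self._station(
            "S2", range(2000, 2012), 12
        )
        table = core.aggregate_monthly(records, [])
        out, profiles = core.filter_stations(table)
        assert [p.station_id for p in profiles] == ["S2"]

    def test_sparse_years_do_not_qualify(self):
        records = self._station("S1", range(2000, 2015), 6) + self._station(
            "S2", range(2000, 2012), 12
        )
        table = core.aggregate_monthly(records, [])
        out, _ = core.filter_stations(table)
        assert out.stations() == ["S2"]

    def test_all_filtered_raises(self):
        table = core.aggregate_monthly(self._station("S1", range(2000, 2003), 12), [])
        with pytest.raises(core.EmptyResultError):
            core.filter_stations(table)

    @pytest.mark.parametrize("min_years", [2, 5, 8, 11])
    def test_raising_min_years_is_monotone(self, min_years):
        records = (
            self._station("S1", range(2000, 2004), 12)
            + self._station("S2", range(2000, 2007), 12)
            + self._station("S3", range(2000, 2012), 12)
        )
        table = core.aggregate_monthly(records, [])
        try:
            loose, _ = core.filter_stations(table, min_years=min_years - 1)
        except core.EmptyResultError:
            loose = None
        try:
            strict, _ = core.filter_stations(table, min_years=min_years)
        except core.EmptyResultError:
            return
        assert set(strict.stations()) <= set(loose.stations())

    def test_mean_salinity_over_sampled_months(self):
        records = self._station("S1", range(2000, 2012), 12)
        envs = [
            env("S1", f"{y}-{m + 1:02d}-10", salinity=float(m))
            for y in range(2000, 2012)
            for m in range(12)
        ]
        table = core.aggregate_monthly(records, envs)
        _, profiles = core.filter_stations(table)
        assert profiles[0].mean_salinity == pytest.approx(5.5)


class TestTransform:
    @pytest.mark.parametrize(
        "value,kind,expected",
        [
            (100.0, "log10", 2.0),
            (0.0, "ln1p", 0.0),
            (9.0, "sqrt", 3.0),
            (math.e, "ln", 1.0),
        ],
    )
    def test_named_transforms(self, value, kind, expected):
        assert core.transform(value, kind) == pytest.approx(expected)

    def test_ln_of_zero_with_floor(self):
        assert core.transform(0.0, "ln", floor=0.01) == pytest.approx(
            math.log(0.01), abs=1e-4
        )

    def test_ln_of_zero_without_floor_raises(self):
        with pytest.raises(core.DomainError):
            core.transform(0.0, "ln")

    def test_sqrt_of_negative_raises(self):
        with pytest.raises(core.DomainError):
            core.transform(-1.0, "sqrt")

    def test_unknown_kind_raises(self):
        with pytest.raises(core.ConfigError):
            core.transform(1.0, "logit")
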