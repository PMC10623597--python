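"""Country-table reading, year aggregation, and sampling-plan apportionment."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from twinworld import (
    CountryRecord,
    CountryTable,
    aggregate_years,
    build_sampling_plan,
    read_country_table,
    write_country_table,
)


def write_csv(path, rows):
    lines = ["country,year,mean,sd,population"]
    lines += [",".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadCountryTable:
    def test_multi_year_country_is_averaged(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, [("Aland", y, m, 2.0, 1000) for y, m in
                      [(2015, 5.0), (2016, 5.2), (2017, 5.4)]])
        table = read_country_table(p)
        assert len(table) == 1
        rec = table.records[0]
        assert rec.mean == pytest.approx(5.2)
        assert rec.sd == pytest.approx(2.0)
        assert set(rec.yearly) == {2015, 2016, 2017}

    def test_negative_sd_raises(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, [("Aland", 2015, 5.0, -1.0, 1000)])
        with pytest.raises(ValueError, match="sd"):
            read_country_table(p)

    def test_mean_outside_ladder_raises(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, [("Aland", 2015, 11.0, 2.0, 1000)])
        with pytest.raises(ValueError, match="ladder"):
            read_country_table(p)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("country,year,mean\nAland,2015,5.0\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_country_table(p)

    def test_157_countries_survive(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, [(f"C{i:03d}", 2015, 5.0, 2.0, 1000) for i in range(157)])
        assert len(read_country_table(p)) == 157

    def test_country_with_only_missing_years_dropped(self, tmp_path, caplog):
        p = tmp_path / "t.csv"
        p.write_text(
            "country,year,mean,sd,population\n"
            "Aland,2015,5.0,2.0,1000\n"
            "Borduria,2015,,,2000\n"
        )
        with caplog.at_level("WARNING"):
            table = read_country_table(p)
        assert table.names() == ["Aland"]
        assert "Borduria" in caplog.text

    def test_year_filter(self, tmp_path):
        p = tmp_path / "t.csv"
        write_csv(p, [("Aland", 2015, 4.0, 1.0, 1000), ("Aland", 2019, 6.0, 3.0, 1000)])
        table = read_country_table(p, years=[2015])
        assert table.records[0].mean == pytest.approx(4.0)
        assert table.years == {2015}

    def test_round_trip_identity(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_csv(p1, [("Aland", 2015, 4.0, 1.0, 1000), ("Aland", 2019, 6.0, 3.0, 1000),
                       ("Borduria", 2016, 2.4, 1.7, 5000)])
        t1 = read_country_table(p1)
        write_country_table(t1, p2)
        t2 = read_country_table(p2)
        assert t1 == t2


class TestAggregateYears:
    @pytest.mark.parametrize(
        "yearly, expected",
        [
            ({2015: (5.0, 2.0)}, (5.0, 2.0)),
            ({2015: (4.0, 1.0), 2019: (6.0, 3.0)}, (5.0, 2.0)),
            ({2015: (2.4, 1.7), 2016: (2.4, 1.7), 2017: (2.4, 1.7)}, (2.4, 1.7)),
        ],
    )
    def test_examples(self, yearly, expected):
        mean, sd = aggregate_years(yearly)
        assert mean == pytest.approx(expected[0])
        assert sd == pytest.approx(expected[1])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_years({})

    @given(st.lists(
        st.tuples(st.floats(0, 10), st.floats(0.1, 5)), min_size=1, max_size=8))
    def test_permutation_invariant(self, pairs):
        forward = {2000 + i: p for i, p in enumerate(pairs)}
        backward = {2000 + i: p for i, p in enumerate(reversed(pairs))}
        assert aggregate_years(forward) == pytest.approx(aggregate_years(backward))


def make_table(pops):
    recs = tuple(
        CountryRecord(name=f"C{i}", mean=5.0, sd=2.0, population=float(p))
        for i, p in enumerate(pops)
    )
    return CountryTable(recs)


class TestSamplingPlan:
    def test_equal_mode_157_countries(self):
        table = make_table([1000] * 157)
        plan = build_sampling_plan(table, "equal", 1000)
        assert all(c == (1000, 1000) for c in plan.counts.values())
        assert plan.total_pairs == 314_000

    def test_population_weighted_exact_proportions(self):
        table = make_table([3_000_000, 1_000_000])
        plan = build_sampling_plan(table, "population_weighted", 400)
        assert plan.counts["C0"] == (300, 300)
        assert plan.counts["C1"] == (100, 100)

    def test_largest_remainder_tie_break(self):
        # equal populations and quotas 33.33: the leftover pair goes to the
        # first country in name order
        table = make_table([1, 1, 1])
        plan = build_sampling_plan(table, "population_weighted", 100)
        mz = [plan.counts[f"C{i}"][0] for i in range(3)]
        assert mz == [34, 33, 33]
        assert plan.total_mz == 100

    def test_minimum_one_pair_per_country(self):
        table = make_table([10_000_000, 1])
        plan = build_sampling_plan(table, "population_weighted", 10)
        assert plan.counts["C1"][0] >= 1
        assert plan.total_mz == 10

    def test_too_small_total_raises(self):
        table = make_table([1, 1, 1])
        with pytest.raises(ValueError, match="pairs_per_zygosity"):
            build_sampling_plan(table, "population_weighted", 2)

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            build_sampling_plan(make_table([1]), "fancy", 10)

    @given(
        pops=st.lists(st.integers(1, 10**9), min_size=1, max_size=40),
        extra=st.integers(0, 5000),
    )
    def test_totals_conserved_for_any_population_vector(self, pops, extra):
        table = make_table(pops)
        total = len(pops) + extra
        plan = build_sampling_plan(table, "population_weighted", total)
        assert plan.total_mz == total
        assert plan.total_dz == total
        assert all(n >= 1 for pair in plan.counts.values() for n in pair)


class TestRecordValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mean=11.0, sd=1.0, population=1),
            dict(mean=5.0, sd=0.0, population=1),
            dict(mean=5.0, sd=1.0, population=0),
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CountryRecord(name="X", **kwargs)

    def test_yearly_must_match_aggregate(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CountryRecord(name="X", mean=5.0, sd=1.0, population=1,
                          yearly={2015: (4.0, 1.0)})

    def test_duplicate_names_rejected(self):
        r = CountryRecord(name="X", mean=5.0, sd=1.0, population=1)
        with pytest.raises(ValueError, match="unique"):
            CountryTable((r, r))
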