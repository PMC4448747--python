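"""Growth tables and cumulative promiscuity statistics, with brute-force oracles."""

import pytest
from hypothesis import given, settings, strategies as st

from promtime import (
    ActivityRecord,
    Dataset,
    GrowthTable,
    annual_mean_promiscuity,
    annual_summary,
    cohort_subset,
    constant_promiscuity_fixture,
    current_mean_promiscuity,
    delta_histogram,
    fold_increase,
    growth_table,
    promiscuity_series,
)
from promtime.timecourse import DELTA_BINS, delta_bin_label
from conftest import random_dataset
from _brute import (
    brute_annual_mean,
    brute_delta_histogram,
    brute_growth,
    brute_promiscuity,
)


def rec(compound="C1", target="T1", assay="A1", year=2000):
    return ActivityRecord(compound_id=compound, target_id=target, assay_id=assay,
                          release_year=year)


def dataset_of(*records):
    return Dataset.from_records(records)


class TestGrowthTable:
    def test_single_record(self):
        table = growth_table(dataset_of(rec()), "compounds")
        assert table.frame.to_dict("list") == {"year": [2000], "n_new": [1],
                                               "n_cumulative": [1]}

    def test_compound_counted_only_in_earliest_year(self):
        table = growth_table(
            dataset_of(rec(year=1990), rec(target="T2", year=2000)), "compounds")
        assert table.new(1990) == 1
        assert table.new(2000) == 0
        assert table.cumulative(2000) == 1

    def test_gap_years_present_with_zero_new(self):
        table = growth_table(
            dataset_of(rec(year=1990), rec(compound="C2", year=1993)), "compounds")
        assert table.years == [1990, 1991, 1992, 1993]
        assert table.new(1991) == 0

    def test_activity_records_counted_per_release_year(self):
        table = growth_table(
            dataset_of(rec(), rec(target="T2", assay="A2"),
                       rec(compound="C2", year=2001)), "activities")
        assert table.new(2000) == 2
        assert table.cumulative(2001) == 3

    def test_empty_dataset_gives_empty_table(self):
        assert growth_table(Dataset.from_records([]), "targets").frame.empty

    def test_missing_year_raises(self):
        with pytest.raises(ValueError, match="release year"):
            growth_table(dataset_of(rec(year=None)), "compounds")

    def test_cumulation_of_printed_first_two_years(self):
        # two debut cohorts: 3188 new compounds, then 6496 new compounds
        table = GrowthTable.from_new_counts("compounds", {1976: 3188, 1977: 6496})
        assert table.cumulative(1977) == 9684


class TestFoldIncrease:
    def test_ratio_of_cumulative_counts(self):
        table = GrowthTable.from_new_counts("compounds", {2000: 4, 2010: 6})
        assert fold_increase(table, 2000, 2010) == pytest.approx(2.5)

    def test_identity_year(self):
        table = GrowthTable.from_new_counts("assays", {2000: 7})
        assert fold_increase(table, 2000, 2000) == 1.0

    def test_zero_denominator_raises(self):
        table = GrowthTable.from_new_counts("targets", {2000: 0, 2001: 5})
        with pytest.raises(ValueError, match="zero"):
            fold_increase(table, 2000, 2001)

    def test_absent_year_raises(self):
        table = GrowthTable.from_new_counts("targets", {2000: 1})
        with pytest.raises(KeyError):
            fold_increase(table, 1999, 2000)


class TestPromiscuitySeries:
    def test_worked_example_degrees(self, worked_example):
        (profile,) = promiscuity_series(worked_example, horizon=2014)
        assert profile.first_year == 1990
        assert profile.degree(1990) == 1
        assert profile.degree(1999) == 1
        assert profile.degree(2000) == 3
        assert profile.degree(2004) == 3
        assert profile.degree(2005) == 4
        assert profile.degree(2014) == 4
        assert profile.delta == 3

    def test_single_record_constant_degree(self):
        (profile,) = promiscuity_series(dataset_of(rec(year=1993)), horizon=2014)
        assert profile.delta == 0
        assert all(profile.degree(y) == 1 for y in range(1993, 2015))

    def test_remeasured_target_counts_once(self):
        dataset = dataset_of(rec(year=1990), rec(assay="A2", year=2005))
        (profile,) = promiscuity_series(dataset)
        assert profile.final_degree == 1
        assert profile.delta == 0

    def test_horizon_defaults_to_latest_year(self):
        profiles = promiscuity_series(dataset_of(rec(year=1990),
                                                 rec(compound="C2", year=2003)))
        assert all(p.horizon == 2003 for p in profiles)

    def test_records_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="beyond horizon"):
            promiscuity_series(dataset_of(rec(year=2010)), horizon=2005)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_degrees_never_decrease(self, seed):
        dataset = random_dataset(seed % 997, n_compounds=5)
        for profile in promiscuity_series(dataset):
            degrees = [profile.degree(y)
                       for y in range(profile.first_year, profile.horizon + 1)]
            assert degrees[0] >= 1
            assert all(a <= b for a, b in zip(degrees, degrees[1:]))


class TestAnnualMean:
    def test_mean_of_two_compounds(self):
        dataset = dataset_of(
            rec(compound="C1", target="T1", year=2000),
            rec(compound="C2", target="T1", year=2000),
            rec(compound="C2", target="T2", assay="A2", year=2000),
        )
        means = annual_mean_promiscuity(promiscuity_series(dataset))
        assert means[2000] == pytest.approx(1.5)

    def test_all_single_target_means_one_every_year(self):
        dataset = dataset_of(*(rec(compound=f"C{i}", year=1990 + i) for i in range(5)))
        means = annual_mean_promiscuity(promiscuity_series(dataset))
        assert set(means.values()) == {1.0}

    def test_three_compounds_mixed_degrees(self):
        # degrees at 2010: C1 -> 1, C2 -> 1, C3 -> 4; brute mean 2.0
        dataset = dataset_of(
            rec(compound="C1", year=2000),
            rec(compound="C2", target="T9", year=2005),
            *(rec(compound="C3", target=f"T{j}", assay=f"A{j}", year=2001 + j)
              for j in range(4)),
        )
        means = annual_mean_promiscuity(promiscuity_series(dataset, horizon=2010))
        assert means[2010] == pytest.approx(2.0)

    def test_compound_absent_before_debut(self):
        dataset = dataset_of(rec(compound="C1", year=1990),
                             rec(compound="C2", target="T2", assay="A2", year=2000))
        means = annual_mean_promiscuity(promiscuity_series(dataset))
        assert 1989 not in means
        assert means[1990] == 1.0

    def test_summary_frame_has_denominators(self):
        dataset = dataset_of(rec(compound="C1", year=1990),
                             rec(compound="C2", year=1995))
        summary = annual_summary(promiscuity_series(dataset))
        assert list(summary.columns) == ["year", "n_qualifying_compounds",
                                         "mean_promiscuity"]
        by_year = summary.set_index("year")["n_qualifying_compounds"]
        assert by_year[1990] == 1 and by_year[1995] == 2


class TestDeltaHistogram:
    @pytest.mark.parametrize("delta, label", [
        (0, "0"), (1, "1"), (5, "5"), (6, "6–10"), (7, "6–10"), (10, "6–10"),
        (11, "11–20"), (20, "11–20"), (21, "21–50"), (50, "21–50"),
        (51, ">50"), (400, ">50"),
    ])
    def test_bin_assignment(self, delta, label):
        assert delta_bin_label(delta) == label

    def test_counts_and_total(self):
        # compounds with deltas 0, 0, 1, 51
        records = [rec(compound="K1", year=2000), rec(compound="K2", year=2001),
                   rec(compound="K3", year=2000),
                   rec(compound="K3", target="TX", assay="AX", year=2001)]
        for j in range(52):
            records.append(rec(compound="K4", target=f"T{j}", assay=f"A{j}",
                               year=2000 if j == 0 else 2001))
        hist = delta_histogram(promiscuity_series(dataset_of(*records)))
        assert hist.total == 4
        assert hist.counts["0"] == 2
        assert hist.counts["1"] == 1
        assert hist.counts[">50"] == 1
        assert sum(hist.counts.values()) == hist.total

    def test_multi_target_debut_is_delta_zero(self):
        hist = delta_histogram(promiscuity_series(constant_promiscuity_fixture(5, 1976)))
        assert hist.counts["0"] == hist.total == 1

    def test_mixed_horizons_rejected(self):
        a = promiscuity_series(dataset_of(rec(year=2000)), horizon=2010)
        b = promiscuity_series(dataset_of(rec(compound="C2", year=2000)), horizon=2012)
        with pytest.raises(ValueError, match="horizon"):
            delta_histogram(a + b)

    def test_bin_labels_ordered(self):
        hist = delta_histogram([])
        assert list(hist.to_frame()["bin"]) == list(DELTA_BINS)


class TestCohorts:
    def test_cohort_keeps_all_records_of_debuting_compounds(self):
        dataset = dataset_of(rec(year=1994), rec(target="T2", assay="A2", year=2001))
        cohort = cohort_subset(dataset, 1994)
        assert len(cohort) == 2

    def test_earlier_debut_excluded_despite_matching_record(self):
        dataset = dataset_of(rec(year=1993), rec(target="T2", assay="A2", year=1994))
        assert len(cohort_subset(dataset, 1994)) == 0

    def test_empty_cohort(self):
        assert len(cohort_subset(dataset_of(rec(year=2000)), 1994)) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_cohorts_partition_the_compound_set(self, seed):
        dataset = random_dataset(seed)
        all_ids = set(dataset.compound_ids)
        seen = set()
        for year in dataset.years:
            ids = set(cohort_subset(dataset, year).compound_ids)
            assert ids.isdisjoint(seen)
            seen |= ids
        assert seen == all_ids

    def test_current_mean_at_horizon(self):
        # final degrees 1, 1, 1, 3 -> mean 1.5
        records = [rec(compound=f"C{i}", year=2000) for i in range(3)]
        records += [rec(compound="C3", target=f"T{j}", assay=f"A{j}", year=2000 + j)
                    for j in range(3)]
        assert current_mean_promiscuity(dataset_of(*records), 2014) == pytest.approx(1.5)

    def test_current_mean_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            current_mean_promiscuity(Dataset.from_records([]))


class TestBruteForceEquivalence:
    """The library statistics must match an independent naive recount."""

    @pytest.mark.parametrize("seed", range(20))
    def test_promiscuity_and_means_match_oracle(self, seed):
        dataset = random_dataset(seed)
        profiles = {p.compound_id: p for p in promiscuity_series(dataset)}
        expected = brute_promiscuity(dataset)
        assert profiles.keys() == expected.keys()
        for cid, (first, degrees) in expected.items():
            assert profiles[cid].first_year == first
            assert dict(profiles[cid].degree_by_year) == degrees
        assert annual_mean_promiscuity(profiles.values()) == \
            pytest.approx(brute_annual_mean(dataset))

    @pytest.mark.parametrize("seed", range(10))
    def test_histogram_and_growth_match_oracle(self, seed):
        dataset = random_dataset(seed + 100)
        hist = delta_histogram(promiscuity_series(dataset))
        brute = brute_delta_histogram(dataset)
        assert {b: c for b, c in hist.counts.items() if c} == brute
        for kind in ("compounds", "targets", "assays", "activities"):
            table = growth_table(dataset, kind)
            expected = brute_growth(dataset, kind)
            assert {y: n for y, n in zip(table.years, table.frame["n_new"]) if n} \
                == expected
            assert table.cumulative(max(table.years)) == sum(expected.values())
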