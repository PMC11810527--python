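"""Duplicate merging, replicate concordance, cohort summaries, binning."""

import pandas as pd
import pytest

from heaa import estimate_age
from heaa.clock import AgeEstimate
from heaa.cohort import (
    Individual,
    bin_ages,
    cohort_summary,
    frequency_table_summary,
    merge_duplicates,
    replicate_concordance,
)
from heaa.datasets import frequency_records, sheet_from_table


def _estimate(sample_id, age):
    return AgeEstimate(sample_id, 0, 0, 0, age, max(0.0, age - 4.47), age + 4.47, age)


def _sheet(rows):
    return pd.DataFrame(rows, columns=["sample_id", "individual_id", "sex"])


@pytest.fixture(scope="module")
def individuals(biopsy_table):
    estimates = [
        estimate_age(
            r["sample_id"], r["gria2_freq"], r["cdkn2a_freq"], r["tet2_freq"]
        )
        for _, r in biopsy_table.iterrows()
    ]
    return merge_duplicates(estimates, sheet_from_table(biopsy_table))


class TestMergeDuplicates:
    @pytest.mark.parametrize(
        "ind, expected",
        [("2", 8.38), ("7", 10.82), ("16", 14.78), ("21", 11.76)],
    )
    def test_duplicate_pair_consensus_ages(self, individuals, ind, expected):
        by_id = {i.individual_id: i for i in individuals}
        assert by_id[ind].consensus_age == expected
        assert len(by_id[ind].sample_ids) == 2

    def test_single_sample_individual_is_identity(self):
        ests = [_estimate("a", 10.21)]
        (ind,) = merge_duplicates(ests, _sheet([("a", "1", "male")]))
        assert ind.consensus_age == 10.21
        assert ind.sample_ids == ("a",)

    def test_consensus_lies_between_the_pair(self, individuals):
        for ind in individuals:
            if len(ind.sample_ages) == 2:
                lo, hi = sorted(ind.sample_ages)
                assert lo <= ind.consensus_age <= hi

    def test_conflicting_sex_is_an_integrity_error(self):
        ests = [_estimate("a", 5.0), _estimate("b", 6.0)]
        sheet = _sheet([("a", "1", "male"), ("b", "1", "female")])
        with pytest.raises(ValueError, match="sex"):
            merge_duplicates(ests, sheet)

    def test_unknown_sample_id_is_an_error(self):
        with pytest.raises(KeyError):
            merge_duplicates([_estimate("zz", 5.0)], _sheet([("a", "1", "male")]))

    def test_mother_calf_annotation_is_echoed(self, biopsy_table):
        estimates = [
            estimate_age(
                r["sample_id"], r["gria2_freq"], r["cdkn2a_freq"], r["tet2_freq"]
            )
            for _, r in biopsy_table.iterrows()
        ]
        inds = merge_duplicates(estimates, sheet_from_table(biopsy_table))
        by_id = {i.individual_id: i for i in inds}
        assert "mother" in by_id["14"].annotation
        assert by_id["14"].consensus_age == 30.40
        assert by_id["13"].consensus_age == 5.30


class TestReplicateConcordance:
    def test_published_pair_differences(self, individuals):
        dmin, dmax, diffs = replicate_concordance(individuals)
        assert (dmin, dmax) == (1.51, 3.66)
        assert diffs == {"2": 3.66, "7": 2.33, "16": 1.51, "21": 3.30}

    def test_every_pair_difference_within_the_ci_width(self, individuals):
        _, _, diffs = replicate_concordance(individuals)
        assert len(diffs) == 4
        assert all(d <= 8.94 for d in diffs.values())

    def test_identical_pair_has_zero_difference(self):
        ind = Individual("1", "male", ("a", "b"), (7.5, 7.5), 7.5)
        assert replicate_concordance([ind]) == (0.0, 0.0, {"1": 0.0})

    def test_no_duplicates_is_empty_not_an_error(self):
        ind = Individual("1", "male", ("a",), (7.5,), 7.5)
        assert replicate_concordance([ind]) == (None, None, {})


class TestCohortSummary:
    def test_published_overall_statistics(self, individuals):
        s = cohort_summary(individuals)
        assert s.n_individuals == 21
        assert (s.age_min, s.age_max, s.age_mean) == (2.95, 30.40, 12.02)

    def test_published_sex_stratified_statistics(self, individuals):
        s = cohort_summary(individuals)
        assert s.by_sex["male"]["n"] == 15
        assert s.by_sex["male"]["age_mean"] == 12.23
        assert s.by_sex["female"]["n"] == 6
        assert s.by_sex["female"]["age_mean"] == 11.48

    def test_single_individual_degenerate_case(self):
        ind = Individual("1", "male", ("a",), (10.0,), 10.0)
        s = cohort_summary([ind])
        assert s.age_min == s.age_max == s.age_mean == 10.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])


class TestBinAges:
    def test_published_age_structure(self, individuals):
        labels, counts, peak = bin_ages(individuals)
        assert counts == (2, 4, 11, 3, 0, 0, 1)
        assert peak == "10.00–14.99"
        assert labels[0] == "0.00–4.99"
        assert sum(counts) == len(individuals)

    def test_half_open_boundary(self):
        ind = Individual("1", "male", ("a",), (5.0,), 5.0)
        labels, counts, peak = bin_ages([ind])
        assert counts == (0, 1)
        assert peak == "5.00–9.99"

    def test_peak_tie_goes_to_youngest_bin(self):
        inds = [
            Individual("1", "male", ("a",), (1.0,), 1.0),
            Individual("2", "male", ("b",), (7.0,), 7.0),
        ]
        _, counts, peak = bin_ages(inds)
        assert counts == (1, 1)
        assert peak == "0.00–4.99"

    def test_counts_are_permutation_invariant(self, individuals):
        _, a, _ = bin_ages(individuals)
        _, b, _ = bin_ages(list(reversed(individuals)))
        assert a == b

    def test_bad_width_rejected(self, individuals):
        with pytest.raises(ValueError):
            bin_ages(individuals, width=0)


class TestFrequencyTableSummary:
    def test_published_per_gene_summaries(self, biopsy_table):
        summary = frequency_table_summary(frequency_records(biopsy_table))
        assert summary.loc["GRIA2", "freq_min":"freq_mean"].tolist() == [
            0.66, 2.66, 1.71
        ]
        assert summary.loc["CDKN2A", "freq_mean"] == 2.22
        assert summary.loc["TET2", "freq_min":"freq_mean"].tolist() == [
            5.59, 19.19, 11.37
        ]
        assert summary["coverage_mean"].tolist() == [20316, 27582, 29856]
        assert (summary["n"] == 25).all()

    def test_single_record_min_equals_max_equals_mean(self):
        df = pd.DataFrame(
            [{"sample_id": "a", "gene": "GRIA2", "frequency": 1.5, "coverage": 100}]
        )
        s = frequency_table_summary(df)
        assert s.loc["GRIA2", ["freq_min", "freq_max", "freq_mean"]].tolist() == [
            1.5, 1.5, 1.5
        ]

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            frequency_table_summary(pd.DataFrame({"gene": ["GRIA2"]}))
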