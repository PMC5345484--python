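import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmatqa.cohort import (
    CohortFormatError,
    CohortRecord,
    EmptySelectionError,
    cohort_summary,
    histogram,
    load_cohort,
    percentile_of,
    save_cohort,
    summary_rows,
)
from vmatqa.synth import CohortSpec, simulate_cohort


def rec(complexity, site="brain", fx="standard", qa=True, pid="p"):
    return CohortRecord(plan_id=pid, site=site, fractionation=fx,
                        complexity=complexity, qa_pass=qa)


class TestRecordValidation:
    def test_non_positive_complexity_rejected(self):
        with pytest.raises(ValueError, match="complexity"):
            rec(0.0)

    def test_bad_fractionation_rejected(self):
        with pytest.raises(ValueError, match="fractionation"):
            rec(0.1, fx="weekly")


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        records = [
            rec(0.132, "head and neck", "standard", True, "a"),
            rec(0.210, "brain", "SBRT", False, "b"),
            CohortRecord("c", "lung", "unknown", 0.1, None),
        ]
        path = str(tmp_path / "cohort.csv")
        save_cohort(records, path)
        assert load_cohort(path) == records

    def test_three_row_file(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "plan_id,site,fractionation,complexity_mm_inv,qa_pass\n"
            "a,brain,standard,0.1,true\n"
            "b,brain,SBRT,0.2,false\n"
            "c,lung,standard,0.15,\n"
        )
        records = load_cohort(str(path))
        assert len(records) == 3
        assert records[2].qa_pass is None

    def test_negative_complexity_names_line(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "plan_id,site,fractionation,complexity_mm_inv,qa_pass\n"
            "a,brain,standard,0.1,true\n"
            "b,brain,standard,-0.1,true\n"
        )
        with pytest.raises(CohortFormatError, match="line 3"):
            load_cohort(str(path))

    def test_non_numeric_complexity_names_line(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "plan_id,site,fractionation,complexity_mm_inv,qa_pass\n"
            "a,brain,standard,abc,true\n"
        )
        with pytest.raises(CohortFormatError, match="line 2"):
            load_cohort(str(path))

    def test_wrong_header_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("id,complexity\n1,0.2\n")
        with pytest.raises(CohortFormatError, match="header"):
            load_cohort(str(path))

    def test_bad_qa_value_rejected(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "plan_id,site,fractionation,complexity_mm_inv,qa_pass\n"
            "a,brain,standard,0.1,maybe\n"
        )
        with pytest.raises(CohortFormatError, match="qa_pass"):
            load_cohort(str(path))


class TestCohortSummary:
    def test_single_passing_record_below_threshold(self):
        s = cohort_summary([rec(0.1)], threshold=0.18)
        g = s.overall
        assert (g.n_total, g.n_fail, g.n_above, g.n_fail_above) == (1, 0, 0, 0)

    def test_failing_above_counts_strictly(self):
        records = [rec(0.15, qa=False, pid="a"), rec(0.19, qa=False, pid="b")]
        g = cohort_summary(records, threshold=0.18).overall
        assert g.n_fail == 2
        assert g.n_fail_above == 1

    def test_tie_at_threshold_not_above(self):
        g = cohort_summary([rec(0.18)], threshold=0.18).overall
        assert g.n_above == 0

    def test_single_failing_plan_mean_without_sd(self):
        records = [rec(0.159, qa=False), rec(0.129, qa=True, pid="q")]
        g = cohort_summary(records, threshold=0.18).overall
        assert g.mean_fail == pytest.approx(0.159)
        assert g.sd_fail is None

    def test_no_failing_plans_dash(self):
        g = cohort_summary([rec(0.1), rec(0.2, pid="q")], threshold=0.18).overall
        assert g.mean_fail is None and g.sd_fail is None

    def test_simulated_cohort_counts_match_enumeration(self):
        records = simulate_cohort(CohortSpec(n_pass=200, n_fail=40, seed=9))
        t = 0.18
        s = cohort_summary(records, threshold=t)
        g = s.overall
        assert g.n_total == 240
        assert g.n_fail == sum(1 for r in records if r.qa_pass is False)
        assert g.n_above == sum(1 for r in records if r.complexity > t)
        assert g.n_fail_above == sum(
            1 for r in records if r.qa_pass is False and r.complexity > t
        )
        fails = [r.complexity for r in records if r.qa_pass is False]
        assert g.mean_fail == pytest.approx(np.mean(fails))
        assert g.sd_fail == pytest.approx(np.std(fails, ddof=1))

    def test_groups_partition_total(self):
        records = [
            rec(0.1, "brain", "standard", pid="a"),
            rec(0.2, "brain", "SBRT", pid="b"),
            rec(0.15, "lung", "standard", pid="c"),
        ]
        s = cohort_summary(records, threshold=0.18)
        assert sum(g.n_total for g in s.groups) == s.overall.n_total

    def test_count_identities_fuzz(self):
        rng = np.random.default_rng(17)
        sites = ["brain", "lung", "liver"]
        for _ in range(30):
            records = [
                rec(float(rng.uniform(0.01, 0.4)), sites[rng.integers(3)],
                    "standard", bool(rng.random() < 0.8), pid=str(i))
                for i in range(int(rng.integers(1, 60)))
            ]
            t = float(rng.uniform(0.05, 0.3))
            s = cohort_summary(records, threshold=t)
            for g in [s.overall] + s.groups:
                n_pass_above = sum(
                    1 for r in records
                    if (g.site == "all" or (r.site == g.site))
                    and r.qa_pass is True and r.complexity > t
                )
                assert g.n_fail_above <= min(g.n_fail, g.n_above)
                assert g.n_above == g.n_fail_above + n_pass_above

    def test_summary_rows_mirror_groups(self):
        records = [rec(0.1), rec(0.2, "lung", pid="q")]
        rows = summary_rows(cohort_summary(records, 0.18))
        assert rows[0]["site"] == "all"
        assert {r["site"] for r in rows[1:]} == {"brain", "lung"}


class TestHistogram:
    def test_example_bins(self):
        records = [rec(0.005), rec(0.015, pid="b"), rec(0.015, pid="c")]
        edges, counts = histogram(records, bin_width=0.01)
        assert counts.tolist() == [1, 2]
        assert edges[0] == 0.0
        assert edges[-1] == pytest.approx(0.02)

    def test_site_filter(self):
        records = [rec(0.1, "brain"), rec(0.1, "lung", pid="q")]
        _, counts = histogram(records, site_filter="brain")
        assert counts.sum() == 1

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(2)
        records = [rec(float(c), pid=str(i))
                   for i, c in enumerate(rng.uniform(0.01, 0.5, 137))]
        _, counts = histogram(records, bin_width=0.013)
        assert counts.sum() == 137

    def test_empty_after_filter_raises(self):
        with pytest.raises(EmptySelectionError):
            histogram([rec(0.1)], site_filter="pelvis")

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            histogram([rec(0.1)], bin_width=0.0)


class TestPercentile:
    def test_above_everything_is_100(self):
        records = [rec(0.1, pid=str(i)) for i in range(7)]
        assert percentile_of(0.5, records) == 100.0

    def test_midrank_single_equal_record(self):
        assert percentile_of(0.1, [rec(0.1)]) == 50.0

    def test_median_of_101_distinct(self):
        records = [rec(0.01 * (i + 1), pid=str(i)) for i in range(101)]
        assert percentile_of(0.01 * 51, records) == pytest.approx(50.0)

    def test_empty_after_filter_raises(self):
        with pytest.raises(EmptySelectionError):
            percentile_of(0.1, [rec(0.1)], site_filter="lung")

    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=0.01, max_value=0.5, allow_nan=False),
            min_size=1, max_size=30,
        ),
        m1=st.floats(min_value=0.0, max_value=0.6),
        m2=st.floats(min_value=0.0, max_value=0.6),
    )
    def test_percentile_monotone_in_m(self, values, m1, m2):
        records = [rec(v, pid=str(i)) for i, v in enumerate(values)]
        lo, hi = sorted([m1, m2])
        assert percentile_of(lo, records) <= percentile_of(hi, records)
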