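import numpy as np
import pandas as pd
import pytest

from faerspv import io, onset

from conftest import demo_row, make_quarter


def run_onset(demo_rows, drug_rows, ther_rows):
    q = make_quarter(demo_rows, drug_rows=drug_rows, ther_rows=ther_rows)
    dedup = io.deduplicate([q])
    cases = io.clean_demographics(dedup)
    cohort, mentions = io.select_drug_cohort(cases, dedup.drug, ["adbry"])
    return onset.compute_onsets(cohort, dedup.ther, mentions)


class TestComputeOnsets:
    DRUG = [["1", "1", "PS", "ADBRY", ""]]

    def test_calendar_day_interval(self):
        rec, tally = run_onset([demo_row("1", "1", event="20210214")], self.DRUG,
                               [["1", "1", "20210101", ""]])
        assert list(rec["days"]) == [44]
        assert sum(tally.values()) == 0

    def test_event_before_start_excluded(self):
        rec, tally = run_onset([demo_row("1", "1", event="20201231")], self.DRUG,
                               [["1", "1", "20210101", ""]])
        assert len(rec) == 0 and tally["event_before_start"] == 1

    def test_partial_start_date_excluded(self):
        rec, tally = run_onset([demo_row("1", "1", event="20210214")], self.DRUG,
                               [["1", "1", "202101", ""]])
        assert len(rec) == 0 and tally["partial_date"] == 1

    def test_missing_ther_row_excluded(self):
        rec, tally = run_onset([demo_row("1", "1", event="20210214")], self.DRUG, [])
        assert len(rec) == 0 and tally["missing_start"] == 1

    def test_missing_event_excluded(self):
        rec, tally = run_onset([demo_row("1", "1", event="")], self.DRUG,
                               [["1", "1", "20210101", ""]])
        assert tally["missing_event"] == 1

    def test_earliest_full_start_wins(self):
        rec, _ = run_onset([demo_row("1", "1", event="20210301")], self.DRUG,
                           [["1", "1", "20210201", ""], ["1", "1", "20210101", ""]])
        assert list(rec["days"]) == [59]

    def test_same_day_retained_as_zero(self):
        rec, _ = run_onset([demo_row("1", "1", event="20210101")], self.DRUG,
                           [["1", "1", "20210101", ""]])
        assert list(rec["days"]) == [0]

    def test_tally_plus_retained_equals_input(self):
        demos = [demo_row(str(i), str(i), event=e) for i, e in
                 enumerate(["20210214", "20201231", "", "20210301"])]
        drugs = [[str(i), "1", "PS", "ADBRY", ""] for i in range(4)]
        thers = [["0", "1", "20210101", ""], ["1", "1", "20210101", ""],
                 ["2", "1", "20210101", ""]]
        rec, tally = run_onset(demos, drugs, thers)
        assert len(rec) + sum(tally.values()) == 4


class TestSummarize:
    def test_median_of_three(self):
        s = onset.summarize_onsets(pd.DataFrame({"days": [5, 37, 200]}))
        assert s.median_days == 37

    def test_manual_binning(self):
        s = onset.summarize_onsets(pd.DataFrame({"days": [10, 20, 40, 70, 100, 200]}))
        assert s.bin_props == pytest.approx(
            {"0-30": 2 / 6, "31-60": 1 / 6, "61-90": 1 / 6, "91-180": 1 / 6,
             ">180": 1 / 6})

    def test_degenerate_all_equal(self):
        s = onset.summarize_onsets(pd.DataFrame({"days": [15] * 9}))
        assert (s.median_days, s.q1_days, s.q3_days) == (15, 15, 15)
        assert s.bin_props["0-30"] == 1.0

    def test_bin_boundaries_inclusive(self):
        s = onset.summarize_onsets(pd.DataFrame({"days": [0, 30, 31, 180, 181]}))
        assert s.bin_props["0-30"] == pytest.approx(2 / 5)
        assert s.bin_props["91-180"] == pytest.approx(1 / 5)
        assert s.bin_props[">180"] == pytest.approx(1 / 5)

    def test_quartile_order_and_bin_sum(self, rng):
        days = rng.integers(0, 400, size=101)
        s = onset.summarize_onsets(pd.DataFrame({"days": days}))
        assert s.q1_days <= s.median_days <= s.q3_days
        assert sum(s.bin_props.values()) == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        days = list(rng.integers(0, 300, size=60))
        s1 = onset.summarize_onsets(pd.DataFrame({"days": days}))
        s2 = onset.summarize_onsets(pd.DataFrame({"days": days[::-1]}))
        assert (s1.median_days, s1.q1_days, s1.q3_days) == \
               (s2.median_days, s2.q1_days, s2.q3_days)
        assert s1.bin_props == s2.bin_props

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            onset.summarize_onsets(pd.DataFrame({"days": []}))

    def test_lognormal_median_recovery(self):
        # onsets drawn from the stated distribution: empirical median near exp(mu)
        rng = np.random.default_rng(5)
        days = np.round(rng.lognormal(np.log(37.0), 1.0, size=10_000))
        s = onset.summarize_onsets(pd.DataFrame({"days": days}))
        assert abs(s.median_days - 37.0) / 37.0 < 0.05
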