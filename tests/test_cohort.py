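"""Paired cohort statistics, percent conventions, fixtures and loaders."""

import random

import numpy as np
import pandas as pd
import pytest

from glcmskin import PatientRecord, load_measurements, paired_tests, percent_change
from glcmskin.cohort import (
    channel_summary_from_table,
    load_packaged_channel_table,
    load_packaged_records,
    packaged_fixture_path,
    round_half_up,
    summarize_channels,
    summarize_cohort,
)


def _record(pid, metric, before, after, channel="gray"):
    return PatientRecord(pid, {(metric, channel): (before, after)})


class TestPercentChange:
    def test_largest_brightness_increase(self):
        # 139.25 -> 174.32: a 35.07 rise on the post value, about 20%
        assert percent_change(139.25, 174.32) == pytest.approx(35.07 / 174.32)

    def test_largest_contrast_decrease(self):
        # 8.88 -> 7.68: a 1.20 drop on the pre value, about 13.5%
        assert percent_change(8.88, 7.68) == pytest.approx(1.20 / 8.88)

    def test_no_change_and_symmetry(self):
        assert percent_change(5.0, 5.0) == 0.0
        assert percent_change(3.0, 4.0) == percent_change(4.0, 3.0)

    def test_explicit_conventions(self):
        assert percent_change(10.0, 12.0, "before") == pytest.approx(0.2)
        assert percent_change(10.0, 12.0, "after") == pytest.approx(2 / 12)
        with pytest.raises(ValueError, match="convention"):
            percent_change(1.0, 2.0, "bogus")

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            percent_change(0.0, 0.0)


class TestSummarizeCohort:
    def test_brightness_fixture_means(self):
        records = load_packaged_records()
        s = summarize_cohort(records, "brightness")
        assert s.n == 12
        assert round_half_up(s.mean_before, 1) == 156.1
        assert round_half_up(s.mean_after, 1) == 174.6
        assert round_half_up(s.mean_absolute_change, 1) == 18.5

    def test_homogeneity_fixture_extremes(self):
        records = load_packaged_records()
        s = summarize_cohort(records, "homogeneity")
        assert s.largest.patient_id == 8
        assert s.smallest.patient_id == 1
        assert s.largest.absolute_change == pytest.approx(0.29)

    def test_single_patient_degenerate(self):
        s = summarize_cohort([_record(1, "brightness", 1.0, 2.0)], "brightness")
        assert (s.mean_before, s.mean_after) == (1.0, 2.0)
        assert s.sd_before is None and s.sd_after is None
        assert s.mean_absolute_change == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            summarize_cohort([], "brightness")

    def test_order_invariance(self):
        records = load_packaged_records()
        ref = summarize_cohort(records, "contrast")
        rng = random.Random(3)
        for _ in range(5):
            shuffled = records[:]
            rng.shuffle(shuffled)
            s = summarize_cohort(shuffled, "contrast")
            assert s.mean_absolute_change == pytest.approx(ref.mean_absolute_change)
            assert s.largest == ref.largest and s.smallest == ref.smallest

    def test_extreme_ties_break_to_lower_patient_id(self):
        records = [_record(2, "contrast", 5.0, 4.0), _record(1, "contrast", 6.0, 5.0)]
        s = summarize_cohort(records, "contrast")
        assert s.largest.patient_id == 1 and s.smallest.patient_id == 1


class TestChannels:
    def test_table_fixture_blue_argmax(self):
        chan = channel_summary_from_table(load_packaged_channel_table())
        assert chan.largest_contrast_channel == "B" and not chan.tie
        assert chan.channels["B"].contrast_decrease == pytest.approx(2.82)
        assert chan.channels["G"].homogeneity_increase == pytest.approx(0.0)

    def test_per_patient_records_aggregate(self):
        records = []
        for pid in (1, 2):
            rec = PatientRecord(pid)
            for ch, drop in (("R", 1.0), ("G", 2.0), ("B", 3.0)):
                rec.values[("contrast", ch)] = (10.0 + pid, 10.0 + pid - drop)
                rec.values[("homogeneity", ch)] = (0.5, 0.6)
            records.append(rec)
        chan = summarize_channels(records)
        assert chan.largest_contrast_channel == "B"
        assert chan.channels["R"].contrast_before == pytest.approx(11.5)
        assert chan.missing_channels == ()

    def test_missing_channel_flagged(self):
        rec = PatientRecord(1, {("contrast", "R"): (2.0, 1.0),
                                ("homogeneity", "R"): (0.5, 0.6)})
        chan = summarize_channels([rec])
        assert set(chan.missing_channels) == {"G", "B"}

    def test_identical_before_after_is_a_tie(self):
        records = []
        rec = PatientRecord(1)
        for ch in ("R", "G", "B"):
            rec.values[("contrast", ch)] = (5.0, 5.0)
            rec.values[("homogeneity", ch)] = (0.5, 0.5)
        records.append(rec)
        chan = summarize_channels(records)
        assert chan.tie and chan.largest_contrast_channel is None


class TestPairedTests:
    def test_contrast_fixture_rejects_at_05(self):
        records = load_packaged_records()
        rep = paired_tests(records, "contrast")
        assert not rep.degenerate
        assert rep.t_pvalue < 0.001
        # all 12 differences negative: exact signed-rank mass 2 * (1/2)^12
        assert rep.wilcoxon_pvalue < 0.001

    def test_constant_differences_flagged(self):
        records = [_record(i, "brightness", 10.0, 11.0) for i in range(1, 13)]
        rep = paired_tests(records, "brightness")
        assert rep.degenerate and rep.t_statistic is None

    def test_antisymmetric_differences_give_zero_t(self):
        records = [_record(1, "contrast", 5.0, 6.0), _record(2, "contrast", 5.0, 4.0),
                   _record(3, "contrast", 7.0, 8.0), _record(4, "contrast", 7.0, 6.0)]
        rep = paired_tests(records, "contrast")
        assert rep.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_minimum_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            paired_tests([_record(1, "contrast", 1.0, 2.0)], "contrast")


class TestLoadMeasurements:
    def test_packaged_table_has_twelve_records(self):
        records = load_measurements(packaged_fixture_path("table1_brightness.csv"))
        assert len(records) == 12
        assert records[0].get("brightness") == (165.25, 196.35)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            load_measurements(p)

    def test_duplicate_row_names_line(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "patient_id,metric,channel,before,after\n"
            "1,brightness,gray,100,110\n"
            "1,brightness,gray,100,120\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            load_measurements(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "patient_id,metric,channel,before,after\n"
            "1,brightness,gray,100,110\n"
            "2,brightness,gray,oops,120\n"
        )
        with pytest.raises(ValueError, match="line 3"):
            load_measurements(p)

    def test_wrong_schema_rejected(self, tmp_path):
        p = tmp_path / "schema.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="expected columns"):
            load_measurements(p)


def test_round_half_up_ties():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(18.4975, 1) == 18.5
    assert round_half_up(-0.125, 2) == -0.13
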