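"""Summaries, fold/percent arithmetic, t/ANOVA/Tukey, time courses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import fociscope as fs
from fociscope.gating import CellRecord
from fociscope.stats import (SummaryRow, anova_tukey, compare_two_groups,
                             fold_change, format_fold, percent_increase,
                             repair_time_course, summarize_foci,
                             TimeCourseGapError)

from .oracles import hand_anova_f, pooled_t, two_pass_mean_sem


def make_records(counts, phase="G1", line="hDF", marker="gH2AX",
                 dose=0.0, time=0.0):
    cond = fs.ConditionParams(line_id=line, marker=marker, dose_gy=dose,
                              time_h=time)
    return [CellRecord(nucleus_id=i, foci_count=int(c), phase=phase,
                       condition=cond) for i, c in enumerate(counts)]


class TestSummarize:
    def test_mean_sem_n_hand_computed(self):
        rows = summarize_foci(make_records([1, 2, 3]))
        assert len(rows) == 1
        r = rows[0]
        assert r.mean_foci == pytest.approx(2.0)
        assert r.sem == pytest.approx(0.5774, abs=1e-4)
        assert r.n_cells == 3

    def test_single_cell_sem_zero(self):
        with pytest.warns(UserWarning):
            rows = summarize_foci(make_records([7]))
        assert rows[0].mean_foci == 7.0
        assert rows[0].sem == 0.0

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=60))
    def test_agrees_with_two_pass_oracle(self, counts):
        rows = summarize_foci(make_records(counts))
        mean, sem = two_pass_mean_sem(counts)
        assert rows[0].mean_foci == pytest.approx(mean, rel=1e-9)
        assert rows[0].sem == pytest.approx(sem, rel=1e-9, abs=1e-12)

    def test_groups_split_by_phase(self):
        records = make_records([1, 2, 3], phase="G1") + \
            make_records([10, 20], phase="SG2")
        rows = summarize_foci(records)
        by_phase = {r.phase: r for r in rows}
        assert by_phase["G1"].n_cells == 3
        assert by_phase["SG2"].mean_foci == 15.0


class TestFoldArithmetic:
    def test_identity(self):
        assert fold_change(3.7, 3.7) == 1.0

    def test_reference_ratios(self, reference_table):
        irr = fs.reference_mean(reference_table, "hDF", "na", "gH2AX", "1Gy", "G1")
        ctrl = fs.reference_mean(reference_table, "hDF", "na", "gH2AX", "control", "G1")
        ratio = fold_change(irr, ctrl)
        assert ratio == pytest.approx(17.60, abs=0.01)
        assert format_fold(ratio) == 18
        hi = fs.reference_mean(reference_table, "CBIA-5", "high", "gH2AX", "1Gy", "SG2")
        lo = fs.reference_mean(reference_table, "CBIA-5", "high", "gH2AX", "1Gy", "G1")
        assert format_fold(fold_change(hi, lo)) == pytest.approx(2.1)

    def test_denominator_validation(self):
        with pytest.raises(fs.ValidationError):
            fold_change(1.0, 0.0)

    def test_percent_increase_cases(self):
        assert percent_increase(5, 5) == 0.0
        assert percent_increase(1.13, 19.89) == pytest.approx(1660.2, abs=0.05)
        assert percent_increase(2, 1) == -50.0
        with pytest.raises(fs.ValidationError):
            percent_increase(0.0, 1.0)

    @given(st.floats(0.1, 100), st.floats(0.0, 100))
    def test_fold_percent_consistency(self, den, num):
        assert fold_change(num, den) == pytest.approx(
            1.0 + percent_increase(den, num) / 100.0, rel=1e-12, abs=1e-12)


class TestTwoGroups:
    def test_identical_groups(self):
        res = compare_two_groups([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_matches_pooled_oracle(self):
        a, b = [1, 2, 3, 4], [11, 12, 13, 14]
        res = compare_two_groups(a, b)
        t, p = pooled_t(a, b)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(fs.ValidationError):
            compare_two_groups([1], [1, 2])

    def test_type_one_error_near_alpha(self):
        # Poisson(5) null, n=200 per group, 1000 replicates
        rng = np.random.default_rng(12345)
        a = rng.poisson(5.0, (1000, 200))
        b = rng.poisson(5.0, (1000, 200))
        _, p = sps.ttest_ind(a, b, axis=1)
        rate = np.mean(p < 0.05)
        # cross-check a handful against our implementation
        for k in range(5):
            assert compare_two_groups(a[k], b[k]).p_value == pytest.approx(p[k])
        assert 0.03 <= rate <= 0.07


class TestAnovaTukey:
    def test_equal_groups_f_zero(self):
        res = anova_tukey({"a": [2, 2, 2], "b": [2, 2, 2], "c": [2, 2, 2]})
        assert res.statistic == 0.0
        assert not any(sig for *_x, sig in res.pairwise)

    def test_matches_hand_anova(self):
        groups = {"g1": [6, 8, 4, 5, 3, 4], "g2": [8, 12, 9, 11, 6, 8],
                  "g3": [13, 9, 11, 8, 7, 12]}
        res = anova_tukey(groups)
        f = hand_anova_f(list(groups.values()))
        assert res.statistic == pytest.approx(f, rel=1e-9)
        f_scipy, p_scipy = sps.f_oneway(*groups.values())
        assert res.p_value == pytest.approx(p_scipy)

    def test_two_groups_redirected(self):
        with pytest.raises(fs.ValidationError):
            anova_tukey({"a": [1, 2], "b": [3, 4]})

    def test_discrimination_pattern(self):
        # one low-rate group vs two equal high-rate groups: only pairs with
        # the low group significant
        rng = np.random.default_rng(7)
        groups = {"somatic": rng.poisson(1.1, 400),
                  "stem_a": rng.poisson(5.7, 400),
                  "stem_b": rng.poisson(5.7, 400)}
        res = anova_tukey(groups)
        for a, b, _p, sig in res.pairwise:
            involves_low = "somatic" in (a, b)
            assert sig == involves_low

    @given(st.integers(0, 5000))
    def test_tukey_p_not_below_pairwise_t(self, seed):
        # baseline: unadjusted pairwise t using the shared pooled MSE, the
        # quantity Tukey's studentized-range correction inflates
        rng = np.random.default_rng(seed)
        groups = {k: rng.normal(loc, 1.0, 8)
                  for k, loc in zip("abc", rng.uniform(0, 2, 3))}
        res = anova_tukey(groups)
        n_total = sum(len(v) for v in groups.values())
        mse = sum(((np.asarray(v) - np.mean(v)) ** 2).sum()
                  for v in groups.values()) / (n_total - len(groups))
        for a, b, adj_p, _sig in res.pairwise:
            se = np.sqrt(mse * (1 / len(groups[a]) + 1 / len(groups[b])))
            t = abs(np.mean(groups[a]) - np.mean(groups[b])) / se
            p_raw = 2 * sps.t.sf(t, n_total - len(groups))
            assert adj_p >= p_raw - 1e-9


class TestTimeCourse:
    def row(self, time, mean, line="hDF", marker="gH2AX", phase="G1"):
        return SummaryRow(line_id=line, marker=marker, dose_gy=1.0,
                          time_h=time, phase=phase, mean_foci=mean,
                          sem=0.1, n_cells=100)

    def test_flat_series(self):
        rows = [self.row(t, 20.0) for t in (0.0, 0.5, 2.0, 6.0)]
        tc = repair_time_course(rows)[0]
        assert tc.percent_remaining_2h == 100.0
        assert tc.percent_remaining_6h == 100.0

    def test_decline_arithmetic(self):
        rows = [self.row(0.0, 1.0), self.row(0.5, 20.0),
                self.row(2.0, 10.0), self.row(6.0, 5.0)]
        tc = repair_time_course(rows)[0]
        assert tc.percent_remaining_2h == 50.0
        assert tc.percent_remaining_6h == 25.0

    def test_missing_time_point_raises(self):
        rows = [self.row(0.0, 1.0), self.row(0.5, 20.0), self.row(2.0, 10.0)]
        with pytest.raises(TimeCourseGapError):
            repair_time_course(rows)

    def test_fast_repair_lower_residual(self):
        fast = [self.row(0.0, 1.0, line="fast"), self.row(0.5, 20.0, line="fast"),
                self.row(2.0, 8.0, line="fast"), self.row(6.0, 3.0, line="fast")]
        slow = [self.row(0.0, 1.0, line="slow"), self.row(0.5, 12.0, line="slow"),
                self.row(2.0, 10.0, line="slow"), self.row(6.0, 9.0, line="slow")]
        tc = {r.line_id: r for r in repair_time_course(fast + slow)}
        assert tc["fast"].percent_remaining_6h < tc["slow"].percent_remaining_6h
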