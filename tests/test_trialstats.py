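"""Trial-design statistics: sample size, CIs, tests, randomization, FMA model."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import rehabkit as rk
from rehabkit.trialstats import (
    FmaAssessment,
    GroupSummary,
    SampleSizeParams,
    incidence,
)

DESIGN = SampleSizeParams()  # the trial's published design values


class TestSampleSize:
    def test_published_design_gives_47_per_group(self):
        assert rk.noninferiority_sample_size(DESIGN) == 47

    def test_twenty_percent_dropout_inflates_to_59(self):
        assert rk.inflate_for_dropout(47, 0.20) == 59

    def test_no_dropout_is_identity(self):
        assert rk.inflate_for_dropout(47, 0.0) == 47

    def test_half_dropout_doubles(self):
        assert rk.inflate_for_dropout(10, 0.5) == 20

    def test_dropout_rate_of_one_rejected(self):
        with pytest.raises(ValueError):
            rk.inflate_for_dropout(47, 1.0)

    def test_quadratic_scaling_in_the_denominator(self):
        # doubling |mu1 - mu2| + delta divides the pre-ceiling n by 4
        p = SampleSizeParams(mu1=12.0, mu2=10.0, sigma=5.5, margin_fraction=0.4)
        raw = (p.z_alpha_half + p.z_beta) ** 2 * 2 * p.sigma**2 / (2.0 + p.margin) ** 2
        mu_diff2 = 2 * (abs(p.mu1 - p.mu2) + p.margin) - p.margin
        p2 = SampleSizeParams(mu1=p.mu2 + mu_diff2, mu2=p.mu2, sigma=p.sigma,
                              margin_fraction=p.margin_fraction)
        assert rk.noninferiority_sample_size(p2) == math.ceil(raw / 4)

    def test_sigma_doubling_with_fixed_absolute_margin_quadruples(self):
        p1 = SampleSizeParams(mu1=11.0, mu2=11.0, sigma=5.5, margin_fraction=0.4)
        # same absolute margin (2.2) at doubled sigma -> halved margin_fraction
        p2 = SampleSizeParams(mu1=11.0, mu2=11.0, sigma=11.0, margin_fraction=0.2)
        raw1 = (1.96 + 0.84) ** 2 * 2 * p1.sigma**2 / p1.margin**2
        assert rk.noninferiority_sample_size(p2) == math.ceil(4 * raw1)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rk.noninferiority_sample_size(
                SampleSizeParams(mu1=10.0, mu2=10.0, sigma=5.5, margin_fraction=1e-300)
            )

    @given(
        st.floats(0.1, 3.0), st.floats(0.1, 3.0),
        st.floats(0.0, 10.0), st.floats(1.0, 20.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotonicities(self, frac_a, frac_b, mu_diff, sigma):
        """n non-increasing in margin fraction and |mu1-mu2|; non-decreasing in sigma."""
        lo, hi = sorted((frac_a, frac_b))
        base = SampleSizeParams(mu1=10 + mu_diff, mu2=10.0, sigma=sigma, margin_fraction=lo)
        wider = SampleSizeParams(mu1=10 + mu_diff, mu2=10.0, sigma=sigma, margin_fraction=hi)
        assert rk.noninferiority_sample_size(wider) <= rk.noninferiority_sample_size(base)
        closer = SampleSizeParams(mu1=10.0, mu2=10.0, sigma=sigma, margin_fraction=lo)
        assert rk.noninferiority_sample_size(closer) >= rk.noninferiority_sample_size(base)
        noisier = SampleSizeParams(mu1=10 + mu_diff, mu2=10.0, sigma=2 * sigma, margin_fraction=lo)
        assert rk.noninferiority_sample_size(noisier) >= rk.noninferiority_sample_size(base)


class TestGroupCI:
    @pytest.mark.parametrize(
        "n,mean,sd,lower,upper",
        [
            (55, 11.98, 8.46, 9.69, 14.27),   # control total change
            (54, 6.28, 5.28, 4.84, 7.72),     # experimental lower-extremity change
            (55, 7.45, 7.24, 5.49, 9.41),     # control upper-extremity change
        ],
    )
    def test_reproduces_reported_intervals(self, n, mean, sd, lower, upper):
        lo, hi = rk.group_ci(GroupSummary(n=n, mean=mean, sd=sd))
        assert (round(lo, 2), round(hi, 2)) == (lower, upper)

    def test_experimental_total_upper_limit(self):
        _, hi = rk.group_ci(GroupSummary(n=54, mean=17.56, sd=11.65))
        assert round(hi, 2) == 20.74

    def test_zero_sd_degenerates_to_the_mean(self):
        lo, hi = rk.group_ci(GroupSummary(n=10, mean=3.0, sd=0.0))
        assert lo == hi == 3.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rk.group_ci(GroupSummary(n=1, mean=0.0, sd=1.0))

    def test_width_shrinks_like_one_over_sqrt_n(self):
        widths = {}
        for n in (20, 80):
            lo, hi = rk.group_ci(GroupSummary(n=n, mean=0.0, sd=5.0))
            assert lo < 0.0 < hi
            widths[n] = hi - lo
        # quadrupling n roughly halves the width (t quantile shrinks a little too)
        assert widths[80] < widths[20] / 1.9


def _t_tail_oracle(t_abs, df):
    """Two-sided p by numerical integration of the hand-written t density."""
    log_c = math.lgamma((df + 1) / 2) - math.lgamma(df / 2) - 0.5 * math.log(df * math.pi)

    def pdf(x):
        return math.exp(log_c - (df + 1) / 2 * math.log1p(x * x / df))

    tail, _ = quad(pdf, t_abs, np.inf)
    return 2 * tail


class TestTwoSampleTest:
    CONTROL = GroupSummary(55, 11.98, 8.46)
    EXPERIMENTAL = GroupSummary(54, 17.56, 11.65)

    def test_total_change_comparison_significant_at_p_005(self):
        _, _, p = rk.two_sample_test(self.CONTROL, self.EXPERIMENTAL)
        assert round(p, 3) == 0.005

    def test_pooled_variant_agrees_at_three_decimals_here(self):
        _, _, p = rk.two_sample_test(self.CONTROL, self.EXPERIMENTAL, equal_var=True)
        assert round(p, 3) == 0.005

    def test_identical_summaries_give_null_result(self):
        t, _, p = rk.two_sample_test(self.CONTROL, self.CONTROL)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_huge_shift_is_overwhelming(self):
        shifted = GroupSummary(55, 11.98 + 10 * 8.46, 8.46)
        _, _, p = rk.two_sample_test(self.CONTROL, shifted)
        assert p < 1e-6

    @pytest.mark.parametrize(
        "g1,g2",
        [
            (GroupSummary(55, 11.98, 8.46), GroupSummary(54, 17.56, 11.65)),
            (GroupSummary(20, 1.0, 2.0), GroupSummary(35, 2.5, 3.5)),
            (GroupSummary(12, -4.0, 1.0), GroupSummary(40, -3.2, 6.0)),
        ],
    )
    def test_p_matches_numerical_integration_oracle(self, g1, g2):
        t, df, p = rk.two_sample_test(g1, g2)
        assert p == pytest.approx(_t_tail_oracle(abs(t), df), abs=1e-6)


class TestProportions:
    def test_identical_gender_split_is_null(self):
        chi_p, fisher_p, (i1, i2) = rk.compare_proportions(43, 60, 43, 60)
        assert chi_p == pytest.approx(1.0)
        assert fisher_p == pytest.approx(1.0)
        assert i1 == i2 == 71.67

    def test_adverse_event_incidences_and_p(self):
        chi_p, _, (i1, i2) = rk.compare_proportions(28, 60, 22, 60)
        assert (i1, i2) == (46.67, 36.67)
        assert round(chi_p, 2) == 0.27

    def test_sparse_table_fisher(self):
        _, fisher_p, _ = rk.compare_proportions(7, 60, 4, 60)
        assert round(fisher_p, 2) == 0.53

    def test_extreme_separation_tends_to_zero(self):
        prev = 1.0
        for n in (5, 20, 80):
            chi_p, fisher_p, _ = rk.compare_proportions(0, n, n, n)
            assert fisher_p < prev
            prev = fisher_p
        assert fisher_p < 1e-6 or chi_p < 1e-6

    def test_completion_rate(self):
        assert incidence(109, 120) == pytest.approx(90.83)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            incidence(5, 0)
        with pytest.raises(ValueError):
            incidence(7, 5)


class TestBlockRandomization:
    def test_complete_strata_balance_exactly(self):
        alloc = rk.block_randomize({"center_1": 60, "center_2": 60}, block_length=4, seed=9)
        for stratum, seq in alloc.assignments.items():
            assert seq.count("experimental") == seq.count("control") == 30

    def test_every_complete_block_is_balanced(self):
        alloc = rk.block_randomize({"s": 40}, block_length=4, seed=3)
        seq = alloc.assignments["s"]
        for i in range(0, 40, 4):
            block = seq[i : i + 4]
            assert block.count("experimental") == 2

    def test_prefix_imbalance_bounded_by_half_block(self):
        for seed in range(5):
            alloc = rk.block_randomize({"s": 62}, block_length=6, seed=seed)
            seq = alloc.assignments["s"]
            for i in range(1, len(seq) + 1):
                prefix = seq[:i]
                imbalance = abs(prefix.count("experimental") - prefix.count("control"))
                assert imbalance <= 3

    def test_block_two_gives_balanced_even_prefixes(self):
        seq = rk.block_randomize({"s": 30}, block_length=2, seed=1).assignments["s"]
        for i in range(2, 31, 2):
            assert seq[:i].count("experimental") == i // 2

    def test_same_seed_reproduces_the_list(self):
        a = rk.block_randomize({"x": 33, "y": 21}, block_length=4, seed=42)
        b = rk.block_randomize({"x": 33, "y": 21}, block_length=4, seed=42)
        assert a.assignments == b.assignments

    def test_odd_block_length_rejected(self):
        with pytest.raises(ValueError):
            rk.block_randomize({"s": 10}, block_length=3, seed=0)

    def test_flatten_numbers_consecutively(self):
        df = rk.block_randomize({"a": 4, "b": 4}, block_length=2, seed=0).flatten()
        assert list(df["randomization_number"]) == list(range(1, 9))
        assert set(df["arm"]) == {"experimental", "control"}


class TestFma:
    def test_full_marks_partition_66_34_100(self):
        a = FmaAssessment(upper_items=(2,) * 33, lower_items=(2,) * 17)
        assert rk.fma_totals(a) == (66, 34, 100)

    def test_floor(self):
        a = FmaAssessment(upper_items=(0,) * 33, lower_items=(0,) * 17)
        assert rk.fma_totals(a) == (0, 0, 0)

    def test_partial(self):
        a = FmaAssessment(upper_items=(1,) * 33, lower_items=(0,) * 17)
        assert rk.fma_totals(a) == (33, 0, 33)

    def test_item_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            FmaAssessment(upper_items=(3,) + (0,) * 32, lower_items=(0,) * 17)

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValueError):
            FmaAssessment(upper_items=(0,) * 32, lower_items=(0,) * 17)

    @given(
        st.tuples(*[st.integers(0, 2)] * 33),
        st.tuples(*[st.integers(0, 2)] * 17),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_totals_consistent(self, upper, lower):
        u, l, total = rk.fma_totals(FmaAssessment(upper_items=upper, lower_items=lower))
        assert total == u + l
        assert 0 <= u <= 66 and 0 <= l <= 34 and total <= 100
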