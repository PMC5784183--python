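import numpy as np
import pytest

import audiosim as asim
from audiosim.agreement import (PairedMeasurements, PairedRecord, bland_altman,
                                cronbach_alpha, format_agreement_table,
                                icc_consistency, mean_diff_ci, order_effect,
                                pair, sd_ci_chi2, summarize)
from audiosim.core import ABOVE_MAX, DEFAULT_GRID, Audiogram


def make_pairs(a, b):
    return PairedMeasurements(
        [PairedRecord(f"s{i}", "left", 1000, float(x), float(y))
         for i, (x, y) in enumerate(zip(a, b))])


def full_audiograms(n_subjects, value=10):
    return [Audiogram(f"S{i:03d}", ear, "HL", {f: value for f in DEFAULT_GRID})
            for i in range(n_subjects) for ear in ("left", "right")]


class TestPair:
    def test_full_cohort_gives_980_records(self):
        a = full_audiograms(70)
        b = full_audiograms(70)
        assert len(pair(a, b)) == 980

    def test_flagged_cells_are_discarded(self):
        a = full_audiograms(70)
        b = full_audiograms(70)
        # flag 13 cells on side b, mirroring the trial's discard accounting
        k = 0
        for ag in b:
            if k == 13:
                break
            ag.thresholds.pop(8000)
            ag.oor_flags[8000] = ABOVE_MAX
            k += 1
        pairs = pair(a, b)
        assert len(pairs) == 967
        assert pairs.discarded_b == 13 and pairs.discarded_a == 0

    def test_one_sided_subject_rejected(self):
        a = full_audiograms(3)
        b = full_audiograms(2)
        with pytest.raises(ValueError):
            pair(a, b)

    def test_empty_inputs_pair_to_empty(self):
        assert len(pair([], [])) == 0


class TestSummaryCis:
    @pytest.mark.parametrize("mean,sd,n,expected", [
        (2.6, 8.3, 967, (2.1, 3.1)),
        (-0.1, 4.4, 952, (-0.4, 0.2)),
        (7.0, 9.3, 133, (5.4, 8.6)),
    ])
    def test_mean_ci_reproduces_reported_intervals(self, mean, sd, n, expected):
        lo, hi = mean_diff_ci(mean, sd, n)
        assert (round(lo, 1), round(hi, 1)) == expected

    @pytest.mark.parametrize("sd,n,expected", [
        (8.3, 967, (7.9, 8.7)),
        (4.4, 952, (4.2, 4.6)),
    ])
    def test_sd_ci_reproduces_reported_intervals(self, sd, n, expected):
        lo, hi = sd_ci_chi2(sd, n)
        assert (round(lo, 1), round(hi, 1)) == expected

    def test_zero_mean_interval_is_symmetric(self):
        lo, hi = mean_diff_ci(0.0, 3.0, 50)
        assert lo == pytest.approx(-hi)

    def test_zero_sd_degenerate(self):
        assert sd_ci_chi2(0.0, 100) == (0.0, 0.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            mean_diff_ci(0, 1, 1)
        with pytest.raises(ValueError):
            sd_ci_chi2(1, 1)


class TestSummarize:
    def test_identical_sides(self):
        rows = summarize(make_pairs([10, 15, 20], [10, 15, 20]),
                         per_frequency=False)
        row = rows[-1]
        assert row.mean_diff == 0 and row.sd_diff == 0
        assert all(v == 100.0 for v in row.cumulative.values())

    def test_hand_counted_cumulative_distribution(self):
        rows = summarize(make_pairs([3, -7, 12], [0, 0, 0]),
                         per_frequency=False)
        cum = rows[-1].cumulative
        assert round(cum[5]) == 33 and round(cum[10]) == 67 and cum[15] == 100

    def test_pooled_n_equals_sum_of_frequency_ns(self, rng):
        records = [PairedRecord(f"s{i}", "left", int(f), float(rng.normal()),
                                float(rng.normal()))
                   for i in range(20) for f in DEFAULT_GRID]
        rows = summarize(PairedMeasurements(records))
        per_freq = [r for r in rows if r.frequency != "Total"]
        total = [r for r in rows if r.frequency == "Total"][0]
        assert sum(r.n for r in per_freq) == total.n == 140

    def test_record_order_invariance(self, rng):
        records = [PairedRecord(f"s{i}", "left", 1000, float(rng.normal()),
                                float(rng.normal())) for i in range(30)]
        r1 = summarize(PairedMeasurements(records), per_frequency=False)[-1]
        shuffled = [records[j] for j in rng.permutation(30)]
        r2 = summarize(PairedMeasurements(shuffled), per_frequency=False)[-1]
        assert r1.mean_diff == pytest.approx(r2.mean_diff)
        assert r1.sd_diff == pytest.approx(r2.sd_diff)

    def test_swapping_sides_negates_mean_and_preserves_spread(self, rng):
        pairs = make_pairs(rng.normal(20, 8, 40), rng.normal(18, 6, 40))
        r = summarize(pairs, per_frequency=False)[-1]
        rs = summarize(pairs.swapped(), per_frequency=False)[-1]
        assert rs.mean_diff == pytest.approx(-r.mean_diff)
        assert rs.sd_diff == pytest.approx(r.sd_diff)
        assert rs.mean_abs_diff == pytest.approx(r.mean_abs_diff)
        assert rs.icc == pytest.approx(r.icc)
        assert rs.cumulative == r.cumulative

    def test_formatted_table_rounds_at_boundary_only(self):
        pairs = make_pairs([10, 15, 25, 30], [12, 11, 22, 24])
        rows = summarize(pairs, per_frequency=False)
        df = format_agreement_table(rows)
        assert df.loc[0, "mean_diff"] == round(rows[-1].mean_diff, 1)


class TestReliability:
    def test_constant_shift_gives_perfect_consistency(self, rng):
        a = rng.normal(20, 10, 30)
        pairs = make_pairs(a, a + 7)
        icc, lo, hi = icc_consistency(pairs)
        assert icc == pytest.approx(1.0)
        alpha, *_ = cronbach_alpha(pairs)
        assert alpha == pytest.approx(1.0)

    def test_independent_sides_give_near_zero(self, rng):
        pairs = make_pairs(rng.normal(0, 10, 2000), rng.normal(0, 10, 2000))
        icc, *_ = icc_consistency(pairs)
        alpha, *_ = cronbach_alpha(pairs)
        assert abs(icc) < 0.1 and abs(alpha) < 0.2

    def test_alpha_icc_identity(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 25))
            pairs = make_pairs(rng.normal(0, 10, n),
                               rng.normal(0, 10, n))
            try:
                icc, *_ = icc_consistency(pairs)
                alpha, *_ = cronbach_alpha(pairs)
            except ValueError:
                continue
            assert alpha == pytest.approx(2 * icc / (1 + icc), abs=1e-10)

    def test_matches_pingouin_anova_oracle(self, rng):
        """Cross-check ICC (two-way consistency, single) and alpha against
        an independent ANOVA implementation on small instances."""
        import pandas as pd
        import pingouin as pg
        for n in (4, 7, 12, 20):
            a = rng.normal(30, 12, n)
            b = a + rng.normal(2, 6, n)
            pairs = make_pairs(a, b)
            icc, lo, hi = icc_consistency(pairs)
            df = pd.DataFrame({
                "subject": list(range(n)) * 2,
                "rater": ["a"] * n + ["b"] * n,
                "score": np.concatenate([a, b])})
            ref = pg.intraclass_corr(df, "subject", "rater", "score")
            ref3 = ref[ref.Type == "ICC(C,1)"].iloc[0]
            assert icc == pytest.approx(ref3.ICC, abs=1e-9)
            # pingouin rounds its CI to 2 decimals
            assert (lo, hi) == pytest.approx(tuple(ref3.CI95), abs=0.0051)
            alpha, alo, ahi = cronbach_alpha(pairs)
            ref_a, ref_ci = pg.cronbach_alpha(
                pd.DataFrame({"a": a, "b": b}))
            assert alpha == pytest.approx(ref_a, abs=1e-9)
            assert (alo, ahi) == pytest.approx(tuple(ref_ci), abs=0.005)

    def test_degenerate_variance_rejected(self):
        pairs = make_pairs([5, 5, 5], [5, 5, 5])
        with pytest.raises(ValueError):
            icc_consistency(pairs)
        with pytest.raises(ValueError):
            cronbach_alpha(pairs)


class TestBlandAltman:
    def test_constant_difference(self):
        out = bland_altman(make_pairs([10, 20, 30], [7, 17, 27]),
                           per_frequency=False)
        assert out["Total"] == pytest.approx((3.0, 3.0, 3.0))

    def test_limits_near_1_96_for_standard_normal(self, rng):
        d = rng.normal(0, 1, 20000)
        out = bland_altman(make_pairs(d, np.zeros_like(d)), per_frequency=False)
        m, lo, hi = out["Total"]
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_limits_bracket_mean(self, rng):
        out = bland_altman(make_pairs(rng.normal(5, 3, 50),
                                      rng.normal(0, 3, 50)), per_frequency=False)
        m, lo, hi = out["Total"]
        assert lo <= m <= hi


class TestOrderEffect:
    def test_identical_groups_pool(self, rng):
        d = rng.normal(2, 5, 200)
        res = order_effect(d, d.copy())
        assert res.pool

    def test_strongly_shifted_groups_do_not_pool(self, rng):
        d1 = rng.normal(0, 5, 200)
        se = 5 / np.sqrt(200)
        d2 = rng.normal(10 * se, 5, 200)
        res = order_effect(d1, d2)
        assert not res.pool

    def test_group_means_match_direct_computation(self, rng):
        d1, d2 = rng.normal(1, 2, 50), rng.normal(3, 2, 60)
        res = order_effect(d1, d2)
        assert res.mean_1 == pytest.approx(d1.mean())
        assert res.mean_2 == pytest.approx(d2.mean())
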