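"""Statistics battery: hand-checked examples and independent oracles."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from hippocal.errors import DegenerateSampleError, ParameterError
from hippocal.stats import (
    interaction_permutation_p,
    mann_kendall,
    one_way_anova_bonferroni,
    paired_t,
    repeated_group_time_model,
    wilcoxon_rank_sum,
)


class TestWilcoxon:
    def test_fully_separated_small_samples(self):
        # exact one-sided p = 1/C(6,3) = 0.05 -> two-sided 0.1
        r = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(0.1)

    def test_identical_samples(self):
        r = wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r.p_value == 1.0

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x, y = rng.normal(size=6), rng.normal(size=8)
            mine = wilcoxon_rank_sum(x, y).p_value
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=15)
        a = wilcoxon_rank_sum(x, y).p_value
        b = wilcoxon_rank_sum(np.exp(x), np.exp(y)).p_value
        assert a == pytest.approx(b)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_rank_sum([], [1.0])


class TestMannKendall:
    def test_strictly_increasing_length_8(self):
        r = mann_kendall(np.arange(8.0))
        assert r.statistic == 28  # C(8,2) concordant pairs
        assert r.extra["tau"] == 1.0

    def test_constant_series(self):
        r = mann_kendall(np.ones(8))
        assert r.statistic == 0 and r.p_value == 1.0

    def test_reversal_antisymmetry(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=10)
        a, b = mann_kendall(x), mann_kendall(x[::-1])
        assert a.statistic == -b.statistic
        assert a.p_value == pytest.approx(b.p_value)

    def test_s_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            x = np.round(rng.normal(size=8), 1)  # ties likely
            s = 0
            for i in range(8):
                for j in range(i + 1, 8):
                    s += np.sign(x[j] - x[i])
            assert mann_kendall(x).statistic == s

    def test_short_series_rejected(self):
        with pytest.raises(ParameterError):
            mann_kendall([1.0, 2.0])


class TestPairedT:
    def test_zero_mean_differences(self):
        r = paired_t([0, 0, 0, 0], [1, -1, 1, -1])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_example(self):
        # d = {1,2,3}: t = 2 * sqrt(3) = 3.4641, df = 2
        r = paired_t([0, 0, 0], [1, 2, 3])
        assert r.statistic == pytest.approx(2 * np.sqrt(3.0))
        assert r.extra["df"] == 2

    def test_constant_shift_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=10), rng.normal(size=10)
        mine = paired_t(x, y)
        ref = sps.ttest_rel(y, x)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)


def _cohort_table(rng, time_effect=0.0, group_effect=0.0, interaction=0.0, n_mice=4, sd=0.2):
    days = [0, 9, 16, 23]
    rows = []
    for g, gi in [("cuprizone", 1.0), ("control", 0.0)]:
        for m in range(n_mice):
            base = rng.normal(0, 0.3)
            for i, d in enumerate(days):
                y = (
                    base
                    + time_effect * i
                    + group_effect * gi
                    + interaction * i * gi
                    + rng.normal(0, sd)
                )
                rows.append({"group": g, "mouse_id": f"{g}{m}", "day": d, "y": y})
    return pd.DataFrame(rows)


class TestRepeatedMeasures:
    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        tbl = _cohort_table(rng, time_effect=0.3, interaction=0.4)
        mine = repeated_group_time_model(tbl, "y").set_index("effect")
        ref = pg.mixed_anova(
            data=tbl, dv="y", within="day", subject="mouse_id", between="group"
        ).set_index("Source")
        assert mine.loc["group", "F"] == pytest.approx(ref.loc["group", "F"])
        assert mine.loc["time", "F"] == pytest.approx(ref.loc["day", "F"])
        assert mine.loc["group:time", "F"] == pytest.approx(ref.loc["Interaction", "F"])

    def test_identical_responses_report_no_effect(self):
        rows = [
            {"group": g, "mouse_id": f"{g}{m}", "day": d, "y": 1.0}
            for g in ("a", "b")
            for m in range(2)
            for d in (0, 1)
        ]
        res = repeated_group_time_model(pd.DataFrame(rows), "y").set_index("effect")
        assert (res["F"] == 0).all()
        assert (res["p"] == 1.0).all()

    def test_pure_time_effect_detected_group_null_calibrated(self):
        time_hits = 0
        group_calm = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tbl = _cohort_table(rng, time_effect=0.4, sd=0.2)  # 2 SD per step
            res = repeated_group_time_model(tbl, "y").set_index("effect")
            time_hits += res.loc["time", "p"] < 0.05
            group_calm += res.loc["group", "p"] > 0.05
        assert time_hits >= 8
        assert group_calm >= 8

    def test_incomplete_mouse_excluded_with_warning(self):
        rng = np.random.default_rng(1)
        tbl = _cohort_table(rng)
        tbl = tbl[~((tbl["mouse_id"] == "control0") & (tbl["day"] == 9))]
        with pytest.warns(UserWarning, match="incomplete"):
            res = repeated_group_time_model(tbl, "y")
        assert len(res) == 3

    def test_interaction_permutation_agrees_with_parametric(self):
        rng = np.random.default_rng(2)
        tbl = _cohort_table(rng, interaction=0.25, sd=0.3, n_mice=6)
        res = repeated_group_time_model(tbl, "y").set_index("effect")
        p_param = res.loc["group:time", "p"]
        p_perm = interaction_permutation_p(tbl, "y", n_permutations=400, seed=0)
        assert abs(p_param - p_perm) <= 0.05


class TestOneWayAnova:
    def test_hand_checked_sums_of_squares(self):
        # groups {1,2,3}, {2,3,4}, {10,11,12}: SSB = 146, SSW = 6,
        # F = (146/2) / (6/6) = 73.
        omnibus, pairwise = one_way_anova_bonferroni(
            [[1, 2, 3], [2, 3, 4], [10, 11, 12]]
        )
        assert omnibus.statistic == pytest.approx(73.0)
        assert (pairwise["p_adjusted"] >= pairwise["p_raw"]).all()

    def test_identical_groups(self):
        omnibus, pairwise = one_way_anova_bonferroni([[1.0, 1.0], [1.0, 1.0]])
        assert omnibus.statistic == 0.0
        assert (pairwise["p_adjusted"] == 1.0).all()

    def test_bonferroni_multiplies_and_clips(self):
        _, pairwise = one_way_anova_bonferroni(
            [[1, 2, 3], [2, 3, 4], [10, 11, 12]]
        )
        k = 3
        for _, row in pairwise.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_raw"] * k))

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            one_way_anova_bonferroni([[1.0], [1.0, 2.0]])
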