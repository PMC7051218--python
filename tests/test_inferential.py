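"""Repeated-measures ANOVA, power analysis and accumulation-curve checks.

Oracles: a loop-based sums-of-squares decomposition written from the
definitions, pingouin's rm_anova, and statsmodels' noncentral-F power
routine — all independent of the implementation under test.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from evrepro import (
    AbundanceTable,
    Flavor,
    GroupingScheme,
    PresenceMatrix,
    anova_power,
    bonferroni_alpha,
    fold_increase,
    required_replicates,
    rm_anova,
)
from evrepro.inferential import AccumulationModel, accumulation_curve, cohens_f


def apex_table(values):
    values = np.asarray(values, dtype=float)
    return AbundanceTable(
        protein_ids=tuple(f"P{i}" for i in range(values.shape[0])),
        replicate_ids=tuple(f"R{j + 1}" for j in range(values.shape[1])),
        values=values,
        flavor=Flavor.APEX,
    )


def brute_force_rm_anova(y):
    """Within-subject one-way ANOVA via explicit residual loops."""
    y = np.asarray(y, dtype=float)
    s, k = y.shape
    grand = y.mean()
    cond = [np.mean([y[i][j] for i in range(s)]) for j in range(k)]
    subj = [np.mean([y[i][j] for j in range(k)]) for i in range(s)]
    ss_between = s * sum((c - grand) ** 2 for c in cond)
    ss_subject = k * sum((m - grand) ** 2 for m in subj)
    ss_error = sum(
        (y[i][j] - cond[j] - subj[i] + grand) ** 2 for i in range(s) for j in range(k)
    )
    df_b, df_e = k - 1, (k - 1) * (s - 1)
    f = (ss_between / df_b) / (ss_error / df_e)
    return f, ss_between, ss_subject, ss_error


class TestRmAnova:
    def test_identical_conditions_give_null_result(self):
        vals = np.tile(np.array([[3.0], [5.0], [9.0]]), (1, 9))
        r = rm_anova(apex_table(vals))
        assert r.f_value == 0.0
        assert r.p_value == 1.0

    def test_toy_example_against_brute_force_and_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        y = np.array(
            [[10.0, 12.0, 15.0], [8.0, 9.0, 12.0], [11.0, 14.0, 13.0], [7.0, 7.5, 9.0]]
        )
        t = apex_table(y)
        r = rm_anova(t)
        f_oracle, ssb, sss, sse = brute_force_rm_anova(y)
        assert r.f_value == pytest.approx(f_oracle, rel=1e-12)
        assert r.ss_between == pytest.approx(ssb, rel=1e-12)
        assert r.ss_subjects == pytest.approx(sss, rel=1e-12)
        assert r.ss_error == pytest.approx(sse, rel=1e-10)
        long = pd.DataFrame(
            {
                "y": y.ravel(),
                "cond": list(t.replicate_ids) * 4,
                "subj": np.repeat(range(4), 3),
            }
        )
        aov = pg.rm_anova(data=long, dv="y", within="cond", subject="subj")
        assert r.f_value == pytest.approx(float(aov["F"][0]), rel=1e-9)
        assert r.p_value == pytest.approx(float(aov["p_unc"][0]), rel=1e-6)
        assert (r.df_between, r.df_error) == (int(aov["ddof1"][0]), int(aov["ddof2"][0]))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instances_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.integers(3, 10)
        k = rng.integers(2, 9)
        y = rng.lognormal(3, 1, (s, k))
        r = rm_anova(apex_table(y))
        f_oracle, *_ = brute_force_rm_anova(y)
        assert r.f_value == pytest.approx(f_oracle, rel=1e-8)

    def test_invariant_to_per_subject_constant(self):
        rng = np.random.default_rng(21)
        y = rng.lognormal(2, 0.5, (6, 4))
        shifted = y + rng.uniform(1, 50, (6, 1))
        a = rm_anova(apex_table(y))
        b = rm_anova(apex_table(shifted))
        assert a.f_value == pytest.approx(b.f_value, rel=1e-9)

    def test_invariant_to_condition_relabeling(self):
        rng = np.random.default_rng(22)
        y = rng.lognormal(2, 0.5, (6, 5))
        perm = [3, 0, 4, 2, 1]
        a = rm_anova(apex_table(y))
        b = rm_anova(apex_table(y[:, perm]))
        assert a.f_value == pytest.approx(b.f_value, rel=1e-12)

    def test_grouped_conditions_use_member_means(self):
        rng = np.random.default_rng(23)
        y = rng.lognormal(2, 0.5, (5, 9))
        g = GroupingScheme(
            scheme="TR", groups=(("R1", "R2", "R3"), ("R4", "R5", "R6"), ("R7", "R8", "R9"))
        )
        r = rm_anova(apex_table(y), g)
        means = np.stack([y[:, i : i + 3].mean(axis=1) for i in (0, 3, 6)], axis=1)
        f_oracle, *_ = brute_force_rm_anova(means)
        assert r.f_value == pytest.approx(f_oracle, rel=1e-10)
        assert (r.df_between, r.df_error) == (2, 2 * 4)

    def test_complete_cases_only(self):
        y = np.ones((4, 3))
        y[0] = [2.0, 3.0, 4.0]
        y[1] = [5.0, 1.0, 2.0]
        y[2, 1] = 0.0  # incomplete -> dropped
        y[3] = [4.0, 2.0, 2.0]
        r = rm_anova(apex_table(y))
        assert r.n_subjects == 3

    def test_df_structure_for_common_protein_counts(self):
        # 108 complete-case proteins x 3 conditions -> df (2, 214)
        rng = np.random.default_rng(24)
        y = rng.lognormal(3, 1, (108, 3))
        r = rm_anova(apex_table(y))
        assert (r.df_between, r.df_error) == (2, 214)

    def test_too_few_subjects_rejected(self):
        y = np.zeros((3, 3))
        y[0] = [1.0, 2.0, 3.0]
        with pytest.raises(ValueError, match="complete-case"):
            rm_anova(apex_table(y))


class TestBonferroni:
    def test_three_and_nine_way_thresholds(self):
        assert bonferroni_alpha(0.05, 3) == pytest.approx(0.0167, abs=5e-5)
        assert bonferroni_alpha(0.05, 9) == pytest.approx(0.00556, abs=5e-6)

    def test_identity_case(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    @pytest.mark.parametrize("alpha,k", [(0.0, 3), (1.0, 3), (0.05, 0)])
    def test_invalid_inputs(self, alpha, k):
        with pytest.raises(ValueError):
            bonferroni_alpha(alpha, k)


class TestAnovaPower:
    def test_null_effect_power_equals_alpha(self):
        for alpha in (0.05, 0.016):
            assert anova_power(0.0, 3, 10, alpha) == pytest.approx(alpha, rel=1e-12)

    def test_matches_independent_noncentral_f_routine(self):
        FTestAnovaPower = pytest.importorskip("statsmodels.stats.power").FTestAnovaPower
        for f, k, n, alpha in [(0.5, 3, 20, 0.05), (0.25, 9, 8, 0.016), (1.2, 4, 3, 0.01)]:
            ours = anova_power(f, k, n, alpha)
            theirs = FTestAnovaPower().power(
                effect_size=f, nobs=k * n, alpha=alpha, k_groups=k
            )
            assert ours == pytest.approx(theirs, abs=1e-6)

    def test_strictly_increasing_in_n(self):
        powers = [anova_power(0.3, 3, n, 0.016) for n in range(2, 40)]
        assert all(b > a for a, b in zip(powers, powers[1:]))

    def test_tends_to_one(self):
        assert anova_power(0.2, 3, 2000, 0.016) > 0.999


class TestRequiredReplicates:
    def test_large_effect_saturates_at_two(self):
        rng = np.random.default_rng(31)
        y = rng.lognormal(0, 0.01, (20, 3)) * np.array([1.0, 100.0, 10000.0])
        r = required_replicates(apex_table(y))
        assert r.n_required == 2

    def test_bracketing_invariant(self):
        rng = np.random.default_rng(32)
        y = rng.lognormal(3, 1, (40, 9))
        r = required_replicates(apex_table(y))
        assert r.achieved_power >= r.power_target
        if r.n_required > 2:
            below = anova_power(r.effect_size_f, r.k_groups, r.n_required - 1, r.alpha)
            assert below < r.power_target

    def test_self_consistent_with_planted_effect(self):
        # plant a known Cohen's f, then invert the power function directly
        rng = np.random.default_rng(33)
        y = rng.lognormal(3, 0.8, (60, 9))
        f = cohens_f(y)
        r = required_replicates(apex_table(y))
        n = 2
        while anova_power(f, 9, n, 0.016) < 0.8:
            n += 1
        assert r.n_required == n

    def test_zero_effect_has_no_finite_requirement(self):
        rng = np.random.default_rng(34)
        base = rng.lognormal(3, 1, (30, 1))
        y = np.tile(base, (1, 9))  # identical columns: f = 0
        r = required_replicates(apex_table(y))
        assert r.n_required is None
        assert r.achieved_power == pytest.approx(r.alpha)

    def test_zero_within_variance_rejected(self):
        y = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 1))
        with pytest.raises(ValueError, match="variance"):
            required_replicates(apex_table(y))


def presence(mat):
    mat = np.asarray(mat, dtype=bool)
    return PresenceMatrix(
        protein_ids=tuple(f"P{i}" for i in range(mat.shape[0])),
        replicate_ids=tuple(f"R{j + 1}" for j in range(mat.shape[1])),
        present=mat,
    )


class TestFoldIncrease:
    def test_saturated_matrix_zero_fold(self):
        r = fold_increase(presence(np.ones((12, 9))), n_target=27)
        assert r.fold_increase == 0.0
        assert r.s_extrapolated == 12.0
        assert all(v == 12.0 for v in r.accumulation_curve)

    def test_exhaustive_subset_oracle_small(self):
        mat = np.array(
            [
                [1, 0, 0, 0, 0],
                [1, 1, 0, 0, 0],
                [0, 1, 1, 1, 0],
                [1, 1, 1, 1, 1],
                [0, 0, 0, 0, 1],
            ],
            dtype=bool,
        )
        p = presence(mat)
        curve = accumulation_curve(p)
        for n in range(1, 6):
            subsets = list(itertools.combinations(range(5), n))
            expected = np.mean(
                [mat[:, list(sub)].any(axis=1).sum() for sub in subsets]
            )
            assert curve[n - 1] == pytest.approx(expected)

    def test_hand_computed_s1_s2(self):
        # columns detect {2, 1, 3} proteins; pairwise unions {P0..}: hand count
        mat = np.array([[1, 0, 0], [1, 1, 0], [0, 0, 1], [0, 0, 1], [0, 0, 1]], dtype=bool)
        curve = accumulation_curve(presence(mat))
        assert curve[0] == pytest.approx((2 + 1 + 3) / 3)
        # unions: {c1,c2}=2, {c1,c3}=5, {c2,c3}=4 -> mean 11/3
        assert curve[1] == pytest.approx(11 / 3)

    def test_curve_non_decreasing_with_dropout(self, synthetic_dataset):
        from evrepro import presence_matrix

        _, lfq, _, _, _ = synthetic_dataset
        curve = accumulation_curve(presence_matrix(lfq))
        assert all(b >= a for a, b in zip(curve, curve[1:]))

    @pytest.mark.parametrize("model", list(AccumulationModel))
    def test_fold_non_negative_and_models_run(self, model, synthetic_dataset):
        from evrepro import presence_matrix

        _, lfq, _, _, _ = synthetic_dataset
        r = fold_increase(presence_matrix(lfq), n_target=18, model=model)
        assert r.fold_increase >= 0.0
        assert r.s_extrapolated >= r.s_observed

    def test_target_below_observed_rejected(self):
        with pytest.raises(ValueError):
            fold_increase(presence(np.ones((3, 9))), n_target=5)
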