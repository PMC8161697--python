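"""Statistical battery: mixed models, t-tests, pAUC, DeLong, rmcorr, power."""

import numpy as np
import pandas as pd
import pytest

import enfaceoct as eo
from enfaceoct.stats import (
    bootstrap_ci,
    compare_paired_auc,
    delong_auc_variance,
    fit_lmm,
    min_detectable_r,
    pearson_ci,
    posthoc_ttests,
    power_for_r,
    rmcorr,
    standardized_pauc,
    subgroup_filter,
    welch_t_from_summary,
)


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

class TestFitLmm:
    def test_zero_variance_recovers_offset_exactly(self):
        spec = eo.CohortSpec(
            n_per_group=5, sd_eye=0.0, sd_sector=0.0, sd_resid=0.0,
            glaucoma_offset_fg=40.0, seed=0,
        )
        tab = eo.generate_cohort(spec)
        res = fit_lmm(tab, "first_gap_um")
        # ML optimizer tolerance bounds the attainable precision here
        assert res.group_difference_um == pytest.approx(40.0, abs=1e-4)
        assert res.var_resid == pytest.approx(0.0, abs=1e-4)

    def test_matches_ols_when_random_variances_vanish(self):
        """With eye and sector variance forced to ~0 the fixed effect equals
        the ordinary two-sample mean difference."""
        spec = eo.CohortSpec(n_per_group=8, sd_eye=0.0, sd_sector=0.0, sd_resid=6.0,
                             glaucoma_offset_fg=25.0, seed=4)
        tab = eo.generate_cohort(spec)
        res = fit_lmm(tab, "first_gap_um")
        ols = (
            tab[tab.group == "control"]["first_gap_um"].mean()
            - tab[tab.group == "glaucoma"]["first_gap_um"].mean()
        )
        assert res.group_difference_um == pytest.approx(ols, abs=1e-4)

    def test_lrt_detects_large_effect(self):
        tab = eo.generate_cohort(eo.CohortSpec(n_per_group=20, seed=8))
        res = fit_lmm(tab, "first_gap_um")
        assert res.converged
        assert res.lrt_chi2 > 20
        assert res.lrt_p < 1e-4
        assert res.ci_low <= res.group_difference_um <= res.ci_high

    def test_requires_both_groups(self):
        tab = eo.generate_cohort(eo.CohortSpec(n_per_group=3, seed=0))
        with pytest.raises(ValueError):
            fit_lmm(tab[tab.group == "control"], "first_gap_um")


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

class TestWelch:
    @pytest.mark.parametrize(
        "m1,sd1,m2,sd2,expected_p",
        [
            (68.6, 5.0, 69.3, 5.1, 0.66),   # age row
            (0.7, 2.0, 0.0, 1.4, 0.21),     # spherical equivalent row
        ],
    )
    def test_summary_rows_round_to_published_p(self, m1, sd1, m2, sd2, expected_p):
        _, _, p = welch_t_from_summary(m1, sd1, 20, m2, sd2, 20)
        assert round(p, 2) == expected_p

    def test_mean_deviation_row_hand_formula(self):
        # diff 5.1, SE = sqrt(1.21/20 + 9.61/20): t = 6.93..., p < 1e-4
        t, df, p = welch_t_from_summary(0.6, 1.1, 20, -4.5, 3.1, 20)
        se = np.sqrt(1.1**2 / 20 + 3.1**2 / 20)
        assert t == pytest.approx(5.1 / se, abs=1e-12)
        assert t == pytest.approx(6.93, abs=0.01)
        assert p < 0.0001

    def test_equal_summaries_give_t_zero_p_one(self):
        t, _, p = welch_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_degenerate_zero_variance_flagged(self):
        t, df, p = welch_t_from_summary(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert t == 0.0 and np.isnan(p)

    def test_posthoc_family_of_14_threshold(self):
        tab = eo.generate_cohort(eo.CohortSpec(n_per_group=10, seed=2))
        res = posthoc_ttests(tab)
        assert len(res) == 14
        assert res["alpha_adjusted"].unique() == pytest.approx([0.05 / 14])
        assert round(0.05 / 14, 4) == 0.0036
        # identical groups give t = 0
        same = tab.copy()
        same["first_gap_um"] = 50.0
        row = posthoc_ttests(same, measures=("first_gap_um",)).iloc[0]
        assert row["t"] == 0.0


# ---------------------------------------------------------------------------
# pAUC
# ---------------------------------------------------------------------------

def sweep_pauc_oracle(scores, labels, fpr_max=0.10):
    """Brute-force ROC from an explicit threshold sweep + trapezoid with
    boundary interpolation (independent of the implementation path)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    thresholds = np.unique(scores)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for th in thresholds:
        pred = scores >= th
        tpr.append(np.sum(pred & labels) / labels.sum())
        fpr.append(np.sum(pred & ~labels) / (~labels).sum())
    fpr, tpr = np.array(fpr), np.array(tpr)
    xs = np.linspace(0.0, fpr_max, 20001)
    ys = np.interp(xs, fpr, tpr)
    return float(np.trapezoid(ys, xs))


class TestStandardizedPauc:
    def test_perfect_separation_is_one(self):
        scores = np.r_[np.zeros(10), np.ones(10)]  # low = disease
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        res = standardized_pauc(scores, labels, direction="lower")
        assert res.standardized == pytest.approx(1.0)
        assert res.raw == pytest.approx(0.10)

    def test_chance_level_with_heavy_ties(self, rng):
        n = 10_000
        scores = rng.integers(0, 3, size=2 * n).astype(float)
        labels = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        res = standardized_pauc(scores, labels, direction="lower")
        assert res.standardized == pytest.approx(0.5, abs=0.02)

    def test_matches_threshold_sweep_oracle(self, rng):
        for _ in range(50):
            n1, n0 = rng.integers(5, 30, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # force ties
            labels = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
            scores[labels] -= rng.uniform(0, 2)
            res = standardized_pauc(scores, labels, direction="lower")
            oracle = sweep_pauc_oracle(-scores, labels)
            assert res.raw == pytest.approx(oracle, abs=2e-4)

    def test_invariant_under_monotone_transforms(self, rng):
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        base = standardized_pauc(scores, labels, direction="higher").standardized
        for f in (np.exp, lambda x: 3 * x + 7, lambda x: x**3):
            t = standardized_pauc(f(scores), labels, direction="higher").standardized
            assert t == pytest.approx(base, abs=1e-12)

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError):
            standardized_pauc([1.0, 2.0], [True, True])


class TestBootstrapCi:
    def test_perfect_separation_ci_is_1_1(self):
        scores = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        res = bootstrap_ci(scores, labels, B=200, seed=0, direction="lower")
        assert res.ci == (1.0, 1.0)

    def test_seeded_reproducibility(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        a = bootstrap_ci(scores, labels, B=300, seed=7)
        b = bootstrap_ci(scores, labels, B=300, seed=7)
        assert a.ci == b.ci


class TestComparePairedAuc:
    def test_self_comparison_p_is_one(self, rng):
        scores = rng.normal(size=40)
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        assert compare_paired_auc(scores, scores, labels, method="delong") == 1.0
        assert compare_paired_auc(scores, scores, labels, method="bootstrap", B=100, seed=0) == 1.0

    def test_delong_auc_equals_mann_whitney_oracle(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(100):
            n1, n0 = rng.integers(4, 25, size=2)
            scores = np.round(rng.normal(size=n1 + n0), 1)
            labels = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
            auc_a, _, _ = delong_auc_variance(scores, scores, labels)
            u = mannwhitneyu(scores[labels], scores[~labels]).statistic
            assert auc_a == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_paired_auc([1, 2], [1, 2, 3], [True, False, True])


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

class TestRmcorr:
    @pytest.mark.parametrize(
        "n_subj,n_rep,expected_df",
        [(40, 6, 199), (20, 6, 99), (20, 5, 79)],
    )
    def test_error_degrees_of_freedom(self, n_subj, n_rep, expected_df, rng):
        subjects = np.repeat(np.arange(n_subj), n_rep)
        x = rng.normal(size=subjects.size)
        y = rng.normal(size=subjects.size)
        assert rmcorr(subjects, x, y).df == expected_df

    def test_df_formula_exhaustive(self, rng):
        for n_subj in range(2, 11):
            for n_rep in range(2, 7):
                subjects = np.repeat(np.arange(n_subj), n_rep)
                x = rng.normal(size=subjects.size)
                y = rng.normal(size=subjects.size)
                res = rmcorr(subjects, x, y)
                assert res.df == n_subj * n_rep - n_subj - 1

    def test_equals_demeaned_pearson_oracle(self, rng):
        for _ in range(100):
            n_subj = int(rng.integers(3, 12))
            n_rep = int(rng.integers(2, 7))
            subjects = np.repeat(np.arange(n_subj), n_rep)
            x = rng.normal(size=subjects.size) + np.repeat(rng.normal(0, 3, n_subj), n_rep)
            y = 0.5 * x + rng.normal(size=subjects.size)
            res = rmcorr(subjects, x, y)
            xd = x - np.repeat([x[subjects == s].mean() for s in range(n_subj)], n_rep)
            yd = y - np.repeat([y[subjects == s].mean() for s in range(n_subj)], n_rep)
            oracle = np.corrcoef(xd, yd)[0, 1]
            assert res.r == pytest.approx(oracle, abs=1e-10)

    def test_cross_check_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        subjects = np.repeat(np.arange(15), 4)
        x = rng.normal(size=60) + np.repeat(rng.normal(0, 2, 15), 4)
        y = 0.7 * x + rng.normal(size=60)
        df = pd.DataFrame({"s": subjects, "x": x, "y": y})
        ours = rmcorr(subjects, x, y)
        theirs = pingouin.rm_corr(data=df, x="x", y="y", subject="s")
        assert ours.r == pytest.approx(float(theirs["r"].iloc[0]), abs=1e-6)
        assert ours.df == int(theirs["dof"].iloc[0])
        assert ours.p == pytest.approx(float(theirs["pval"].iloc[0]), rel=1e-6)

    def test_zero_within_subject_variance_flagged(self):
        subjects = np.repeat([0, 1], 3)
        x = np.repeat([1.0, 2.0], 3)  # constant within subject
        y = np.random.default_rng(0).normal(size=6)
        res = rmcorr(subjects, x, y)
        assert not res.valid and np.isnan(res.r)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, ci, p = pearson_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_null_correlation_small(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        r, _, _ = pearson_ci(x, y)
        assert abs(r) < 0.05

    def test_zero_variance_flagged(self):
        r, ci, p = pearson_ci(np.ones(10), np.arange(10.0))
        assert np.isnan(r)


class TestPower:
    @pytest.mark.parametrize("n,expected", [(40, 0.48), (20, 0.65)])
    def test_published_minimum_detectable_r(self, n, expected):
        assert round(min_detectable_r(n, power=0.90, alpha=0.05), 2) == expected

    def test_round_trip_power(self):
        r = min_detectable_r(40, power=0.90, alpha=0.05)
        assert power_for_r(r, 40) == pytest.approx(0.90, abs=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_r(3)
        with pytest.raises(ValueError):
            min_detectable_r(40, power=1.5)


class TestSubgroupFilter:
    def test_boundary_inclusion(self):
        tab = pd.DataFrame(
            {
                "eye_id": list("abcdef"),
                "group": ["glaucoma"] * 4 + ["control"] * 2,
                "md_db": [-1.0, -3.9, -4.0, -4.1, -10.0, 2.0],
            }
        )
        out = subgroup_filter(tab)
        assert (out.group == "glaucoma").sum() == 3  # -4.0 retained
        assert (out.group == "control").sum() == 2  # controls kept regardless

    def test_empty_subgroup_raises(self):
        tab = pd.DataFrame(
            {"eye_id": ["a"], "group": ["glaucoma"], "md_db": [-20.0]}
        )
        with pytest.raises(ValueError, match="-4"):
            subgroup_filter(tab)

    def test_seeded_cohort_count_reproducible(self):
        tab = eo.generate_cohort(eo.CohortSpec(n_per_group=20, seed=12))
        n1 = subgroup_filter(tab)[lambda d: d.group == "glaucoma"]["eye_id"].nunique()
        tab2 = eo.generate_cohort(eo.CohortSpec(n_per_group=20, seed=12))
        n2 = subgroup_filter(tab2)[lambda d: d.group == "glaucoma"]["eye_id"].nunique()
        assert n1 == n2
        assert 1 <= n1 <= 20
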