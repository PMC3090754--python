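"""Statistics: t tests, permutation schemes, balanced n-way ANOVA,
multiple-comparison thresholding, and the two-level group pipeline."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from sourcestorm.core_io import ChannelInfo, EpochSet, SensorArray
from sourcestorm.stats import (StatMap, anova_nway, difference,
                               permutation_test, threshold, ttest,
                               two_level_group)


class TestTtest:
    def test_hand_computed_example(self):
        """t for A=[1,2,3] vs B=[4,5,6]: diff -3, pooled var 1, se sqrt(2/3)."""
        res = ttest(np.array([1.0, 2, 3])[:, None],
                    np.array([4.0, 5, 6])[:, None])
        assert abs(res.statistic[0] - (-3.674)) < 1e-3
        assert res.df == 4

    def test_identical_groups(self):
        A = np.array([1.0, 2, 3])[:, None]
        res = ttest(A, A.copy(), paired=True)
        assert res.statistic[0] == 0.0 and res.p[0] == 1.0

    def test_zero_variance_rule(self):
        A = np.ones((5, 3))
        B = np.ones((5, 3)) * 2
        with pytest.warns(UserWarning, match="zero variance"):
            res = ttest(A, B, paired=True)
        assert (res.statistic == 0).all() and (res.p == 1).all()

    def test_welch_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((12, 4))
        B = 2 * rng.standard_normal((8, 4)) + 0.3
        res = ttest(A, B, equal_var=False)
        from scipy import stats as sps
        ref = sps.ttest_ind(A, B, equal_var=False)
        assert np.allclose(res.statistic, ref.statistic)
        assert np.allclose(res.p, ref.pvalue)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest(np.ones((1, 2)), np.ones((5, 2)))


class TestDifference:
    def test_identical_is_zero(self):
        A = np.random.default_rng(1).standard_normal((4, 6))
        assert np.allclose(difference(A, A), 0.0)

    def test_shift_recovered(self):
        A = np.random.default_rng(2).standard_normal((4, 6))
        assert np.allclose(difference(A + 1.5, A), 1.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            difference(np.empty((0, 3)), np.ones((2, 3)))


class TestPermutation:
    def test_paired_n3_matches_exhaustive_oracle(self):
        """Oracle: direct enumeration of all 2^3 sign flips of the paired t."""
        A = np.array([2.1, 1.4, 3.3])[:, None]
        B = np.array([1.0, 1.2, 2.0])[:, None]
        res = permutation_test(A, B, paired=True, n_perm=1000, seed=0)
        D = (A - B)[:, 0]

        def tstat(d):
            return d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))

        t_obs = tstat(D)
        count = 0
        for signs in product([1, -1], repeat=3):
            if abs(tstat(D * np.array(signs))) >= abs(t_obs) - 1e-12:
                count += 1
        assert res.p[0] == count / 8

    def test_identical_groups_large_p(self):
        A = np.random.default_rng(3).standard_normal((8, 2))
        res = permutation_test(A, A.copy(), paired=False, n_perm=500, seed=1)
        assert (res.p >= 0.5).all()

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        A, B = rng.standard_normal((2, 15, 3))
        r1 = permutation_test(A, B, n_perm=300, seed=7)
        r2 = permutation_test(A, B, n_perm=300, seed=7)
        assert np.array_equal(r1.p, r2.p)

    def test_p_never_zero(self):
        A = np.zeros((6, 1))
        B = np.full((6, 1), 10.0) + np.random.default_rng(5).standard_normal((6, 1)) * 0.01
        res = permutation_test(A, B, paired=True, n_perm=5000, seed=2)
        assert res.p[0] > 0

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(np.ones((3, 1)), np.zeros((3, 1)), n_perm=50)


class TestAnova:
    def test_two_way_matches_statsmodels_oracle(self):
        """Oracle: statsmodels OLS anova_lm on the same balanced 2x3 design."""
        rng = np.random.default_rng(6)
        a = np.repeat([0, 1], 12)
        b = np.tile(np.repeat([0, 1, 2], 4), 2)
        y = (0.5 * a + 0.2 * b + 0.4 * a * (b == 2)
             + rng.standard_normal(24))
        res = anova_nway(y[:, None], {"A": a, "B": b})

        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        df = pd.DataFrame({"y": y, "A": a.astype(str), "B": b.astype(str)})
        table = anova_lm(smf.ols("y ~ C(A) * C(B)", data=df).fit(), typ=2)
        assert np.isclose(res["A"].statistic[0], table.loc["C(A)", "F"])
        assert np.isclose(res["B"].statistic[0], table.loc["C(B)", "F"])
        assert np.isclose(res["A*B"].statistic[0], table.loc["C(A):C(B)", "F"])
        assert np.isclose(res["A"].p[0], table.loc["C(A)", "PR(>F)"])

    def test_hand_sums_of_squares_2x2(self):
        """Oracle: hand-computed balanced 2x2 decomposition."""
        # cell means: (0,0)=1, (0,1)=3, (1,0)=2, (1,1)=8; r=2 replicates
        y = np.array([1 - .1, 1 + .1, 3 - .1, 3 + .1,
                      2 - .1, 2 + .1, 8 - .1, 8 + .1])
        a = np.repeat([0, 1], 4)
        b = np.tile([0, 0, 1, 1], 2)
        res = anova_nway(y[:, None], {"A": a, "B": b})
        grand = 3.5
        ss_a = 8 * ((2 - grand) ** 2)       # means over A: 2 and 5
        ss_b = 8 * ((1.5 - grand) ** 2)     # means over B: 1.5 and 5.5
        # interaction effect: cell - rowmean - colmean + grand = -/+1
        ss_ab = 2 * 4 * 1.0 ** 2
        ss_resid = 8 * 0.01
        assert np.isclose(res["A"].statistic[0], (ss_a / 1) / (ss_resid / 4))
        assert np.isclose(res["B"].statistic[0], (ss_b / 1) / (ss_resid / 4))
        assert np.isclose(res["A*B"].statistic[0], (ss_ab / 1) / (ss_resid / 4))

    def test_noiseless_design_reports_large_finite_f(self):
        y = np.array([1.0, 1, 3, 3, 2, 2, 8, 8])
        a = np.repeat([0, 1], 4)
        b = np.tile([0, 0, 1, 1], 2)
        res = anova_nway(y[:, None], {"A": a, "B": b})
        assert np.isfinite(res["A"].statistic[0])
        assert res["A"].statistic[0] > 1e10

    def test_unbalanced_rejected(self):
        y = np.arange(7, dtype=float)
        a = np.array([0, 0, 0, 0, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 0, 0, 1])
        with pytest.raises(ValueError, match="unbalanced"):
            anova_nway(y[:, None], {"A": a, "B": b})

    def test_more_than_four_factors_rejected(self):
        y = np.zeros(32)
        factors = {f"F{i}": np.tile(np.repeat([0, 1], 2 ** i), 32 // 2 ** (i + 1))
                   for i in range(5)}
        with pytest.raises(ValueError, match="factors"):
            anova_nway(y[:, None], factors)

    def test_four_way_effects_sum_to_model_ss(self):
        rng = np.random.default_rng(7)
        levels = [2, 2, 2, 2]
        reps = 3
        combos = np.array(list(product(*[range(l) for l in levels])))
        obs = np.repeat(combos, reps, axis=0)
        y = rng.standard_normal(len(obs))
        factors = {f"F{i}": obs[:, i] for i in range(4)}
        res = anova_nway(y[:, None], factors)
        assert len(res) == 15  # all mains and interactions of 4 factors
        ss_model = 0.0
        for key, sm in res.items():
            df_eff = sm.df[0]
            # recover SS from F: SS = F * df_eff * MS_resid
            ss_model += sm.statistic[0] * df_eff
        # compare against direct cell-mean model SS / residual MS
        grand = y.mean()
        cells = {tuple(c): y[(obs == c).all(axis=1)].mean() for c in combos}
        fitted = np.array([cells[tuple(c)] for c in obs])
        ss_mod_direct = ((fitted - grand) ** 2).sum()
        ss_res = ((y - fitted) ** 2).sum()
        ms_res = ss_res / (len(y) - len(combos))
        assert np.isclose(ss_model * ms_res, ss_mod_direct)


class TestThreshold:
    def _map(self, p, stat=None):
        p = np.asarray(p, dtype=float)
        return StatMap(statistic=stat if stat is not None else np.ones_like(p),
                       p=p, method="test")

    def test_bonferroni_threshold(self):
        p = np.full(100, 4e-4)
        mask = threshold(self._map(p), "bonferroni", 0.05)
        assert mask.all()  # 4e-4 < 0.05/100 = 5e-4
        p2 = np.full(100, 6e-4)
        assert not threshold(self._map(p2), "bonferroni", 0.05).any()

    def test_bh_step_up_example(self):
        """Hand BH: all four p-values pass their step-up thresholds."""
        mask = threshold(self._map([0.001, 0.02, 0.03, 0.04]), "fdr", 0.05)
        assert mask.all()

    def test_bh_monotone_in_q(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=50) ** 2
        counts = [threshold(self._map(p), "fdr", q).sum()
                  for q in (0.01, 0.05, 0.1, 0.2)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_maxstat_requires_null(self):
        with pytest.raises(ValueError, match="max"):
            threshold(self._map([0.01]), "maxstat", 0.05)

    def test_maxstat_uses_null_quantile(self):
        null = np.arange(1, 101, dtype=float)  # quantile(0.95) ~ 95
        sm = self._map(np.full(3, 0.5), stat=np.array([50.0, 96.0, 99.0]))
        mask = threshold(sm, "maxstat", 0.05, perm_null=null)
        assert list(mask) == [False, True, True]


def _epochs_from(data, sfreq=100.0, t0=-0.2):
    n_tr, n_ch, n_s = data.shape
    channels = [ChannelInfo(name=f"C{i}", kind="EEG") for i in range(n_ch)]
    times = t0 + np.arange(n_s) / sfreq
    return EpochSet(epochs=data, times=times,
                    sensors=SensorArray(channels=channels))


class TestTwoLevelGroup:
    WINDOWS = ((-0.2, -0.01), (0.05, 0.25))

    def _subjects(self, n_subj, effect, seed):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_subj):
            data = rng.standard_normal((10, 2, 50))
            data[:, :, 25:] += effect
            out.append(_epochs_from(data))
        return out

    def test_identical_windows_null(self):
        subs = []
        for s in range(4):
            data = np.tile(np.ones((1, 2, 50)) * (s + 1), (5, 1, 1))
            subs.append(_epochs_from(data))
        res = two_level_group(subs, self.WINDOWS)
        assert (res.statistic == 0).all() and (res.p == 1).all()

    def test_detects_strong_effect(self):
        res = two_level_group(self._subjects(10, 2.0, 9), self.WINDOWS)
        assert (res.p < 0.01).all()

    def test_weighted_equals_unweighted_for_equal_variances(self):
        # identical within-subject noise => identical weights => the weighted
        # paired t must reduce to the ordinary one exactly
        rng = np.random.default_rng(10)
        base = rng.standard_normal((10, 2, 50))
        subs = []
        for s in range(6):
            data = base + rng.standard_normal() * 0.5
            data = data.copy()
            data[:, :, 25:] += 0.5 + 0.1 * s
            subs.append(_epochs_from(data))
        res_u = two_level_group(subs, self.WINDOWS, weighted=False)
        res_w = two_level_group(subs, self.WINDOWS, weighted=True)
        assert np.allclose(res_w.statistic, res_u.statistic, atol=1e-9)
        D = []
        for ep in subs:
            avg = ep.epochs.mean(axis=0)
            m1 = (ep.times >= -0.2) & (ep.times <= -0.01)
            m2 = (ep.times >= 0.05) & (ep.times <= 0.25)
            D.append(avg[:, m1].mean(axis=1) - avg[:, m2].mean(axis=1))
        D = np.stack(D)
        t_ref = D.mean(axis=0) / (D.std(axis=0, ddof=1) / np.sqrt(len(subs)))
        assert np.allclose(res_u.statistic, t_ref, atol=1e-12)

    def test_subject_without_trials_excluded(self):
        subs = self._subjects(3, 1.0, 11)
        subs[1].rejected[:] = True
        with pytest.warns(UserWarning, match="excluded"):
            res = two_level_group(subs, self.WINDOWS)
        assert res.df == 1  # two subjects remain

    def test_fewer_than_two_subjects_rejected(self):
        subs = self._subjects(2, 1.0, 12)
        subs[0].rejected[:] = True
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="fewer than 2"):
                two_level_group(subs, self.WINDOWS)

    def test_permutation_variant_runs(self):
        res = two_level_group(self._subjects(8, 1.0, 13), self.WINDOWS,
                              test="permutation", n_perm=200, seed=3)
        assert res.method == "group-perm-paired"
        assert (res.p > 0).all()
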