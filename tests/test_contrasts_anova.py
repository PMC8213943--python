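"""Planned peak contrasts and the repeated-measures ANOVA engine."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from allovot.anova import (gg_epsilon, one_way_anova, rm_anova_gg,
                           two_within_interaction_F)
from allovot.contrasts import (allophonic_peaks, contrast_group_test,
                               phonemic_peak, select_phonemic_center)
from allovot.oscillator import OscillatorParams, predict_dprime

CENTERS = list(range(-40, 41, 10))


def curve(dvals):
    return pd.DataFrame({"center_vot_ms": CENTERS, "dprime": dvals})


class TestPhonemicPeak:
    def test_single_peak(self):
        c = curve([1, 1, 1, 1, 3, 1, 1, 1, 1])
        val, center = phonemic_peak(c, boundary_ms=0.0)
        assert val == pytest.approx(2.0)
        assert center == 0

    def test_flat_curve_zero(self):
        val, _ = phonemic_peak(curve([1.2] * 9), boundary_ms=0.0)
        assert val == pytest.approx(0.0)

    @pytest.mark.parametrize("boundary,expected",
                             [(8.0, 10), (-8.0, -10), (2.0, 0), (None, 0),
                              (np.nan, 0), (5.0, 0)])
    def test_center_selection(self, boundary, expected):
        assert select_phonemic_center(boundary) == expected

    def test_missing_reference_center(self):
        c = curve([np.nan, 1, 1, 1, 3, 1, 1, 1, 1])
        val, _ = phonemic_peak(c, boundary_ms=0.0)
        assert np.isnan(val)

    def test_linearity(self):
        d = np.array([0.5, 0.2, 0.9, 1.4, 2.5, 1.1, 0.7, 0.4, 0.6])
        base, _ = phonemic_peak(curve(d), 0.0)
        scaled, _ = phonemic_peak(curve(3.0 * d), 0.0)
        shifted, _ = phonemic_peak(curve(d + 7.0), 0.0)
        assert scaled == pytest.approx(3.0 * base)
        assert shifted == pytest.approx(base)


class TestAllophonicPeaks:
    def test_elevated_30ms_pairs(self):
        d = [1, 2, 1, 0.4, 0.8, 0.3, 1, 2, 1]
        assert allophonic_peaks(curve(d)) == pytest.approx(1.0)

    def test_flat_curve_zero(self):
        assert allophonic_peaks(curve([0.7] * 9)) == pytest.approx(0.0)

    def test_pure_33hz_oscillator_value(self):
        # w33-only curve: d'(+-30) = 1, the four reference centers = -0.5
        osc = OscillatorParams(k=0.0, w33=1.0, w17=0.0)
        d = np.asarray(predict_dprime(osc, CENTERS))
        assert allophonic_peaks(curve(d)) == pytest.approx(1.5)

    def test_linearity(self):
        d = np.array([0.5, 0.2, 0.9, 1.4, 2.5, 1.1, 0.7, 0.4, 0.6])
        assert allophonic_peaks(curve(3 * d)) == pytest.approx(
            3 * allophonic_peaks(curve(d)))
        assert allophonic_peaks(curve(d + 5)) == pytest.approx(
            allophonic_peaks(curve(d)))


class TestContrastGroupTest:
    def _scores(self, a, b):
        return pd.DataFrame({
            "group": ["NR"] * len(a) + ["DYS"] * len(b),
            "phonemic_peak": list(a) + list(b),
        })

    def test_hand_computed_cohens_d(self):
        res = contrast_group_test(self._scores([1, 2, 3], [4, 5, 6]),
                                  "phonemic_peak")
        assert res["group_order"] == ("DYS", "NR")  # sorted labels
        assert res["mean_diff"] == pytest.approx(5 - 2)  # mean(DYS) - mean(NR)
        assert res["cohens_d"] == pytest.approx(3.0)  # pooled SD = 1

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = contrast_group_test(self._scores(a, b), "phonemic_peak")
        t, p = stats.ttest_ind(b, a)  # sorted group order: DYS first
        assert res["F"] == pytest.approx(t ** 2, rel=1e-10)
        assert res["p"] == pytest.approx(p, rel=1e-10)

    def test_identical_distributions(self):
        res = contrast_group_test(self._scores([1, 2, 3], [1, 2, 3]),
                                  "phonemic_peak")
        assert res["F"] == pytest.approx(0.0, abs=1e-12)
        assert res["cohens_d"] == pytest.approx(0.0, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            contrast_group_test(self._scores([1, 2], [4]), "phonemic_peak")


class TestGGEpsilon:
    def test_two_levels_exactly_one(self):
        rng = np.random.default_rng(0)
        assert gg_epsilon(rng.normal(size=(10, 2))) == 1.0

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for k in (3, 5, 9):
            eps = gg_epsilon(rng.normal(size=(12, k)))
            assert 1 / (k - 1) - 1e-12 <= eps <= 1.0

    def test_pingouin_oracle_to_three_decimals(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 1))
        data = base + rng.normal(scale=[0.5, 1.0, 1.5, 2.0, 0.8],
                                 size=(8, 5))
        ours = gg_epsilon(data)
        theirs = float(pg.epsilon(pd.DataFrame(data), correction="gg"))
        assert ours == pytest.approx(theirs, abs=5e-4)

    def test_singular_covariance_floored(self):
        # 3 subjects, 5 levels: covariance rank-deficient
        rng = np.random.default_rng(3)
        eps = gg_epsilon(rng.normal(size=(3, 5)))
        assert eps >= 1 / 4 - 1e-12


class TestRmAnova:
    def _long(self, wide, groups=None):
        df = wide.reset_index(names="subject")
        long = df.melt(id_vars="subject", var_name="level", value_name="y")
        if groups is not None:
            long["grp"] = long["subject"].map(dict(enumerate(groups)))
        return long

    def test_within_only_matches_pingouin(self):
        rng = np.random.default_rng(4)
        wide = pd.DataFrame(rng.normal(size=(10, 4))
                            + np.array([0.0, 0.5, 1.0, 0.2]))
        ours = rm_anova_gg(wide).iloc[0]
        theirs = pg.rm_anova(data=self._long(wide), dv="y", within="level",
                             subject="subject", correction=True,
                             effsize="np2").iloc[0]
        assert ours["F"] == pytest.approx(theirs["F"], rel=1e-9)
        assert ours["partial_eta2"] == pytest.approx(theirs["np2"], rel=1e-9)
        assert ours["eps"] == pytest.approx(theirs["eps"], abs=1e-9)
        assert ours["p"] == pytest.approx(theirs["p_GG_corr"], rel=1e-6)

    def test_mixed_design_matches_pingouin(self):
        rng = np.random.default_rng(6)
        n1, n2, k = 8, 8, 5
        groups = ["a"] * n1 + ["b"] * n2
        effect = np.vstack([np.zeros((n1, k)),
                            np.tile(np.linspace(0, 1, k), (n2, 1))])
        wide = pd.DataFrame(rng.normal(size=(n1 + n2, k)) + effect
                            + rng.normal(size=(n1 + n2, 1)))
        ours = rm_anova_gg(wide, groups=pd.Series(groups))
        theirs = pg.mixed_anova(data=self._long(wide, groups), dv="y",
                                within="level", subject="subject",
                                between="grp")
        by_effect = {r["effect"]: r for _, r in ours.iterrows()}
        assert by_effect["group"]["F"] == pytest.approx(
            theirs.loc[theirs["Source"] == "grp", "F"].iloc[0], rel=1e-9)
        assert by_effect["within"]["F"] == pytest.approx(
            theirs.loc[theirs["Source"] == "level", "F"].iloc[0], rel=1e-9)
        assert by_effect["group_x_within"]["F"] == pytest.approx(
            theirs.loc[theirs["Source"] == "Interaction", "F"].iloc[0],
            rel=1e-9)

    def test_equal_groups_give_small_interaction(self):
        rng = np.random.default_rng(7)
        wide = pd.DataFrame(rng.normal(size=(40, 9)))
        groups = pd.Series(["a", "b"] * 20)
        tab = rm_anova_gg(wide, groups=groups)
        inter = tab[tab["effect"] == "group_x_within"].iloc[0]
        assert inter["p"] > 0.01  # null data

    def test_listwise_deletion(self):
        rng = np.random.default_rng(8)
        wide = pd.DataFrame(rng.normal(size=(10, 4)))
        wide.iloc[0, 2] = np.nan
        tab = rm_anova_gg(wide)
        full = rm_anova_gg(wide.dropna())
        assert tab.iloc[0]["F"] == pytest.approx(full.iloc[0]["F"])


class TestTwoWithinInteraction:
    def test_identical_conditions_give_zero(self):
        res = two_within_interaction_F(np.zeros((12, 9)))
        assert res["F"] == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(9)
        d = rng.normal(size=(15, 9))
        res1 = two_within_interaction_F(d)
        res2 = two_within_interaction_F(d + 11.0)
        assert res1["F"] == pytest.approx(res2["F"], rel=1e-9)

    def test_matches_full_two_way_rm_anova(self):
        """Interaction F from the difference-score shortcut equals the
        Score-type x VOT interaction of the full two-within-factor
        repeated-measures ANOVA (pingouin oracle, uncorrected df)."""
        rng = np.random.default_rng(10)
        n, k = 12, 5
        model = rng.normal(size=(n, k))
        data = model + rng.normal(scale=0.5, size=(n, k)) \
            + np.linspace(0, 1, k)[None, :]
        rows = []
        for i in range(n):
            for j in range(k):
                rows.append(dict(subject=i, score_type="model", vot=j,
                                 y=model[i, j]))
                rows.append(dict(subject=i, score_type="data", vot=j,
                                 y=data[i, j]))
        long = pd.DataFrame(rows)
        theirs = pg.rm_anova(data=long, dv="y",
                             within=["score_type", "vot"], subject="subject")
        f_pg = theirs.loc[theirs["Source"].str.contains("\\*"), "F"].iloc[0]
        ours = two_within_interaction_F(model - data)
        assert ours["F"] == pytest.approx(f_pg, rel=1e-9)
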