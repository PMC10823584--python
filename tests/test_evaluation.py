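"""Evaluation statistics: AUCs, paired bootstrap, z/Welch tests, consensus."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from neoforest.evaluation import (
    bootstrap_compare,
    pauc01,
    proportions_ztest,
    roc_auc,
    select_consensus,
    welch_ttest_onesided,
)


class TestAuc:
    def test_perfect_and_inverted(self):
        labels = [1, 1, 0, 0]
        assert roc_auc(labels, [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert roc_auc(labels, [0.1, 0.2, 0.8, 0.9]) == 0.0

    def test_hand_enumerated_example(self):
        """labels [1,0,1,0], scores [0.9,0.8,0.7,0.1]: of the four
        positive-negative pairs, three are correctly ordered -> AUC 3/4."""
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.5, 0.6])

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        a = roc_auc(labels, scores)
        assert roc_auc(labels, np.exp(5 * scores)) == pytest.approx(a)
        assert roc_auc(labels, np.log(scores + 1e-9)) == pytest.approx(a)

    def test_pauc01_perfect_ranker(self):
        labels = [1] * 5 + [0] * 20
        scores = np.linspace(1, 0, 25)
        assert pauc01(labels, scores, normalised=True) == pytest.approx(1.0)
        assert pauc01(labels, scores, normalised=False) == pytest.approx(0.1)

    def test_pauc01_le_auc_scaled(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.random(200)
        assert pauc01(labels, scores) <= 1.0


class TestBootstrapCompare:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        comp = bootstrap_compare(labels, scores, scores, n_rounds=200, seed=0)
        assert comp.wins == 0
        assert comp.p_value == 1.0

    def test_perfect_vs_antiperfect(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        noise = rng.normal(0, 1e-6, 200)
        perfect = labels + noise
        anti = -labels + noise
        comp = bootstrap_compare(labels, perfect, anti, n_rounds=1000, seed=1)
        assert comp.p_value < 0.01

    def test_p_values_sum_at_least_one(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        s1, s2 = rng.random(80), rng.random(80)
        fwd = bootstrap_compare(labels, s1, s2, n_rounds=500, seed=5)
        rev = bootstrap_compare(labels, s2, s1, n_rounds=500, seed=5)
        assert fwd.p_value + rev.p_value >= 1.0
        # same resampled rounds: wins swap onto the complementary rounds
        assert np.allclose(fwd.auc_c1, rev.auc_c2)

    def test_rounds_and_determinism(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        s1, s2 = rng.random(60), rng.random(60)
        a = bootstrap_compare(labels, s1, s2, n_rounds=300, seed=9)
        b = bootstrap_compare(labels, s1, s2, n_rounds=300, seed=9)
        assert a.p_value == b.p_value
        assert a.n_rounds == 300 and len(a.auc_c1) == 300


class TestProportionsZtest:
    def test_printed_counts_reproduce_printed_p(self):
        """11/116 immunogenic among outside-ICORE mutations vs 620/2917 for
        inside-ICORE mutations: one-sided pooled z-test gives p = 0.0011."""
        p = proportions_ztest(11, 116, 620, 2917, alternative="smaller")
        assert p == pytest.approx(0.0011, abs=5e-5)

    def test_equal_proportions_give_half(self):
        assert proportions_ztest(10, 100, 20, 200, "smaller") == pytest.approx(0.5)
        assert proportions_ztest(10, 100, 20, 200, "larger") == pytest.approx(0.5)

    def test_against_statsmodels_oracle(self):
        from statsmodels.stats.proportion import proportions_ztest as sm_ztest

        rng = np.random.default_rng(6)
        for _ in range(100):
            n1, n2 = rng.integers(10, 500, 2)
            s1 = rng.integers(1, n1)
            s2 = rng.integers(1, n2)
            ours = proportions_ztest(int(s1), int(n1), int(s2), int(n2), "smaller")
            _, ref = sm_ztest([s1, s2], [n1, n2], alternative="smaller")
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_monotone_in_successes(self):
        ps = [proportions_ztest(s, 100, 50, 200, "smaller") for s in range(5, 60, 5)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            proportions_ztest(1, 0, 1, 10)
        with pytest.raises(ValueError):
            proportions_ztest(11, 10, 1, 10)


class TestWelch:
    def test_identical_samples_give_half(self):
        assert welch_ttest_onesided([1.0, 1.0, 1.0], [1.0, 1.0]) == 0.5

    def test_shifted_normals(self):
        rng = np.random.default_rng(7)
        a = rng.normal(1.0, 1.0, 1000)
        b = rng.normal(0.0, 1.0, 1000)
        assert welch_ttest_onesided(a, b) < 1e-10

    def test_against_manual_satterthwaite(self):
        """Matches a direct evaluation of the Welch statistic and
        Satterthwaite degrees of freedom to 1e-9."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            na, nb = rng.integers(5, 50, 2)
            a = rng.normal(rng.normal(), rng.uniform(0.5, 2.0), na)
            b = rng.normal(rng.normal(), rng.uniform(0.5, 2.0), nb)
            va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
            t = (a.mean() - b.mean()) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            ref = stats.t.sf(t, df)
            assert welch_ttest_onesided(a, b) == pytest.approx(ref, abs=1e-9)

    def test_short_samples_error(self):
        with pytest.raises(ValueError):
            welch_ttest_onesided([1.0], [1.0, 2.0])


class TestConsensusSelection:
    def test_harmonic_mean_values(self):
        ranked = select_consensus([("a", 0.8, 0.8), ("b", 1.0, 0.5)])
        by_name = {cfg: hm for cfg, _, _, hm in ranked}
        assert by_name["a"] == pytest.approx(0.8)
        assert by_name["b"] == pytest.approx(2 / 3)
        assert ranked[0][0] == "a"

    def test_stable_tie_order(self):
        ranked = select_consensus([("first", 0.7, 0.7), ("second", 0.7, 0.7)])
        assert [r[0] for r in ranked] == ["first", "second"]

    def test_harmonic_le_arithmetic(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b = rng.uniform(0.01, 1.0, 2)
            (_, _, _, hm), = select_consensus([("x", a, b)])
            assert hm <= (a + b) / 2 + 1e-12

    def test_nonpositive_auc_errors(self):
        with pytest.raises(ValueError):
            select_consensus([("x", 0.0, 0.5)])
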