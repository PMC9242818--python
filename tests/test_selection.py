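import numpy as np
import pandas as pd
import pytest

from lsradiomics import ConfigurationError, FeatureTable, FeatureTableSpec, generate_feature_table
from lsradiomics.selection import (
    fisher_score,
    mutual_information_score,
    poe,
    poe_acc_rank,
    select_all_methods,
    select_top,
)


def brute_force_poe(x, labels):
    """All-thresholds, both-polarities oracle."""
    best = len(x)
    for t in np.concatenate([x, [x.min() - 1, x.max() + 1]]):
        left = x <= t
        for lo, hi in ((1, 2), (2, 1)):
            err = np.sum(left & (labels != lo)) + np.sum(~left & (labels != hi))
            best = min(best, err)
    return best / len(x)


class TestFisherScore:
    def test_hand_computed_ratio(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([1, 1, 2, 2])
        # D = 1 (means 0.5/2.5 around 1.5), V = 0.25 -> F = 4
        assert fisher_score(x, labels) == pytest.approx(4.0)

    def test_identical_distributions_score_zero(self):
        x = np.array([0.0, 1.0, 0.0, 1.0])
        assert fisher_score(x, np.array([1, 1, 2, 2])) == 0.0

    def test_degenerate_separation_returns_inf(self):
        x = np.array([0.0, 0.0, 1.0, 1.0])
        assert fisher_score(x, np.array([1, 1, 2, 2])) == np.inf

    def test_affine_invariance_exact(self, rng):
        x = rng.random(40)
        labels = np.r_[np.ones(20, int), np.full(20, 2, int)]
        assert fisher_score(3.7 * x - 11.0, labels) == pytest.approx(
            fisher_score(x, labels), rel=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            fisher_score(np.arange(4.0), np.ones(4, int))


class TestPoe:
    def test_separable_feature_zero_error(self):
        assert poe(np.array([1.0, 2, 3, 4]), np.array([1, 1, 2, 2])) == 0.0

    def test_agreement_with_brute_force_oracle(self, rng):
        labels = rng.integers(1, 3, 30)
        labels[:2] = [1, 2]  # both classes present
        for _ in range(50):
            x = rng.normal(size=30)
            assert poe(x, labels) == pytest.approx(brute_force_poe(x, labels))

    def test_ties_handled(self):
        x = np.array([1.0, 1.0, 1.0, 2.0])
        labels = np.array([1, 1, 2, 2])
        assert poe(x, labels) == pytest.approx(brute_force_poe(x, labels))


class TestPoeAccRank:
    def test_perfect_separator_picked_first(self, rng):
        df = pd.DataFrame(
            {
                "a_noise": rng.normal(size=40),
                "b_sep": np.r_[np.zeros(20), np.ones(20)],
                "c_noise": rng.normal(size=40),
            }
        )
        labels = np.r_[np.ones(20, int), np.full(20, 2, int)]
        res = poe_acc_rank(FeatureTable(df, labels), k=3)
        assert res.selected[0] == "b_sep"
        assert res.scores["b_sep"] == 0.0

    def test_duplicate_of_best_not_ranked_second(self, rng):
        """An exact duplicate (ACC=1) must lose to an independent feature
        with no worse POE."""
        sep = np.r_[np.zeros(20), np.ones(20)] + rng.normal(0, 0.05, 40)
        indep = np.r_[np.zeros(20), np.ones(20)] + rng.normal(0, 0.05, 40)
        df = pd.DataFrame({"a_best": sep, "b_dup": sep.copy(), "c_indep": indep})
        labels = np.r_[np.ones(20, int), np.full(20, 2, int)]
        res = poe_acc_rank(FeatureTable(df, labels), k=3)
        assert res.selected[0] == "a_best"
        assert res.selected[1] != "b_dup"


class TestMutualInformation:
    def test_feature_equal_to_label_is_one_bit(self):
        labels = np.r_[np.ones(50, int), np.full(50, 2, int)]
        assert mutual_information_score(labels.astype(float), labels, n_bins=2) == pytest.approx(1.0)

    def test_constant_feature_is_zero_bits(self):
        labels = np.r_[np.ones(10, int), np.full(10, 2, int)]
        assert mutual_information_score(np.zeros(20), labels) == 0.0

    def test_independent_feature_near_zero(self, rng):
        """Mean MI of label-independent features stays below the small-sample
        bias budget (0.05 bits at n=200)."""
        labels = np.r_[np.ones(100, int), np.full(100, 2, int)]
        vals = [
            mutual_information_score(rng.normal(size=200), labels) for _ in range(200)
        ]
        assert np.mean(vals) < 0.05

    def test_invariance_to_monotone_rescaling(self, rng):
        labels = np.r_[np.ones(50, int), np.full(50, 2, int)]
        x = rng.normal(size=100) + 0.5 * (labels == 2)
        assert mutual_information_score(np.exp(x), labels) == pytest.approx(
            mutual_information_score(x, labels)
        )


class TestSelectTop:
    def test_combined_list_has_three_k_names(self):
        t = generate_feature_table(FeatureTableSpec(seed=0))
        _, combined = select_all_methods(t, k=10)
        assert len(combined) == 30

    def test_k_larger_than_feature_count_warns_and_returns_all(self):
        t = generate_feature_table(FeatureTableSpec(n_informative=2, n_noise=3, seed=1))
        with pytest.warns(UserWarning):
            res = select_top(t, "fisher", k=10)
        assert len(res.selected) == 5

    def test_planted_features_recovered_by_all_methods(self):
        for seed in (0, 1, 2):
            t = generate_feature_table(FeatureTableSpec(seed=seed))
            results, _ = select_all_methods(t, k=10)
            for method, res in results.items():
                n_inf = sum(1 for n in res.selected if n.startswith("inf"))
                assert n_inf >= 9, f"{method} recovered only {n_inf}/10 (seed {seed})"

    def test_scores_deterministic(self):
        t = generate_feature_table(FeatureTableSpec(seed=5))
        a = select_top(t, "mi")
        b = select_top(t, "mi")
        assert a.selected == b.selected and a.scores == b.scores

    def test_unknown_method_rejected(self):
        t = generate_feature_table(FeatureTableSpec(seed=0))
        with pytest.raises(ConfigurationError):
            select_top(t, "lasso")
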