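"""Fitness-to-adaptation regression, outlier calling, repeatability, overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aletrack import (FitnessAdaptationModel, ParameterError,
                      benjamini_hochberg, overlap_test, regress_adaptation,
                      replicate_repeatability)


def replicate_table(pre, adapt, n_rep=1, noise_sd=0.0, seed=0):
    """Long replicate table from strain-level arrays."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, (p, a) in enumerate(zip(pre, adapt)):
        for r in range(n_rep):
            rows.append((f"s{i:04d}", r, p, a + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["strain_id", "replicate",
                                       "preadaptation_D", "A75"])


class TestRegression:
    def test_collinear_input_recovers_line_exactly(self):
        pre = np.linspace(2.5, 6.5, 20)
        adapt = 0.85 * pre - 1.9
        res = regress_adaptation(replicate_table(pre, adapt))
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(0.85, abs=1e-10)
        assert res.intercept == pytest.approx(-1.9, abs=1e-9)

    def test_noise_free_single_class_slope_near_phi(self):
        # generative model: adaptation = phi * deficit; pre = basal + deficit
        rng = np.random.default_rng(1)
        deficits = rng.uniform(0.5, 4.0, 300)
        pre = 2.27 + deficits
        res = regress_adaptation(replicate_table(pre, 0.9 * deficits))
        assert res.slope == pytest.approx(0.9, abs=1e-9)
        assert res.rsquared > 0.99

    def test_permutation_destroys_association(self):
        rng = np.random.default_rng(2)
        deficits = rng.uniform(0.5, 4.0, 300)
        pre = 2.27 + deficits
        shuffled = rng.permutation(0.9 * deficits)
        res = regress_adaptation(replicate_table(pre, shuffled))
        assert res.rsquared < 0.05

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ParameterError):
            regress_adaptation(replicate_table(np.full(5, 3.0), np.arange(5.0)))

    def test_summary_mentions_key_quantities(self):
        pre = np.linspace(2.5, 6.5, 10)
        res = regress_adaptation(replicate_table(pre, 0.5 * pre))
        s = res.summary()
        assert "R^2" in s and "slope" in s


def bh_stepup_oracle(pvals, q):
    """Hand-applied BH step-up rule: largest k with p_(k) <= k q / m."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_max = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


class TestBenjaminiHochberg:
    def test_worked_example(self):
        # hand-applied step-up rule: thresholds k*0.05/7 are 0.0071, 0.0143,
        # 0.0214, ... so the largest k with p_(k) below its threshold is 2
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.3])
        rejected = benjamini_hochberg(p) <= 0.05
        assert np.array_equal(rejected,
                              [True, True, False, False, False, False, False])
        assert np.array_equal(rejected, bh_stepup_oracle(p, 0.05))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_stepup_rule_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 60))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        for q in (0.01, 0.05, 0.2):
            assert np.array_equal(benjamini_hochberg(p) <= q,
                                  bh_stepup_oracle(p, q))

    def test_bulk_agreement_with_stepup(self):
        rng = np.random.default_rng(99)
        for _ in range(2000):
            p = rng.random(25)
            assert np.array_equal(benjamini_hochberg(p) <= 0.05,
                                  bh_stepup_oracle(p, 0.05))


class TestOutlierCalling:
    @staticmethod
    def make_residual_experiment(seed, n_null=300, n_out=0, shift=0.5,
                                 n_rep=12, sd=0.2):
        rng = np.random.default_rng(seed)
        deficits = rng.uniform(0.5, 4.0, n_null + n_out)
        pre = 2.27 + deficits
        true_adapt = 0.9 * deficits
        true_adapt[n_null:] += shift
        rows = []
        for i in range(n_null + n_out):
            for r in range(n_rep):
                rows.append((f"s{i:04d}", r, pre[i],
                             true_adapt[i] + rng.normal(0, sd)))
        df = pd.DataFrame(rows, columns=["strain_id", "replicate",
                                         "preadaptation_D", "A75"])
        planted = {f"s{i:04d}" for i in range(n_null, n_null + n_out)}
        return df, planted

    def test_zero_residuals_no_calls(self):
        pre = np.linspace(2.5, 6.5, 20)
        df = replicate_table(pre, 0.85 * pre - 1.9, n_rep=3)
        res = regress_adaptation(df)
        calls = res.call_outliers(0.05)
        assert not calls["significant"].any()

    def test_planted_outliers_recovered(self):
        df, planted = self.make_residual_experiment(seed=10, n_out=20)
        res = regress_adaptation(df)
        calls = res.call_outliers(0.05)
        hits = set(calls.loc[calls["significant"], "strain_id"])
        assert len(hits & planted) >= 18
        false_calls = hits - planted
        assert len(false_calls) <= 0.05 * 300 + 5  # expectation bound + slack
        assert (calls.loc[calls["strain_id"].isin(planted & hits),
                          "direction"] == "better").all()

    def test_type_I_fraction_controlled_over_seeds(self):
        fracs = []
        for seed in range(20):
            df, _ = self.make_residual_experiment(seed=seed, n_null=150,
                                                  n_out=0, n_rep=4)
            res = regress_adaptation(df)
            calls = res.call_outliers(0.05)
            fracs.append(calls["significant"].mean())
        assert np.mean(fracs) <= 0.05

    def test_single_replicate_strains_skipped(self):
        pre = np.linspace(2.5, 6.5, 10)
        df = replicate_table(pre, 0.5 * pre, n_rep=2, noise_sd=0.1)
        df = pd.concat([df, pd.DataFrame(
            [("lonely", 0, 3.0, 1.0)], columns=df.columns)], ignore_index=True)
        res = regress_adaptation(df)
        calls = res.call_outliers(0.05)
        assert "lonely" not in set(calls["strain_id"])


class TestRepeatability:
    def test_duplicate_replicates_give_r2_one(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 3, 50)
        rows = [(f"s{i}", r, 3.0, v) for i, v in enumerate(vals)
                for r in range(4)]
        df = pd.DataFrame(rows, columns=["strain_id", "replicate",
                                         "preadaptation_D", "A75"])
        assert replicate_repeatability(df) == pytest.approx(1.0, abs=1e-12)

    def test_attenuation_formula(self):
        # replicate = truth + noise: E[R^2] = Var(T) / (Var(T) + 2 Var(e)/n)
        rng = np.random.default_rng(3)
        n_strains, n_rep = 500, 8
        var_t, var_e = 1.0, 0.8
        truth = rng.normal(0, np.sqrt(var_t), n_strains)
        rows = []
        for i, t in enumerate(truth):
            for r in range(n_rep):
                rows.append((f"s{i:04d}", r, 3.0,
                             t + rng.normal(0, np.sqrt(var_e))))
        df = pd.DataFrame(rows, columns=["strain_id", "replicate",
                                         "preadaptation_D", "A75"])
        observed = np.mean([replicate_repeatability(df, seed=s)
                            for s in range(10)])
        expected = var_t / (var_t + 2 * var_e / (n_rep // 2))
        assert observed == pytest.approx(expected, abs=0.05)

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(5)
        rows = [(f"s{i:03d}", r, 3.0, rng.normal()) for i in range(300)
                for r in range(6)]
        df = pd.DataFrame(rows, columns=["strain_id", "replicate",
                                         "preadaptation_D", "A75"])
        assert replicate_repeatability(df) < 0.05


def fisher_two_sided_oracle(n, size_a, size_b, overlap):
    """Exhaustive enumeration over all size_b subsets of an n-universe."""
    from math import comb
    probs = {}
    for k in range(max(0, size_a + size_b - n), min(size_a, size_b) + 1):
        probs[k] = comb(size_a, k) * comb(n - size_a, size_b - k) / comb(n, size_b)
    p_obs = probs[overlap]
    return sum(p for p in probs.values() if p <= p_obs + 1e-12)


class TestOverlap:
    def test_worked_example_matches_enumeration(self):
        res = overlap_test({0, 1, 2, 3, 4}, {0, 1, 2, 3}, 20)
        assert res.observed == 4
        assert res.expected == pytest.approx(1.0)
        assert res.pvalue == pytest.approx(
            fisher_two_sided_oracle(20, 5, 4, 4), rel=1e-9)

    def test_enumeration_agreement_across_small_tables(self):
        for n, a, b in [(10, 4, 3), (15, 6, 5), (20, 5, 4), (25, 8, 5)]:
            universe = set(range(n))
            set_a = set(range(a))
            for overlap in range(max(0, a + b - n), min(a, b) + 1):
                set_b = set(range(overlap)) | set(range(a, a + b - overlap))
                res = overlap_test(set_a, set_b, n)
                assert res.observed == overlap
                assert res.pvalue == pytest.approx(
                    fisher_two_sided_oracle(n, a, b, overlap), rel=1e-9), \
                    (n, a, b, overlap)

    def test_disjoint_sets_with_small_expectation(self):
        res = overlap_test(set(range(5)), set(range(5, 9)), 1000)
        assert res.observed == 0
        assert res.pvalue > 0.9

    def test_degenerate_full_universe(self):
        u = set(range(12))
        res = overlap_test(u, u, 12)
        assert res.observed == 12
        assert res.expected == 12
        assert res.pvalue == pytest.approx(1.0)

    def test_oversized_set_rejected(self):
        with pytest.raises(ParameterError):
            overlap_test(set(range(30)), set(range(3)), 20)
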