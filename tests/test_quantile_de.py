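"""The two-level quantile DE machinery against independent oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nervede import ExpressionMatrix, TestConfig
from nervede.quantile_de import (bh_adjust, quantile_fold, rank_sum_test,
                                 ranksum_p_matrix, run_de, ssmd, upper_subset)


def enumeration_oracle(x, y) -> float:
    """Two-sided rank-sum p by exhaustive enumeration of group assignments.

    Uses mid-ranks of the pooled values, so it is valid with ties; this is a
    from-scratch implementation independent of the tested code path.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = len(pooled), len(x)
    obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(n), nx):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - nx * (n + 1) / 2.0) >= abs(obs - mu) - 1e-9:
            hits += 1
    return hits / total


def bh_oracle(p, alpha):
    """Brute-force step-up: largest k with p_(k) <= k*alpha/m; q-values by
    the min-over-tail definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    k_max = 0
    for k in range(1, m + 1):
        if ps[k - 1] <= k * alpha / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    q = np.empty(m)
    for i in range(m):
        q[order[i]] = min(min(m * ps[j] / (j + 1) for j in range(i, m)), 1.0)
    return q, reject


class TestRankSum:
    def test_separated_triples_exact_p(self):
        # all 20 assignments enumerable by hand: p = 2/20
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.integers(0, 4, size=nx).astype(float)  # forces ties
            y = rng.integers(0, 4, size=ny).astype(float)
            _, p = rank_sum_test(x, y)
            assert p == pytest.approx(enumeration_oracle(x, y), abs=1e-9)

    def test_asymptotic_matches_permutation_oracle(self):
        # large-sample path within 3 Monte-Carlo SEs of a 20 000-permutation
        # estimate of the two-sided rank-sum tail probability
        rng = np.random.default_rng(11)
        for case in range(3):
            x = rng.normal(0.3 * case, 1, size=30)
            y = rng.normal(0, 1, size=15)
            _, p = rank_sum_test(x, y)
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            mu = 30 * 46 / 2.0
            obs = abs(ranks[:30].sum() - mu)
            hits = 0
            B = 20_000
            for _ in range(B):
                perm = rng.permutation(45)
                hits += abs(ranks[perm[:30]].sum() - mu) >= obs - 1e-9
            phat = hits / B
            se = max(np.sqrt(phat * (1 - phat) / B), 1.0 / B)
            assert abs(p - phat) <= 3 * se + 5e-3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_vectorized_matches_scipy_including_ties(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 40))
        Y = rng.normal(size=(30, 25))
        X[:10] = np.round(X[:10])  # tie-heavy rows
        Y[:10] = np.round(Y[:10])
        X[10] = 0.0
        Y[10] = 0.0  # fully degenerate row
        p_vec = ranksum_p_matrix(X, Y)
        for i in range(30):
            if np.all(np.concatenate([X[i], Y[i]]) == X[i, 0]):
                assert p_vec[i] == 1.0
                continue
            ref = stats.mannwhitneyu(X[i], Y[i], alternative="two-sided",
                                     method="asymptotic").pvalue
            assert p_vec[i] == pytest.approx(ref, rel=1e-10)


class TestUpperSubset:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4], [3, 4]),       # even n: above the midpoint median
        ([5, 5, 5], [5, 5, 5]),       # everything ties the median
        ([1, 2, 3], [2, 3]),          # the median itself is included
    ])
    def test_values_at_or_above_own_median(self, values, expected):
        assert sorted(upper_subset(values).tolist()) == expected

    def test_size_at_least_half(self):
        rng = np.random.default_rng(0)
        for n in (3, 4, 7, 10, 25):
            v = rng.normal(size=n)
            assert upper_subset(v).size >= int(np.ceil(n / 2))


class TestBH:
    def test_textbook_stepup_counts(self):
        q, reject = bh_adjust([0.01, 0.02, 0.03, 0.5], alpha=0.05)
        assert int(reject.sum()) == 3

    def test_all_ones_reject_nothing(self):
        _, reject = bh_adjust([1.0] * 6, alpha=0.05)
        assert not reject.any()

    def test_single_test_reduces_to_raw_threshold(self):
        _, reject = bh_adjust([0.04], alpha=0.05)
        assert reject.all()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            m = rng.integers(1, 11)
            p = rng.random(m)
            q, reject = bh_adjust(p, alpha=0.05)
            q_ref, rej_ref = bh_oracle(p, 0.05)
            np.testing.assert_allclose(q, q_ref, atol=1e-12)
            assert (reject == rej_ref).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestQuantileFold:
    def test_median_fold_with_pseudoquantity(self):
        fold, direction = quantile_fold([3, 3, 3], [2, 2, 2], level=50)
        assert fold == pytest.approx(3.001 / 2.001, abs=1e-12)
        assert direction == "male_up"

    def test_equal_quantiles_tie(self):
        fold, direction = quantile_fold([1, 2, 3], [1, 2, 3], level=50)
        assert fold == 1.0 and direction == "tie"

    def test_zero_quantile_guarded(self):
        fold, direction = quantile_fold([0, 0, 0], [1, 1, 1], level=50)
        assert fold == pytest.approx(1.001 / 0.001, abs=1e-9)
        assert direction == "female_up"


class TestSsmd:
    def test_closed_form(self):
        f = np.array([2.0, 3.0, 4.0])   # mean 3, sd 1
        m = np.array([0.0, 1.0, 2.0])   # mean 1, sd 1
        assert ssmd(f, m) == pytest.approx(2.001 / np.sqrt(2.001), abs=1e-6)

    def test_constant_equal_groups_limit(self):
        v = [5.0, 5.0, 5.0]
        assert ssmd(v, v) == pytest.approx(0.001 / np.sqrt(0.001), abs=1e-12)

    def test_near_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(4)
        f, m = rng.normal(2, 1, 30), rng.normal(0, 1, 30)
        s1, s2 = ssmd(f, m), ssmd(m, f)
        # the swap flips the mean difference, leaving exactly 2*eps/denominator
        denom = np.sqrt(f.var(ddof=1) + m.var(ddof=1) + 0.001)
        assert s1 + s2 == pytest.approx(2 * 0.001 / denom, abs=1e-12)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            ssmd([1.0], [1.0, 2.0])


def _toy_cohort(seed=0, n_genes=60, nm=40, nf=20, effect_gene=0, fold=3.0):
    rng = np.random.default_rng(seed)
    vals = np.exp(rng.normal(1.0, 0.3, size=(n_genes, nm + nf)))
    vals[effect_gene, :nm] *= fold
    m = ExpressionMatrix([f"g{i}" for i in range(n_genes)],
                         [f"s{j}" for j in range(nm + nf)], vals)
    sex = pd.Series(["male"] * nm + ["female"] * nf, index=m.sample_ids)
    return m, sex


class TestRunDe:
    def test_injected_gene_called_with_correct_direction(self):
        m, sex = _toy_cohort()
        de = run_de(m, sex)
        assert de.loc["g0", "call"] == "male_50"
        assert de.loc["g0", "ssmd"] < 0  # female-minus-male orientation

    def test_invariant_to_gene_and_sample_order(self):
        m, sex = _toy_cohort(seed=2)
        de = run_de(m, sex)
        rng = np.random.default_rng(7)
        gperm = rng.permutation(m.n_genes)
        sperm = rng.permutation(m.n_samples)
        m2 = ExpressionMatrix([m.gene_ids[i] for i in gperm],
                              [m.sample_ids[j] for j in sperm],
                              m.values[np.ix_(gperm, sperm)])
        de2 = run_de(m2, sex)
        cols = ["p50", "p75", "q50", "q75", "fc50", "fc75", "ssmd"]
        a = de[cols].sort_index()
        b = de2[cols].sort_index()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)
        assert (de["call"].sort_index() == de2["call"].sort_index()).all()

    def test_single_sex_rejected(self):
        m, _ = _toy_cohort()
        sex = pd.Series(["male"] * m.n_samples, index=m.sample_ids)
        with pytest.raises(ValueError):
            run_de(m, sex)

    def test_level75_calls_exclude_level50_calls(self):
        m, sex = _toy_cohort(seed=3)
        de = run_de(m, sex)
        both = de["sig50"] & de["sig75"]
        assert (de.loc[both, "call"].isin(["male_50", "female_50"])).all()

    def test_detection_monotone_in_fold(self):
        # detection frequency of an injected median effect never decreases
        # as the fold grows
        freqs = []
        for fold in (1.25, 1.7, 2.5):
            hits = 0
            for seed in range(12):
                m, sex = _toy_cohort(seed=seed, fold=fold)
                de = run_de(m, sex)
                hits += bool(de.loc["g0", "sig50"])
            freqs.append(hits / 12)
        assert freqs[0] <= freqs[1] <= freqs[2]
        assert freqs[2] == 1.0

    def test_own_median_variant_runs(self):
        m, sex = _toy_cohort(seed=5)
        de = run_de(m, sex, TestConfig(upper_threshold="own"))
        assert np.isfinite(de["p75"]).all()

    def test_empty_upper_subset_scores_p_one(self):
        # gene expressed only in males: every female value sits below the
        # shared threshold, so the conditional test is undefined (p75 = 1)
        m, sex = _toy_cohort(seed=6)
        vals = m.values.copy()
        vals[1, 40:] = 0.0
        m2 = ExpressionMatrix(m.gene_ids, m.sample_ids, vals)
        de = run_de(m2, sex)
        assert de.loc["g1", "p75"] == 1.0
        assert de.loc["g1", "call"] == "male_50"
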