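import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom, kstest

from ori_panscan.stats import (
    fisher_enrichment,
    linear_fit,
    mann_whitney_u,
    pairwise_wilcoxon,
    pca,
    pearson,
)


def exact_mwu_p_less(x, y):
    """Enumerate all C(n1+n2, n1) group assignments of the pooled values.

    Null probability that U(x vs y) is <= the observed U, for the
    one-sided alternative 'x tends to be smaller than y'.
    """
    def u_stat(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    pooled = list(x) + list(y)
    n1 = len(x)
    observed = u_stat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if u_stat(xs, ys) <= observed + 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_small_sample_exact_example(self):
        report = mann_whitney_u([1, 2], [3, 4], alternative="less")
        assert report.method == "exact"
        assert report.p_value == pytest.approx(1 / 6)

    def test_identical_samples_two_sided_p_one(self):
        report = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert report.p_value == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration_exhaustively(self):
        # all tie-free datasets with n1 + n2 <= 10 up to rank relabelling:
        # every split of the ranks 1..N
        for N in range(4, 9):
            for n1 in range(2, N - 1):
                for idx in itertools.combinations(range(N), n1):
                    x = [float(i + 1) for i in idx]
                    y = [float(i + 1) for i in range(N) if i not in idx]
                    report = mann_whitney_u(x, y, alternative="less")
                    assert report.method == "exact"
                    assert report.p_value == pytest.approx(exact_mwu_p_less(x, y))

    def test_null_p_values_uniform(self, rng):
        ps = []
        for _ in range(300):
            x = rng.normal(size=200)
            y = rng.normal(size=200)
            ps.append(mann_whitney_u(x, y).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_ties_fall_back_to_normal_approximation(self):
        report = mann_whitney_u([1, 1, 2], [2, 3, 3])
        assert report.method == "normal_approx"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPearson:
    def test_perfect_linear(self):
        x = list(range(10))
        r, _ = pearson(x, [2 * v + 1 for v in x])
        assert r == pytest.approx(1.0)
        r, _ = pearson(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_bivariate_normal_recovery(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = 0.5 * x + math.sqrt(1 - 0.25) * rng.normal(size=n)
        r, p = pearson(x, y)
        assert 0.48 <= r <= 0.52
        assert p < 1e-10

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairwiseWilcoxon:
    def test_two_groups_reduce_to_single_test(self, rng):
        a = list(rng.normal(0, 1, 20))
        b = list(rng.normal(1, 1, 20))
        table = pairwise_wilcoxon({"a": a, "b": b})
        single = mann_whitney_u(a, b, alternative="two-sided")
        assert table.loc["a", "b"] == pytest.approx(single.p_value)

    def test_identical_groups_adjusted_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        table = pairwise_wilcoxon({"a": g, "b": g, "c": g})
        off_diag = table.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off_diag, 1.0)

    def test_adjusted_at_least_raw(self, rng):
        groups = {k: list(rng.normal(i, 1, 15)) for i, k in enumerate("abcd")}
        adj = pairwise_wilcoxon(groups, correction="bh")
        for a, b in itertools.combinations("abcd", 2):
            raw = mann_whitney_u(groups[a], groups[b], "two-sided").p_value
            assert adj.loc[a, b] >= raw - 1e-12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_wilcoxon({"a": [1.0], "b": []})


class TestFisherEnrichment:
    def test_closed_form_extreme_table(self):
        # all 5 list genes carry T, and only they do in a background of 100:
        # p = 1 / C(100, 5)
        genes = [f"g{i}" for i in range(5)]
        background = [f"g{i}" for i in range(100)]
        term_map = {g: {"T"} for g in genes}
        (res,) = fisher_enrichment(genes, background, term_map)
        assert res.p_value == pytest.approx(1 / math.comb(100, 5))

    def test_universal_term_p_one(self):
        background = [f"g{i}" for i in range(50)]
        term_map = {g: {"T"} for g in background}
        (res,) = fisher_enrichment(background[:10], background, term_map)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_tail_on_random_tables(self, rng):
        for _ in range(1000):
            N = int(rng.integers(10, 60))
            n = int(rng.integers(1, N))
            K = int(rng.integers(1, N + 1))
            background = [f"g{i}" for i in range(N)]
            gene_list = background[:n]
            with_term = rng.choice(N, size=K, replace=False)
            term_map = {f"g{i}": {"T"} for i in with_term}
            (res,) = fisher_enrichment(gene_list, background, term_map)
            k = res.k
            oracle = hypergeom.sf(k - 1, N, K, n)
            assert res.p_value == pytest.approx(float(oracle), rel=1e-9)

    def test_bh_adjustment_arithmetic(self):
        # step-up Benjamini-Hochberg recomputed directly from the raw p's
        background = [f"g{i}" for i in range(1000)]
        # three terms with increasing raw p via nested carrier sets
        term_map = {}
        for g in background[:100]:
            term_map.setdefault(g, set()).add("T1")
        for g in background[:300]:
            term_map.setdefault(g, set()).add("T2")
        for g in background[:600]:
            term_map.setdefault(g, set()).add("T3")
        results = fisher_enrichment(background[:50], background, term_map)
        raw = sorted(r.p_value for r in results)
        m = len(raw)
        expected = {}
        running_min = 1.0
        for rank in range(m, 0, -1):
            running_min = min(running_min, raw[rank - 1] * m / rank)
            expected[raw[rank - 1]] = running_min
        for r in results:
            assert r.fdr_adjusted_p == pytest.approx(expected[r.p_value])
            assert r.fdr_adjusted_p >= r.p_value
            assert r.fdr_adjusted_p <= min(1.0, r.p_value * m) + 1e-12  # <= Bonferroni

    def test_gene_outside_background_rejected(self):
        with pytest.raises(ValueError, match="alien"):
            fisher_enrichment(["alien"], ["g1"], {})


class TestLinearFit:
    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        slope, intercept, r = linear_fit(x, [2 * v - 1 for v in x])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(-1.0)
        assert r == pytest.approx(1.0)

    def test_r_squared_equals_explained_variance(self, rng):
        x = rng.normal(size=200)
        y = 1.5 * x + rng.normal(scale=0.8, size=200)
        slope, intercept, r = linear_fit(x, y)
        resid = y - (slope * x + intercept)
        ss_res = (resid**2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert r**2 == pytest.approx(1 - ss_res / ss_tot)

    def test_consistent_with_pearson(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        _, _, r_fit = linear_fit(x, y)
        r_p, _ = pearson(x, y)
        assert r_fit == pytest.approx(r_p)


class TestPca:
    def test_collinear_points_single_component(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([x, 2 * x])
        _, _, explained = pca(X, standardize=False)
        assert explained[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_balanced(self, rng):
        X = rng.normal(size=(5000, 2))
        _, _, explained = pca(X)
        assert 0.45 <= explained[0] <= 0.55
        assert explained[0] >= explained[1]

    def test_full_reconstruction(self, rng):
        X = rng.normal(size=(40, 5))
        scores, loadings, explained = pca(X)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(scores @ loadings, Xs, atol=1e-8)
        assert np.all(np.diff(explained) <= 1e-12)
        assert explained.sum() == pytest.approx(1.0)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(30, 4))
        _, loadings_a, _ = pca(X)
        _, loadings_b, _ = pca(X.copy())
        assert np.allclose(loadings_a, loadings_b)
        for row in loadings_a:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_column_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="0"):
            pca(X, standardize=True)
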