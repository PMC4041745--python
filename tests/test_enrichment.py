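import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pathcons import (
    Background,
    DEFAULT_PROFILES,
    GeneSet,
    MethodConfig,
    ValidationError,
    adjust_pvalues,
    binomial_tail,
    chisq_2x2,
    hypergeometric_tail,
    run_ora,
)
from pathcons.snp_annotation import GeneList


def enumeration_tail(k, K, n, N):
    """Independent oracle: count draws of n from N with >= k of the K marked."""
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for x in draw if x < K) >= k
    )
    return hits / math.comb(N, n)


class TestHypergeometricTail:
    def test_k_zero_covers_whole_support(self):
        assert hypergeometric_tail(0, 4, 3, 10) == 1.0

    def test_enumerated_small_cases(self):
        assert hypergeometric_tail(2, 4, 3, 10) == pytest.approx(1 / 3, rel=1e-12)
        assert hypergeometric_tail(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-12)
        # independent enumeration for the same instances
        assert enumeration_tail(2, 4, 3, 10) == pytest.approx(1 / 3, rel=1e-15)
        assert enumeration_tail(5, 5, 5, 20) == pytest.approx(1 / 15504, rel=1e-15)

    def test_bounds_validated(self):
        with pytest.raises(ValidationError):
            hypergeometric_tail(5, 4, 3, 10)

    def test_equals_one_sided_fisher(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(10, 500))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            table = [[k, n - k], [K - k, N - K - n + k]]
            if min(min(row) for row in table) < 0:
                continue
            fisher = stats.fisher_exact(table, alternative="greater").pvalue
            assert hypergeometric_tail(k, K, n, N) == pytest.approx(fisher, rel=1e-12)


class TestBinomialTail:
    def test_k_zero(self):
        assert binomial_tail(0, 10, 5, 100) == 1.0

    def test_half_probability_cube(self):
        assert binomial_tail(3, 50, 3, 100) == pytest.approx(0.125, rel=1e-12)

    def test_matches_direct_summation(self):
        n, K, N, k = 20, 10, 100, 5
        direct = sum(
            math.comb(n, i) * (K / N) ** i * (1 - K / N) ** (n - i) for i in range(k, n + 1)
        )
        assert binomial_tail(k, K, n, N) == pytest.approx(direct, rel=1e-12)


class TestChisq2x2:
    def test_expected_count_gives_one(self):
        # k exactly at its expectation n*K/N: no excess to score
        assert chisq_2x2(5, 50, 20, 200) == 1.0

    def test_shortcut_formula(self):
        # [[40,60],[10,90]]: X² = 200·(40·90−60·10)²/(100·100·50·150) = 24
        p = chisq_2x2(40, 50, 100, 200)
        assert p == pytest.approx(stats.chi2.sf(24.0, 1), rel=1e-10)
        # independent route: Pearson chi-square from scipy's contingency test
        expected = stats.chi2_contingency([[40, 60], [10, 90]], correction=False).pvalue
        assert p == pytest.approx(expected, rel=1e-10)

    def test_under_representation_scores_one(self):
        assert chisq_2x2(1, 50, 20, 200) == 1.0


class TestAdjustPvalues:
    def test_bh_step_up_flattens_linear_grid(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_definition(self):
        assert adjust_pvalues([0.01] + [0.5] * 4, "bonferroni")[0] == pytest.approx(0.05)

    def test_single_p_unchanged_by_bh(self):
        assert adjust_pvalues([0.3], "BH")[0] == pytest.approx(0.3)

    def test_empty_input(self):
        assert adjust_pvalues([], "BH").size == 0

    @staticmethod
    def _oracle(pvals, method):
        """Independently coded sorted-formula corrections."""
        p = np.asarray(pvals, float)
        m = p.size
        order = np.argsort(p, kind="stable")
        out = np.empty(m)
        if method == "bonferroni":
            return np.minimum(1.0, p * m)
        if method == "BH":
            q = p[order] * m / np.arange(1, m + 1)
            # enforce step-up monotonicity from the largest p downwards
            running = np.minimum.accumulate(q[::-1])[::-1]
            out[order] = np.minimum(1.0, running)
            return out
        if method == "holm":
            s = p[order] * (m - np.arange(m))
            out[order] = np.minimum(1.0, np.maximum.accumulate(s))
            return out
        raise AssertionError(method)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=200),
        st.sampled_from(["BH", "bonferroni", "holm"]),
    )
    def test_matches_independent_oracle(self, pvals, method):
        got = adjust_pvalues(pvals, method)
        assert got == pytest.approx(self._oracle(pvals, method), abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=50), st.randoms())
    def test_bh_invariant_to_permutation(self, pvals, rnd):
        base = adjust_pvalues(pvals, "BH")
        idx = list(range(len(pvals)))
        rnd.shuffle(idx)
        permuted = adjust_pvalues([pvals[i] for i in idx], "BH")
        assert permuted == pytest.approx([base[i] for i in idx], abs=1e-12)


def _collection():
    return [
        GeneSet("S1", "ten", "X", frozenset(f"g{i}" for i in range(10))),
        GeneSet("S2", "disjoint", "X", frozenset(f"h{i}" for i in range(5))),
    ]


def _background(n=100):
    return Background(frozenset(list(f"g{i}" for i in range(10)) + [f"b{i}" for i in range(n - 10)]))


class TestRunOra:
    def test_counts_and_raw_p(self):
        query = GeneList("q", tuple(f"g{i}" for i in range(6)) + tuple(f"b{i}" for i in range(14)))
        table = run_ora(query, _collection(), _background(), MethodConfig("m"))
        rec = {r.set_id: r for r in table.records}["S1"]
        assert (rec.k, rec.K, rec.n, rec.N) == (6, 10, 20, 100)
        assert rec.p_raw == pytest.approx(hypergeometric_tail(6, 10, 20, 100), rel=1e-12)
        assert rec.overlap_genes == tuple(sorted(f"g{i}" for i in range(6)))
        # S2 is outside the background universe entirely -> not tested
        assert table.m == 1

    def test_disjoint_query_never_enriched(self):
        query = GeneList("q", tuple(f"b{i}" for i in range(10)))
        table = run_ora(query, _collection(), _background(), MethodConfig("m"))
        assert table.enriched_ids() == set()

    def test_min_genes_vetoes_single_gene_overlap(self):
        bg = Background(frozenset(["g0"] + [f"b{i}" for i in range(999)]))
        coll = [GeneSet("S1", "one", "X", frozenset(["g0"]))]
        query = GeneList("q", ("g0", "b1"))
        table = run_ora(query, coll, bg, MethodConfig("m", correction="none", alpha=0.05))
        (rec,) = table.records
        assert rec.k == 1 and rec.p_adj < 0.05 and not rec.enriched

    def test_invariant_to_query_order_and_duplicates(self):
        genes = tuple(f"g{i}" for i in range(6)) + tuple(f"b{i}" for i in range(14))
        t1 = run_ora(GeneList("q", genes), _collection(), _background(), MethodConfig("m"))
        t2 = run_ora(GeneList("q", genes[::-1]), _collection(), _background(), MethodConfig("m"))
        assert t1.records == t2.records

    def test_empty_background_intersection_raises(self):
        query = GeneList("q", ("zzz",))
        with pytest.raises(ValidationError, match="background"):
            run_ora(query, _collection(), _background(), MethodConfig("m"))

    def test_stricter_alpha_enriches_subset(self):
        query = GeneList("q", tuple(f"g{i}" for i in range(6)) + tuple(f"b{i}" for i in range(14)))
        loose = MethodConfig("loose", "hypergeometric", "BH", 0.05)
        strict = MethodConfig("strict", "hypergeometric", "BH", 1e-6)
        t_loose = run_ora(query, _collection(), _background(), loose)
        t_strict = run_ora(query, _collection(), _background(), strict)
        assert t_strict.enriched_ids() <= t_loose.enriched_ids()

    def test_default_profiles_differ_only_in_stat_correction_alpha(self):
        assert set(DEFAULT_PROFILES) == {"default-0.05", "mid-0.01", "strict-1e4", "strict-1e6"}
        assert all(p.min_genes == 2 for p in DEFAULT_PROFILES.values())
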