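"""Hypergeometric tail, enrichment curves and set overlap reports."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

import talasso as tl


def tail_by_enumeration(n, p_obs, K_val, N):
    """Independent oracle: sum the PMF from p_obs upward via log-gamma
    binomial coefficients."""
    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    total = 0.0
    for j in range(p_obs, min(n, K_val) + 1):
        if n - j > N - K_val:
            continue
        total += np.exp(logC(K_val, j) + logC(N - K_val, n - j) - logC(N, n))
    return min(total, 1.0) if p_obs <= min(n, K_val) else 0.0


class TestHypergeomTail:
    def test_drawing_everything_is_certain(self):
        assert tl.hypergeom_tail(10, 4, 4, 10) == 1.0

    def test_zero_successes_is_certain(self):
        assert tl.hypergeom_tail(5, 0, 3, 20) == 1.0

    def test_worked_example_exact(self):
        """All 5 successes in 5 draws from 5/10: C(5,5)C(5,0)/C(10,5)=1/252."""
        assert tl.hypergeom_tail(5, 5, 5, 10) == pytest.approx(1 / 252,
                                                               rel=1e-12)

    def test_agrees_with_enumeration_on_grid(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            p_obs = int(rng.integers(0, n + 1))
            got = tl.hypergeom_tail(n, p_obs, K, N)
            ref = tail_by_enumeration(n, p_obs, K, N)
            assert got == pytest.approx(ref, rel=1e-12, abs=1e-300)

    def test_monotone_in_p_obs_and_n(self):
        N, K = 40, 12
        for n in (5, 15, 30):
            ps = [tl.hypergeom_tail(n, p, K, N) for p in range(min(n, K) + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
        for p_obs in (1, 3, 5):
            ts = [tl.hypergeom_tail(n, p_obs, K, N) for n in range(p_obs, N + 1)]
            assert all(a <= b + 1e-15 for a, b in zip(ts, ts[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            tl.hypergeom_tail(5, 6, 3, 10)
        with pytest.raises(ValueError):
            tl.hypergeom_tail(11, 2, 3, 10)


def ranking_frame(pairs):
    return pd.DataFrame({"mRNA_id": [g for g, _ in pairs],
                         "miRNA_id": [m for _, m in pairs]})


def toy_universe(n_genes=50, mirs=("m1", "m2")):
    return [(f"g{i}", m) for i in range(n_genes) for m in mirs]


class TestEnrichmentCurve:
    def test_perfect_ranking_minimum_at_k_val(self):
        """All validated pairs ranked first: p(K_val) = 1/C(N, K_val)."""
        uni = toy_universe(500, ("m1",))            # N = 500
        val = uni[:10]
        ranked = ranking_frame(val + uni[10:])
        curve = tl.enrichment_curve(
            ranked, tl.ValidatedSet.from_pairs(val),
            tl.InteractionMask.from_pairs(uni), restrict_universe=False)
        # N_E is cumulative and clamped
        assert (curve.table["N_E"].diff().fillna(1) >= 0).all()
        assert curve.N_T_at_min == 10
        expected = 1 / np.exp(gammaln(501) - gammaln(11) - gammaln(491))
        assert curve.p_min == pytest.approx(expected, rel=1e-9)
        assert curve.N_E_500 == 10

    def test_random_ranking_shows_no_enrichment(self):
        """Permuted rankings: the minimum tail probability rarely dips below
        1e-4 when there is nothing to find (100 seeded permutations)."""
        uni = toy_universe(500, ("m1", "m2"))       # N = 1000
        val = uni[:10]
        vs = tl.ValidatedSet.from_pairs(val)
        mask = tl.InteractionMask.from_pairs(uni)
        deep = 0
        for seed in range(1, 101):
            rng = np.random.default_rng(seed)
            perm = [uni[i] for i in rng.permutation(len(uni))]
            curve = tl.enrichment_curve(ranking_frame(perm), vs, mask,
                                        restrict_universe=False)
            if curve.p_min < 1e-4:
                deep += 1
        assert deep <= 5

    def test_short_ranking_clamps_top500_with_warning(self):
        uni = toy_universe(150, ("m1", "m2"))       # 300 pairs
        val = uni[:5]
        ranked = ranking_frame(val + uni[5:])
        with pytest.warns(UserWarning, match="only 300"):
            curve = tl.enrichment_curve(
                ranked, tl.ValidatedSet.from_pairs(val),
                tl.InteractionMask.from_pairs(uni), restrict_universe=False)
        assert curve.N_E_500 == 5

    def test_restriction_shrinks_universe_to_genes_with_validated(self):
        uni = [("gA", "m1"), ("gA", "m2"), ("gB", "m1"), ("gC", "m2")]
        val = [("gA", "m1")]
        curve = tl.enrichment_curve(
            ranking_frame(uni), tl.ValidatedSet.from_pairs(val),
            tl.InteractionMask.from_pairs(uni))
        assert curve.N == 2 and curve.K_val == 1    # only gA's pairs remain

    def test_moving_a_validated_pair_down_weakens_the_curve(self):
        uni = toy_universe(100, ("m1",))
        val = uni[:5]
        vs = tl.ValidatedSet.from_pairs(val)
        mask = tl.InteractionMask.from_pairs(uni)
        top = tl.enrichment_curve(ranking_frame(val + uni[5:]), vs, mask,
                                  restrict_universe=False)
        swapped = val[:4] + [uni[60]] + uni[5:60] + [val[4]] + uni[61:]
        low = tl.enrichment_curve(ranking_frame(swapped), vs, mask,
                                  restrict_universe=False)
        assert low.p_min > top.p_min

    def test_no_validated_overlap_is_an_error(self):
        uni = toy_universe(5, ("m1",))
        with pytest.raises(ValueError, match="no validated"):
            tl.enrichment_curve(ranking_frame(uni),
                                tl.ValidatedSet.from_pairs([("zz", "m9")]),
                                tl.InteractionMask.from_pairs(uni))

    def test_stride_evaluates_multiples_only(self):
        uni = toy_universe(50, ("m1",))
        curve = tl.enrichment_curve(
            ranking_frame(uni), tl.ValidatedSet.from_pairs(uni[:3]),
            tl.InteractionMask.from_pairs(uni), restrict_universe=False,
            stride=10)
        assert list(curve.table["n"]) == [10, 20, 30, 40, 50]


class TestSetReport:
    def test_pairwise_union_counts(self):
        A = {("g1", "m"), ("g2", "m")}
        B = {("g2", "m"), ("g3", "m")}
        rep = tl.set_report({"A": A, "B": B}).set_index("sets")["size"]
        assert rep["A"] == 2 and rep["A & B"] == 1 and rep["A | B"] == 3

    def test_disjoint_sets(self):
        sets = {"a": {(f"x{i}", "m") for i in range(2)},
                "b": {(f"y{i}", "m") for i in range(3)},
                "c": {(f"z{i}", "m") for i in range(4)}}
        rep = tl.set_report(sets).set_index("sets")["size"]
        assert rep["a | b | c"] == 9
        assert rep["a & b & c"] == 0 and rep["a & b"] == 0

    def test_validated_union_intersected_with_putative_fixture(self):
        """20-pair fixture: |(A u B) & P| matches hand enumeration."""
        P = [(f"g{i}", "m1") for i in range(20)]
        A = [(f"g{i}", "m1") for i in range(0, 8)]          # 8 in P
        B = [(f"g{i}", "m1") for i in range(5, 12)] + [("h1", "m2")]
        union_AB = set(A) | set(B)
        assert len(union_AB & set(P)) == 12                 # g0..g11
        rep = tl.set_report({"AuB": union_AB, "P": set(P)})
        assert rep.set_index("sets")["size"]["AuB & P"] == 12
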