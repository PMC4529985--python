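"""Enrichment ratio, exact hypergeometric tails, the mHG scan, and BH adjustment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from proteoscreen import (
    bh_adjust,
    enrich_all,
    enrichment_ratio,
    hypergeom_tail,
    mhg_corrected_p,
    min_hypergeom,
    ranked_gene_list,
)


def tail_oracle(N, B, n, b):
    """Independent summation over the support, in exact rationals."""
    return float(
        sum(Fraction(comb(B, k) * comb(N - B, n - k), comb(N, n)) for k in range(b, min(n, B) + 1))
    )


class TestEnrichmentRatio:
    @pytest.mark.parametrize(
        "N,B,n,b,expected",
        [
            (33, 11, 8, 8, 3.00),
            (33, 3, 3, 3, 11.00),
            (33, 16, 20, 15, 1.55),
            (33, 10, 8, 7, 2.89),
            (33, 14, 8, 8, 2.36),
        ],
    )
    def test_reference_values(self, N, B, n, b, expected):
        assert round(enrichment_ratio(N, B, n, b), 2) == expected

    def test_full_list_identity_and_empty_term(self):
        assert enrichment_ratio(20, 7, 20, 7) == pytest.approx(1.0)
        assert np.isnan(enrichment_ratio(20, 0, 5, 0))

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            enrichment_ratio(10, 3, 0, 0)
        with pytest.raises(ValueError):
            enrichment_ratio(10, 3, 5, 4)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_rational_identity(self, data):
        N = data.draw(st.integers(2, 60))
        B = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        b = data.draw(st.integers(0, min(n, B)))
        # (b/n)/(B/N) * (B/N) * n == b exactly, up to float rounding.
        assert enrichment_ratio(N, B, n, b) * (B / N) * n == pytest.approx(b, abs=1e-9)


class TestHypergeomTail:
    def test_certain_event(self):
        assert hypergeom_tail(33, 3, 3, 0) == 1.0

    def test_exact_small_case(self):
        assert hypergeom_tail(33, 3, 3, 3) == pytest.approx(1 / comb(33, 3), rel=1e-12)

    def test_matches_summation_oracle(self):
        assert hypergeom_tail(33, 16, 20, 15) == pytest.approx(tail_oracle(33, 16, 20, 15), rel=1e-12)

    @settings(deadline=None, max_examples=120, derandomize=True)
    @given(st.data())
    def test_matches_scipy_and_monotone_in_b(self, data):
        N = data.draw(st.integers(2, 40))
        B = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        b = data.draw(st.integers(0, min(n, B)))
        ours = hypergeom_tail(N, B, n, b)
        assert ours == pytest.approx(float(hypergeom.sf(b - 1, N, B, n)), rel=1e-9, abs=1e-15)
        if b < min(n, B):
            assert hypergeom_tail(N, B, n, b + 1) <= ours + 1e-15


class TestMinHypergeom:
    def test_members_on_top(self):
        n, b, p = min_hypergeom([1, 1, 1, 0, 0, 0, 0])
        assert (n, b) == (3, 3)
        assert p == pytest.approx(1 / comb(7, 3))

    def test_all_zero_flags(self):
        n, b, p = min_hypergeom([0, 0, 0, 0])
        assert p == 1.0 and b == 0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            min_hypergeom([])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(flags=st.lists(st.booleans(), min_size=1, max_size=40))
    def test_matches_exhaustive_scan(self, flags):
        flags = np.array(flags, dtype=bool)
        N, B = flags.size, int(flags.sum())
        scan = [
            (n, int(flags[:n].sum()), float(hypergeom.sf(int(flags[:n].sum()) - 1, N, B, n)))
            for n in range(1, N + 1)
        ]
        best = min(scan, key=lambda t: (t[2], t[0]))
        n_star, b_star, p_min = min_hypergeom(flags)
        assert p_min == pytest.approx(best[2], rel=1e-9, abs=1e-15)
        assert (n_star, b_star) == (best[0], best[1])
        # Minimum property: no fixed prefix beats the scan.
        assert all(p_min <= p + 1e-12 for _, _, p in scan)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(flags=st.lists(st.booleans(), min_size=2, max_size=18))
    def test_corrected_p_dominates_minimum_tail(self, flags):
        _, _, p_min = min_hypergeom(flags)
        p_corr = mhg_corrected_p(flags)
        assert p_min - 1e-12 <= p_corr <= 1.0

    def test_corrected_p_by_enumeration(self):
        # N=5, B=2: enumerate all C(5,2)=10 rankings and compare the exact
        # null distribution of the minimum tail with the DP correction.
        from itertools import combinations

        flags = [1, 1, 0, 0, 0]
        _, _, p_obs = min_hypergeom(flags)
        count = 0
        for pos in combinations(range(5), 2):
            f = np.zeros(5, dtype=bool)
            f[list(pos)] = True
            if min_hypergeom(f)[2] <= p_obs + 1e-12:
                count += 1
        assert mhg_corrected_p(flags) == pytest.approx(count / 10)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(bh_adjust([0.005, 0.04, 0.8]), [0.015, 0.06, 0.8])
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominates_p_and_permutation_equivariant(self, ps):
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-12).all() and (q <= 1 + 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = bh_adjust(np.asarray(ps)[perm])
        np.testing.assert_allclose(q_perm, q[perm])


class TestEnrichAll:
    def test_worked_example_terms(self, worked_example):
        _, _, _, net, annotations, names = worked_example
        scores = {p: net.fractional_score("FGA", p) for p in net.graph.neighbors("FGA")
                  if net.fractional_score("FGA", p) >= 0.9}
        ranked = ranked_gene_list("FGA", scores)
        assert ranked[0] == "FGA" and len(ranked) == 33
        out = enrich_all(ranked, annotations, names=names).set_index("term_id")
        assert len(out) == 9
        assert round(out.loc["GO:0030168", "enrichment"], 2) == 3.00
        assert (out.loc["GO:0030168", "n"], out.loc["GO:0030168", "b"]) == (8, 8)
        assert out.loc["GO:0051592", "p_value"] == pytest.approx(1 / comb(33, 3), rel=1e-9)
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()
        assert list(out["p_value"]) == sorted(out["p_value"])

    def test_disjoint_annotations_empty_result(self):
        out = enrich_all(["a", "b", "c"], {"T1": {"x", "y"}})
        assert out.empty

    def test_planted_term_attains_smallest_p(self):
        ranked = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(4)
        annotations = {
            f"T{i}": set(rng.choice(ranked, 6, replace=False)) for i in range(10)
        }
        annotations["PLANTED"] = set(ranked[:6])
        out = enrich_all(ranked, annotations, alpha=1.1)
        assert out.iloc[0]["term_id"] == "PLANTED"

    def test_duplicate_ranked_genes_rejected(self):
        with pytest.raises(ValueError):
            ranked_gene_list("g", {"g": 0.95})
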