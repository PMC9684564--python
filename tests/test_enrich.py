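"""Fisher's-exact overrepresentation against exact-enumeration oracles."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from baitcall.enrich import (
    Correction,
    enrich_all,
    fisher_overrepresentation,
    top_terms,
)
from baitcall.io import AnnotationMap, AnnotationTerm, GoCategory
from oracles import hypergeom_upper_tail


def make_annotation(term_members: dict[str, set[str]], category=GoCategory.OTHER):
    return AnnotationMap(
        terms={
            tid: AnnotationTerm(tid, f"name {tid}", category, frozenset(members))
            for tid, members in term_members.items()
        }
    )


class TestFisher:
    def test_all_five_query_genes_in_a_five_member_term(self):
        # choosing 5 of 10 and hitting all 5 term members: 1 / C(10,5)
        p = fisher_overrepresentation(k=5, n=5, K=5, N=10)
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_term_covering_whole_background_forces_p_one(self):
        assert fisher_overrepresentation(k=3, n=3, K=10, N=10) == 1.0

    def test_zero_hits_forces_p_one(self):
        assert fisher_overrepresentation(k=0, n=5, K=5, N=20) == 1.0

    @pytest.mark.parametrize(
        "k,n,K,N", [(-1, 5, 5, 10), (6, 5, 5, 10), (2, 5, 1, 10), (2, 11, 5, 10)]
    )
    def test_violated_bounds_rejected(self, k, n, K, N):
        with pytest.raises(ValueError):
            fisher_overrepresentation(k, n, K, N)

    def test_matches_exact_enumeration_for_all_small_backgrounds(self):
        # exhaustive sweep: every admissible (N, K, n, k) with N <= 40
        for N in range(1, 41):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(n, K) + 1):
                        want = hypergeom_upper_tail(k, n, K, N)
                        got = fisher_overrepresentation(k, n, K, N)
                        assert got == pytest.approx(float(want), rel=1e-9, abs=1e-12), (
                            k, n, K, N,
                        )

    def test_adding_a_term_member_to_the_query_never_raises_p(self):
        for N, K in [(30, 8), (40, 15)]:
            for n in range(0, N - 1):
                for k in range(0, min(n, K - 1) + 1):
                    p_before = fisher_overrepresentation(k, n, K, N)
                    p_after = fisher_overrepresentation(k + 1, n + 1, K, N)
                    assert p_after <= p_before + 1e-12


class TestEnrichAll:
    def test_query_matching_one_of_two_disjoint_terms_ranks_it_first(self):
        term_a = {f"a{i}" for i in range(5)}
        term_b = {f"b{i}" for i in range(5)}
        annotation = make_annotation({"T:A": term_a, "T:B": term_b})
        results = enrich_all(term_a, annotation, term_a | term_b, correction="none")
        by_id = {r.term_id: r for r in results}
        # exact: all 5 of 5 drawn from a 5-member term in a 10-gene background
        assert by_id["T:A"].p_value == pytest.approx(1 / 252, rel=1e-12)
        assert by_id["T:A"].p_value < by_id["T:B"].p_value
        assert by_id["T:A"].k == 5 and by_id["T:A"].K == 5 and by_id["T:A"].N == 10
        assert by_id["T:A"].fold_enrichment == pytest.approx(2.0)
        assert top_terms(results, n=1)[0].term_id == "T:A"

    def test_correction_none_reproduces_raw_p(self):
        annotation = make_annotation({"T:A": {"a", "b"}, "T:B": {"c"}})
        results = enrich_all({"a"}, annotation, {"a", "b", "c"}, correction="none")
        assert all(r.fdr == r.p_value for r in results)

    def test_query_disjoint_from_all_terms_gives_p_one(self):
        annotation = make_annotation({"T:A": {"a"}, "T:B": {"b"}})
        results = enrich_all({"x"}, annotation, {"a", "b", "x"}, correction="none")
        assert all(r.p_value == 1.0 for r in results)

    def test_query_genes_outside_background_dropped(self):
        annotation = make_annotation({"T:A": {"a", "b"}})
        results = enrich_all(
            {"a", "not_in_bg"}, annotation, {"a", "b", "c"}, correction="none"
        )
        assert results[0].n == 1  # effective query size after restriction

    def test_alias_map_translates_into_annotation_namespace(self):
        annotation = make_annotation({"T:A": {"RAN", "KPNB1"}})
        results = enrich_all(
            {"P62826"},
            annotation,
            {"P62826", "Q14974", "x"},
            correction="none",
            aliases={"P62826": "RAN", "Q14974": "KPNB1"},
        )
        assert results[0].k == 1 and results[0].K == 2

    def test_empty_effective_query_rejected(self):
        annotation = make_annotation({"T:A": {"a"}})
        with pytest.raises(ValueError):
            enrich_all({"zzz"}, annotation, {"a", "b"})

    def test_bh_fdr_non_decreasing_in_p_within_category(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(40)]
        terms = {
            f"T:{j}": set(rng.choice(universe, size=8, replace=False))
            for j in range(12)
        }
        annotation = make_annotation(terms, category=GoCategory.BIOLOGICAL_PROCESS)
        query = set(rng.choice(universe, size=10, replace=False))
        results = enrich_all(query, annotation, set(universe), correction=Correction.BH)
        ordered = sorted(results, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))
        assert all(r.fdr >= r.p_value - 1e-12 for r in results)

    def test_correction_is_per_category(self):
        # a lone term in its category is uncorrected under Bonferroni
        annotation = AnnotationMap(
            terms={
                "T:bp": AnnotationTerm(
                    "T:bp", "x", GoCategory.BIOLOGICAL_PROCESS, frozenset({"a", "b"})
                ),
                "T:mf1": AnnotationTerm(
                    "T:mf1", "y", GoCategory.MOLECULAR_FUNCTION, frozenset({"a", "c"})
                ),
                "T:mf2": AnnotationTerm(
                    "T:mf2", "z", GoCategory.MOLECULAR_FUNCTION, frozenset({"b", "c"})
                ),
            }
        )
        results = enrich_all(
            {"a"}, annotation, {"a", "b", "c"}, correction=Correction.BONFERRONI
        )
        by_id = {r.term_id: r for r in results}
        assert by_id["T:bp"].fdr == pytest.approx(by_id["T:bp"].p_value)
        assert by_id["T:mf1"].fdr == pytest.approx(
            min(1.0, 2 * by_id["T:mf1"].p_value)
        )

    def test_permutation_p_values_are_conservative(self):
        # random queries from the background: P(p <= alpha) <= alpha (+MC slack)
        rng = np.random.default_rng(11)
        universe = [f"g{i}" for i in range(50)]
        term = set(universe[:10])
        n_draws, n_query = 2000, 10
        pvals = []
        for _ in range(n_draws):
            query = set(rng.choice(universe, size=n_query, replace=False))
            k = len(query & term)
            pvals.append(fisher_overrepresentation(k, n_query, 10, 50))
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.1, 0.25):
            frac = float(np.mean(pvals <= alpha))
            slack = 3 * np.sqrt(alpha * (1 - alpha) / n_draws)
            assert frac <= alpha + slack


class TestTopTerms:
    def _results(self, n_terms, category=GoCategory.BIOLOGICAL_PROCESS):
        universe = {f"g{i}" for i in range(30)}
        annotation = make_annotation(
            {f"T:{j:02d}": {f"g{j}", f"g{j + 1}"} for j in range(n_terms)},
            category=category,
        )
        return enrich_all({"g0", "g1"}, annotation, universe, correction="none")

    def test_top_ten_of_twelve(self):
        assert len(top_terms(self._results(12), n=10)) == 10

    def test_fewer_than_requested_returned_as_is(self):
        assert len(top_terms(self._results(8), n=10)) == 8

    def test_ties_broken_by_term_id(self):
        results = self._results(12)
        ranked = top_terms(results, n=12)
        for a, b in zip(ranked, ranked[1:]):
            assert (a.p_value, a.term_id) <= (b.p_value, b.term_id)

    def test_category_filter(self):
        results = self._results(5, category=GoCategory.MOLECULAR_FUNCTION)
        assert top_terms(results, n=10, category=GoCategory.BIOLOGICAL_PROCESS) == []
        assert len(top_terms(results, n=10, category=GoCategory.MOLECULAR_FUNCTION)) == 5
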