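"""Ontology-aware search: subsumption retrieval, conditions, inference,
autocomplete, and the syntactic baseline it improves on."""

import pytest

from ontoprime import (
    AutocompleteIndex,
    ConfigurationError,
    Ontology,
    OntologyTerm,
    PrimeAssignment,
    QueryCondition,
    SearchEngine,
    UnknownProteinError,
    UnknownTermError,
)
from ontoprime.store import InteractionStore

from conftest import (
    engine_for,
    oracle_descendants,
    oracle_inferred_pairs,
    oracle_protein_search,
)


@pytest.fixture
def go_like():
    """A molecular-function-style fragment: binding > nucleotide binding >
    ATP/GTP binding, plus an unrelated sibling branch."""
    o = Ontology(
        [
            OntologyTerm("MF:root", name="molecular function"),
            OntologyTerm("MF:bind", name="binding", parents=(("MF:root", "is_a"),)),
            OntologyTerm(
                "MF:nb", name="nucleotide binding",
                synonyms=("nt binding",), parents=(("MF:bind", "is_a"),),
            ),
            OntologyTerm("MF:atp", name="ATP binding", parents=(("MF:nb", "is_a"),)),
            OntologyTerm("MF:gtp", name="GTP binding", parents=(("MF:nb", "is_a"),)),
            OntologyTerm("MF:dna", name="DNA binding", parents=(("MF:bind", "is_a"),)),
            OntologyTerm("MF:cat", name="catalytic activity",
                         parents=(("MF:root", "is_a"),)),
        ]
    )
    store = InteractionStore()
    store.add_protein("X").annotations.add("MF:atp")
    store.add_protein("Y").annotations.add("MF:cat")
    store.add_protein("Z").annotations.add("MF:nb")
    store.add_protein("W").annotations.add("MF:gtp")
    for pair in [("X", "Y"), ("X", "Z"), ("X", "W"), ("Y", "W")]:
        store.add_interaction(*pair)
    pa = PrimeAssignment.for_ontology(o)
    return SearchEngine(o, pa, store)


class TestFindProteinsByTerm:
    def test_ancestor_query_reaches_descendant_annotation(self, go_like):
        """'nucleotide binding' retrieves the protein annotated only with the
        more specific 'ATP binding' — the core ontology-aware behavior."""
        assert go_like.find_proteins_by_term("MF:nb") == {"X", "Z", "W"}

    def test_unannotated_leaf_yields_empty_set(self, go_like):
        assert go_like.find_proteins_by_term("MF:dna") == set()

    def test_root_query_reaches_every_annotated_protein(self, go_like):
        assert go_like.find_proteins_by_term("MF:root") == {"X", "Y", "Z", "W"}

    def test_unknown_term_rejected(self, go_like):
        with pytest.raises(UnknownTermError):
            go_like.find_proteins_by_term("MF:nope")

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_matches_descendant_expansion_oracle(self, seed):
        engine = engine_for(seed, n_terms=80, max_parents=3, n_proteins=40)
        for term in engine.ontology.terms:
            assert engine.find_proteins_by_term(term) == oracle_protein_search(
                engine, term
            )


class TestKeywordBaseline:
    def test_misses_descendant_annotation(self, go_like):
        assert go_like.keyword_search_baseline("MF:nb") == {"Z"}

    def test_exact_annotation_returned(self, go_like):
        assert go_like.keyword_search_baseline("MF:atp") == {"X"}

    @pytest.mark.parametrize("seed", [41, 42])
    def test_baseline_subset_of_ontology_search(self, seed):
        engine = engine_for(seed, n_terms=70, n_proteins=30)
        for term in engine.ontology.terms:
            assert engine.keyword_search_baseline(term) <= engine.find_proteins_by_term(term)


class TestFindPartners:
    def test_all_partners_without_condition(self, go_like):
        result = go_like.find_partners("X")
        assert [ia.pair for ia in result.interactions] == [
            ("W", "X"), ("X", "Y"), ("X", "Z"),
        ]

    def test_condition_matched_via_descendant_kept_baseline_drops(self, go_like):
        cond = QueryCondition(("MF:nb",), target="partner")
        result = go_like.find_partners("Y", cond)
        partners = {ia.a if ia.b == "Y" else ia.b for ia in result.interactions}
        assert partners == {"X", "W"}  # ATP/GTP binding satisfy 'nucleotide binding'
        # the syntactic comparator finds neither partner
        assert go_like.keyword_search_baseline("MF:nb") & partners == set()
        # the explanation names the satisfying annotation
        assert result.matched_proteins["X"]["MF:nb"] == {"MF:atp"}

    def test_two_term_condition_is_intersection(self, go_like):
        both = go_like.find_partners("Y", QueryCondition(("MF:nb", "MF:bind")))
        single = [
            go_like.find_partners("Y", QueryCondition((t,)))
            for t in ("MF:nb", "MF:bind")
        ]
        expected = set(single[0].pairs) & set(single[1].pairs)
        assert set(both.pairs) == expected

    def test_unknown_protein(self, go_like):
        with pytest.raises(UnknownProteinError):
            go_like.find_partners("nobody")


class TestMultiConditionSearch:
    def test_single_term_degenerate_matches_term_filter(self, go_like):
        result = go_like.multi_condition_search(QueryCondition(("MF:nb",)))
        qualifying = go_like.find_proteins_by_term("MF:nb")
        expected = [
            ia.pair
            for ia in go_like.store.interactions
            if set(ia.pair) & qualifying
        ]
        assert result.pairs == sorted(expected)

    def test_conjunction_equals_intersection_of_singles(self):
        engine = engine_for(51, n_terms=40, n_proteins=40, n_interactions=80,
                            n_namespaces=2)
        terms = sorted(engine.ontology.terms)[:6]
        for t1 in terms:
            for t2 in terms:
                both = engine.multi_condition_search(QueryCondition((t1, t2)))
                s1 = engine.multi_condition_search(QueryCondition((t1,)))
                s2 = engine.multi_condition_search(QueryCondition((t2,)))
                assert set(both.pairs) == set(s1.pairs) & set(s2.pairs)

    def test_cross_namespace_roots(self):
        engine = engine_for(52, n_terms=30, n_namespaces=2, n_proteins=25,
                            n_interactions=50)
        roots = sorted(engine.ontology.roots)
        assert len(roots) == 2
        result = engine.multi_condition_search(QueryCondition(tuple(roots)))

        # oracle: direct predicate evaluation — each root namespace must be
        # covered by the annotation closure of at least one endpoint
        def covers(pid):
            cover = set()
            for a in engine.store.proteins[pid].annotations:
                cover |= {a} | set(engine.ontology.ancestors(a))
            return cover

        expected = [
            ia.pair
            for ia in engine.store.interactions
            if all(r in covers(ia.a) | covers(ia.b) for r in roots)
        ]
        assert result.pairs == sorted(expected)

        # on a fixed side the conjunction is the strict same-protein one
        strict = engine.multi_condition_search(QueryCondition(tuple(roots), "query"))
        expected_strict = [
            ia.pair
            for ia in engine.store.interactions
            if set(roots) <= covers(ia.a)
        ]
        assert strict.pairs == sorted(expected_strict)

    def test_disjoint_siblings_empty_on_fixed_side(self, go_like):
        """No protein is annotated under both sibling branches, so the
        same-protein conjunction is empty on either fixed side; the relaxed
        either-endpoint target may still pair an ATP-binder with a catalyst."""
        for target in ("query", "partner"):
            result = go_like.multi_condition_search(
                QueryCondition(("MF:atp", "MF:cat"), target)
            )
            assert result.interactions == []

    def test_interaction_counted_once_when_both_endpoints_qualify(self, go_like):
        result = go_like.multi_condition_search(QueryCondition(("MF:root",)))
        assert len(result.pairs) == len(set(result.pairs)) == 4


class TestInference:
    def test_worked_example_pair_inferred(self, worked):
        engine = SearchEngine(Ontology([]), PrimeAssignment([], skip=4), worked.store)
        inferred = engine.infer_interactions()
        assert [ia.pair for ia in inferred] == [("ProteinA", "ProteinB")]
        assert inferred[0].source == "ddi:domainA--domainB"

    def test_no_ddis_loaded_empty(self):
        store = InteractionStore()
        store.add_protein("A").domains.add("d1")
        engine = SearchEngine(Ontology([]), PrimeAssignment([]), store)
        assert engine.infer_interactions() == []

    def test_missing_domain_tables_rejected(self):
        store = InteractionStore()
        store.add_protein("A")
        engine = SearchEngine(Ontology([]), PrimeAssignment([]), store)
        with pytest.raises(ConfigurationError):
            engine.infer_interactions()

    @pytest.mark.parametrize("seed", [61, 62, 63])
    def test_matches_membership_oracle(self, seed):
        engine = engine_for(seed, n_proteins=12, n_domains=6, n_ddis=3,
                            domains_per_protein=(0, 3))
        inferred = {ia.pair for ia in engine.infer_interactions()}
        assert inferred == oracle_inferred_pairs(engine.store)


class TestAutocomplete:
    def test_prefix_expands_to_full_term(self, go_like):
        index = AutocompleteIndex(go_like.ontology)
        hits = index.complete("nucleotide b")
        assert ("MF:nb", "nucleotide binding") in hits

    def test_case_insensitive(self, go_like):
        index = AutocompleteIndex(go_like.ontology)
        assert index.complete("atp") == [("MF:atp", "ATP binding")]

    def test_no_match_empty(self, go_like):
        assert AutocompleteIndex(go_like.ontology).complete("zz") == []

    def test_synonym_only_match_returns_term(self, go_like):
        hits = AutocompleteIndex(go_like.ontology).complete("nt bind")
        assert hits == [("MF:nb", "nt binding")]

    def test_empty_prefix_returns_nothing(self, go_like):
        assert AutocompleteIndex(go_like.ontology).complete("") == []

    def test_limit_and_ordering(self):
        engine = engine_for(71, n_terms=40)
        index = AutocompleteIndex(engine.ontology)
        hits = index.complete("term", limit=5)
        assert len(hits) == 5
        assert hits == sorted(hits, key=lambda h: h[1].lower())


class TestInvariants:
    @pytest.mark.parametrize("seed", [81, 82])
    def test_monotonicity_descendant_subset(self, seed):
        """If q2 descends from q1, every q2 result is a q1 result — the
        'ATP binding' ⊂ 'nucleotide binding' phenomenon, universally."""
        engine = engine_for(seed, n_terms=60, n_proteins=30, n_interactions=60)
        o = engine.ontology
        for q2 in o.terms:
            r2 = engine.find_proteins_by_term(q2)
            for q1 in o.ancestors(q2):
                assert r2 <= engine.find_proteins_by_term(q1)

    def test_root_query_covers_namespace(self):
        engine = engine_for(83, n_terms=40, n_proteins=20, n_interactions=40)
        (root,) = engine.ontology.roots
        annotated = {p for p, ap in engine.store.proteins.items() if ap.annotations}
        assert engine.find_proteins_by_term(root) == annotated
        result = engine.multi_condition_search(QueryCondition((root,)))
        expected = [
            ia.pair for ia in engine.store.interactions if set(ia.pair) & annotated
        ]
        assert result.pairs == sorted(expected)

    def test_queries_are_pure(self, go_like):
        cond = QueryCondition(("MF:nb",))
        first = go_like.multi_condition_search(cond)
        second = go_like.multi_condition_search(cond)
        assert first.pairs == second.pairs
        assert go_like.find_partners("X").pairs == go_like.find_partners("X").pairs
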