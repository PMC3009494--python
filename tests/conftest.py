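"""Shared fixtures and independent oracles.

The oracles deliberately avoid the code paths they check: ancestor sets come
from networkx reachability on the raw edge list, search expectations from
explicit descendant expansion, and inference expectations from a brute-force
domain-membership double loop.
"""

import networkx as nx
import pytest

from ontoprime import Ontology, OntologyTerm, PrimeAssignment, SearchEngine
from ontoprime.fixtures import FixtureSpec, build_store, generate, make_paper_tables

FOUR_TERM_OBO = """\
format-version: 1.2
ontology: four-term-demo

[Term]
id: Term1
name: term one

[Term]
id: Term2
name: term two
is_a: Term1

[Term]
id: Term3
name: term three
relationship: part_of Term2

[Term]
id: Term4
name: term four
is_a: Term2
"""


@pytest.fixture
def worked():
    return make_paper_tables()


@pytest.fixture
def four_term_obo(tmp_path):
    path = tmp_path / "four_term.obo"
    path.write_text(FOUR_TERM_OBO)
    return str(path)


@pytest.fixture
def diamond():
    """D is_a B, D is_a C, B is_a A, C is_a A: the shared-ancestor case."""
    return Ontology(
        [
            OntologyTerm("A"),
            OntologyTerm("B", parents=(("A", "is_a"),)),
            OntologyTerm("C", parents=(("A", "is_a"),)),
            OntologyTerm("D", parents=(("B", "is_a"), ("C", "is_a"))),
        ]
    )


def closure_graph(o: Ontology) -> nx.DiGraph:
    """child -> parent digraph over closure relations only."""
    g = nx.DiGraph()
    g.add_nodes_from(t.term_id for t in o.non_obsolete())
    for t in o.non_obsolete():
        g.add_edges_from((t.term_id, p) for p in o.closure_parents(t.term_id))
    return g


def oracle_ancestors(o: Ontology, term_id: str) -> frozenset:
    return frozenset(nx.descendants(closure_graph(o), term_id))


def oracle_descendants(o: Ontology, term_id: str) -> frozenset:
    return frozenset(nx.ancestors(closure_graph(o), term_id))


def oracle_protein_search(engine: SearchEngine, term_id: str) -> set:
    """Expand the query to its descendant set and intersect with annotations."""
    allowed = {term_id} | set(oracle_descendants(engine.ontology, term_id))
    return {
        pid
        for pid, p in engine.store.proteins.items()
        if p.annotations & allowed
    }


def oracle_inferred_pairs(store) -> set:
    """Brute-force: a pair is inferred iff some known DDI's two domains are
    both present on the union of the pair's domain sets."""
    import itertools

    pairs = set()
    pids = sorted(store.proteins)
    for a, b in itertools.combinations(pids, 2):
        union = store.proteins[a].domains | store.proteins[b].domains
        if any({ddi.d1, ddi.d2} <= union for ddi in store.ddis):
            pairs.add((a, b))
    return pairs


def engine_for(seed: int, **kw) -> SearchEngine:
    spec = FixtureSpec(seed=seed, **kw)
    fix = generate(spec)
    pa = PrimeAssignment.for_ontology(fix.ontology)
    return SearchEngine(fix.ontology, pa, build_store(fix))


@pytest.fixture
def small_engine():
    return engine_for(11, n_terms=60, max_parents=3, n_proteins=25, n_interactions=40)
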