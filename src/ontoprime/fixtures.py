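"""Seeded synthetic corpora and the hard-coded worked examples.

Two things live here:

* :func:`make_paper_tables` — exact in-memory reconstructions of the three
  didactic tables the encoding is usually introduced with: a four-term
  ontology with primes 2,3,5,7 (codes 6, 30, 42), the natural-number coding
  whose classic Gödel numbers (6 000, 180 000, 120 000) fail to express DAG
  ancestry, and a four-entity domain/protein set with primes 11,13,17,19
  whose arithmetic infers one protein-protein interaction (46 189 mod
  143 = 0).

* :func:`generate` — a seeded generator of random ontologies, annotation
  corpora, interaction sets and domain tables. Acyclicity holds by
  construction: a term's parents are drawn only from earlier-created terms
  of the same namespace. Generation uses only the stdlib integer RNG, so a
  seed reproduces byte-identical files on any platform.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import NamedTuple

from .encoding import PrimeAssignment
from .ontology import Ontology, OntologyTerm, write_obo
from .store import InteractionStore

import random


class PaperTables(NamedTuple):
    """The worked examples, ready for encoding and search."""

    ontology: Ontology  # four-term DAG (Term2 is_a Term1, Term3 part_of Term2, ...)
    pa: PrimeAssignment  # Term1..Term4 -> 2, 3, 5, 7
    naturals: dict[str, int]  # the natural-number coding behind original_godel
    relations: dict[str, tuple[str, str, str]]  # R1..R3: (child, relation, parent)
    store: InteractionStore  # ProteinA has domainA, ProteinB has domainB, one DDI
    entity_pa: PrimeAssignment  # domainA,domainB,ProteinA,ProteinB -> 11,13,17,19


def make_paper_tables() -> PaperTables:
    """Build the exact worked-example fixtures (see module docstring)."""
    ontology = Ontology(
        [
            OntologyTerm("Term1", name="term one"),
            OntologyTerm("Term2", name="term two", parents=(("Term1", "is_a"),)),
            OntologyTerm("Term3", name="term three", parents=(("Term2", "part_of"),)),
            OntologyTerm("Term4", name="term four", parents=(("Term2", "is_a"),)),
        ]
    )
    pa = PrimeAssignment.for_ontology(ontology, order="lex")  # 2, 3, 5, 7
    naturals = {"is_a": 1, "part_of": 2, "Term1": 3, "Term2": 4, "Term3": 5, "Term4": 6}
    relations = {
        "R1": ("Term2", "is_a", "Term1"),
        "R2": ("Term3", "part_of", "Term2"),
        "R3": ("Term4", "is_a", "Term2"),
    }
    store = InteractionStore()
    store.add_protein("ProteinA").domains.add("domainA")
    store.add_protein("ProteinB").domains.add("domainB")
    store.add_ddi("domainA", "domainB")
    # domains then proteins, starting at the 5th prime: 11, 13, 17, 19
    entity_pa = PrimeAssignment([], skip=4).extend(store.domain_ids).extend(
        sorted(store.proteins)
    )
    return PaperTables(ontology, pa, naturals, relations, store, entity_pa)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic corpus.

    ``max_parents >= 2`` enables diamonds (multiple paths to a shared
    ancestor), the regime where squarefree codes and naive recursion differ.
    ``depth_bias='leaf'`` draws 70% of annotations from leaf terms, mimicking
    curated GO usage where specific terms dominate; ``'uniform'`` draws from
    all non-root terms equally.
    """

    seed: int = 0
    n_terms: int = 50
    max_parents: int = 2
    n_namespaces: int = 1
    n_proteins: int = 30
    annotations_per_protein: tuple[int, int] = (1, 3)
    n_interactions: int = 40
    n_domains: int = 6
    n_ddis: int = 4
    domains_per_protein: tuple[int, int] = (0, 2)
    part_of_fraction: float = 0.2
    depth_bias: str = "leaf"

    def __post_init__(self) -> None:
        counts = (
            self.n_terms, self.max_parents, self.n_namespaces, self.n_proteins,
        )
        if any(c < 1 for c in counts):
            raise ValueError("n_terms, max_parents, n_namespaces, n_proteins "
                             "must all be positive")
        if self.n_terms < self.n_namespaces:
            raise ValueError("need at least one term per namespace")
        if self.depth_bias not in ("leaf", "uniform"):
            raise ValueError(f"unknown depth_bias {self.depth_bias!r}")


class Fixture(NamedTuple):
    spec: FixtureSpec
    ontology: Ontology
    annotations: dict[str, set[str]]  # protein -> term ids
    interactions: list[tuple[str, str]]
    protein_domains: dict[str, set[str]]
    ddis: list[tuple[str, str]]


def generate(spec: FixtureSpec) -> Fixture:
    """Generate one corpus deterministically from ``spec.seed``."""
    rng = random.Random(spec.seed)
    ns_names = [f"namespace_{k}" for k in range(spec.n_namespaces)]
    by_ns: dict[str, list[str]] = {ns: [] for ns in ns_names}
    terms: list[OntologyTerm] = []
    for i in range(spec.n_terms):
        ns = ns_names[i % spec.n_namespaces]
        tid = f"T:{i:05d}"
        earlier = by_ns[ns]
        parents: tuple[tuple[str, str], ...] = ()
        if earlier:  # the first term of a namespace is its root
            k = min(len(earlier), 1 + rng.randrange(spec.max_parents))
            chosen = rng.sample(earlier, k)
            parents = tuple(
                (p, "part_of" if rng.random() < spec.part_of_fraction else "is_a")
                for p in chosen
            )
        synonyms = (f"syn {i:05d}",) if rng.random() < 0.3 else ()
        terms.append(
            OntologyTerm(
                tid,
                name=f"term {i:05d}",
                namespace=ns,
                synonyms=synonyms,
                parents=parents,
            )
        )
        by_ns[ns].append(tid)
    ontology = Ontology(terms)

    roots = ontology.roots
    non_roots = sorted(t.term_id for t in terms if t.term_id not in roots)
    has_child = {p for t in terms for p, _ in t.parents}
    leaves = sorted(set(non_roots) - has_child)
    def draw_term() -> str:
        if not non_roots:
            return sorted(roots)[0]
        if spec.depth_bias == "leaf" and leaves and rng.random() < 0.7:
            return rng.choice(leaves)
        return rng.choice(non_roots)

    proteins = [f"P:{j:05d}" for j in range(spec.n_proteins)]
    lo, hi = spec.annotations_per_protein
    annotations = {
        pid: {draw_term() for _ in range(rng.randint(lo, hi))} for pid in proteins
    }

    interactions: set[tuple[str, str]] = set()
    attempts = 0
    while len(interactions) < spec.n_interactions and attempts < 50 * spec.n_interactions:
        a, b = rng.choice(proteins), rng.choice(proteins)
        interactions.add((min(a, b), max(a, b)))
        attempts += 1

    domains = [f"D:{k:03d}" for k in range(spec.n_domains)]
    dlo, dhi = spec.domains_per_protein
    protein_domains = {
        pid: set(rng.sample(domains, min(len(domains), rng.randint(dlo, dhi))))
        for pid in proteins
    }
    ddis: set[tuple[str, str]] = set()
    attempts = 0
    while (
        len(ddis) < spec.n_ddis
        and len(domains) > 1
        and attempts < 50 * spec.n_ddis
    ):
        d1, d2 = rng.sample(domains, 2)
        ddis.add((min(d1, d2), max(d1, d2)))
        attempts += 1

    return Fixture(
        spec,
        ontology,
        annotations,
        sorted(interactions),
        protein_domains,
        sorted(ddis),
    )


def build_store(fix: Fixture) -> InteractionStore:
    """Materialize a fixture as an in-memory :class:`InteractionStore`."""
    store = InteractionStore()
    for pid in sorted(fix.annotations):
        p = store.add_protein(pid)
        p.annotations |= fix.annotations[pid]
        p.domains |= fix.protein_domains.get(pid, set())
    for a, b in fix.interactions:
        store.add_interaction(a, b, source="synthetic")
    for d1, d2 in fix.ddis:
        store.add_ddi(d1, d2)
    return store


def write_fixture(fix: Fixture, outdir: str) -> dict[str, str]:
    """Write a fixture as files in the package's input dialects: OBO ontology,
    annotation/interaction/domain TSVs, plus a manifest recording the spec.
    Returns the path of each artifact. Deterministic for a fixed spec."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "obo": os.path.join(outdir, "ontology.obo"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "interactions": os.path.join(outdir, "interactions.tsv"),
        "protein_domains": os.path.join(outdir, "protein_domains.tsv"),
        "ddis": os.path.join(outdir, "domain_interactions.tsv"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    write_obo(fix.ontology, paths["obo"])
    with open(paths["annotations"], "w", encoding="utf-8") as fh:
        fh.write("# protein_id\tterm_id\n")
        for pid in sorted(fix.annotations):
            for t in sorted(fix.annotations[pid]):
                fh.write(f"{pid}\t{t}\n")
    with open(paths["interactions"], "w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in fix.interactions:
            fh.write(f"{a}\t{b}\n")
    with open(paths["protein_domains"], "w", encoding="utf-8") as fh:
        fh.write("# protein_id\tdomain_id\n")
        for pid in sorted(fix.protein_domains):
            for d in sorted(fix.protein_domains[pid]):
                fh.write(f"{pid}\t{d}\n")
    with open(paths["ddis"], "w", encoding="utf-8") as fh:
        fh.write("# domain_a\tdomain_b\n")
        for d1, d2 in fix.ddis:
            fh.write(f"{d1}\t{d2}\n")
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(fix.spec), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
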