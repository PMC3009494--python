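"""Ontology DAGs: terms, typed parent edges, and ancestor closures.

The central object is :class:`Ontology`, a validated collection of
:class:`OntologyTerm` whose parent edges, restricted to a configurable set of
*closure relations* (``is_a`` and ``part_of`` by default), form a directed
acyclic graph. Ancestor closures over that subgraph drive the prime encoding:
a term's code is the product of the primes of the term and every term in
``ancestors(term)``.

OBO flat files are read through :mod:`obonet`; the resulting graph is
re-validated here (dangling parents, cycles) before any encoding happens.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import obonet

from .errors import OntologyValidationError, UnknownTermError

#: Relation types treated as ancestry unless the caller overrides them.
DEFAULT_CLOSURE_RELATIONS = frozenset({"is_a", "part_of"})

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology term: an opaque id, a label, and typed parent edges.

    ``parents`` holds *every* recorded parent edge as ``(parent_id,
    relation_type)`` pairs; which of them count as ancestry is decided by the
    owning :class:`Ontology`'s ``closure_relations``, never silently here.
    """

    term_id: str
    name: str = ""
    namespace: str | None = None
    synonyms: tuple[str, ...] = ()
    parents: tuple[tuple[str, str], ...] = ()
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.term_id:
            raise OntologyValidationError("term_id must be non-empty")


class Ontology:
    """A validated DAG of :class:`OntologyTerm`.

    Parameters
    ----------
    terms:
        The terms, in any iterable order. Ids must be unique.
    closure_relations:
        Relation types that constitute ancestry. Parent edges with other
        relation types are retained on the terms but ignored by
        :meth:`ancestors` and by the encoding.

    Validation (performed at construction): every parent reference resolves;
    no closure edge points at an obsolete term; the closure subgraph is
    acyclic. Together with finiteness this guarantees every non-obsolete term
    reaches at least one root.
    """

    def __init__(
        self,
        terms: Iterable[OntologyTerm],
        closure_relations: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
    ) -> None:
        self.closure_relations = frozenset(closure_relations)
        if not self.closure_relations:
            raise OntologyValidationError("closure_relations must be non-empty")
        self.terms: dict[str, OntologyTerm] = {}
        for t in terms:
            if t.term_id in self.terms:
                raise OntologyValidationError(f"duplicate term id {t.term_id!r}")
            self.terms[t.term_id] = t
        self._closure_parents: dict[str, tuple[str, ...]] = {}
        self._ancestors: dict[str, frozenset[str]] = {}
        self._validate()

    # -- structure -------------------------------------------------------

    def _validate(self) -> None:
        for t in self.terms.values():
            seen: list[str] = []
            for pid, rel in t.parents:
                if pid not in self.terms:
                    raise OntologyValidationError(
                        f"term {t.term_id!r} references missing parent {pid!r}"
                    )
                if rel in self.closure_relations:
                    if self.terms[pid].obsolete:
                        raise OntologyValidationError(
                            f"closure edge {t.term_id!r} -> obsolete term {pid!r}"
                        )
                    if pid not in seen:
                        seen.append(pid)
            self._closure_parents[t.term_id] = tuple(seen)
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for tid, parents in self._closure_parents.items():
            g.add_edges_from((tid, p) for p in parents)
        if nx.is_directed_acyclic_graph(g):
            return
        cycle = nx.find_cycle(g)  # error path only: name one offending cycle
        path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
        raise OntologyValidationError(f"cycle in closure relations: {path}")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term {term_id!r}") from None

    @property
    def roots(self) -> frozenset[str]:
        """Non-obsolete terms with no closure-relation parents."""
        return frozenset(
            tid
            for tid, t in self.terms.items()
            if not t.obsolete and not self._closure_parents[tid]
        )

    def non_obsolete(self) -> list[OntologyTerm]:
        return [t for t in self.terms.values() if not t.obsolete]

    def closure_parents(self, term_id: str) -> tuple[str, ...]:
        """Parents of ``term_id`` via closure relations only."""
        self[term_id]
        return self._closure_parents[term_id]

    # -- ancestor closure ------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via closure relations,
        excluding ``term_id`` itself; each ancestor appears once regardless of
        the number of paths.

        Computed iteratively with memoization, so repeated queries and deep
        chains (tens of thousands of terms) are cheap and recursion-free.
        """
        term = self[term_id]
        if term.obsolete:
            raise UnknownTermError(f"term {term_id!r} is obsolete")
        cache = self._ancestors
        if term_id in cache:
            return cache[term_id]
        stack = [term_id]
        while stack:
            tid = stack[-1]
            if tid in cache:
                stack.pop()
                continue
            parents = self._closure_parents[tid]
            pending = [p for p in parents if p not in cache]
            if pending:
                stack.extend(pending)
                continue
            closure: set[str] = set()
            for p in parents:
                closure.add(p)
                closure |= cache[p]
            cache[tid] = frozenset(closure)
            stack.pop()
        return cache[term_id]

    def topological_order(self) -> list[str]:
        """Non-obsolete term ids ordered parents-before-children
        (deterministic: ties broken lexicographically)."""
        g = nx.DiGraph()
        live = {t.term_id for t in self.non_obsolete()}
        g.add_nodes_from(live)
        for tid in live:
            # edge parent -> child so parents sort first
            g.add_edges_from((p, tid) for p in self._closure_parents[tid])
        return list(nx.lexicographical_topological_sort(g))


def parse_obo(
    path: str,
    closure_relations: Iterable[str] = DEFAULT_CLOSURE_RELATIONS,
) -> Ontology:
    """Read an OBO 1.2/1.4 flat file into a validated :class:`Ontology`.

    ``is_a`` lines and ``relationship`` lines become parent edges with their
    relation type; only types in ``closure_relations`` count as ancestry.
    Obsolete terms are kept, flagged, and excluded from encoding downstream.

    Raises
    ------
    OSError
        If the file cannot be read.
    OntologyValidationError
        On a dangling parent reference or a cycle among closure edges.
    """
    graph = obonet.read_obo(path, ignore_obsolete=False)
    terms = []
    for node, data in graph.nodes(data=True):
        if not data:
            # obonet materialises referenced-but-undefined ids as bare nodes
            raise OntologyValidationError(
                f"parent reference to undefined term {node!r}"
            )
        synonyms = []
        for raw in data.get("synonym", ()):
            m = _SYNONYM_RE.match(raw)
            synonyms.append(m.group(1) if m else raw)
        parents = tuple(
            (parent, rel) for _, parent, rel in graph.out_edges(node, keys=True)
        )
        terms.append(
            OntologyTerm(
                term_id=node,
                name=data.get("name", ""),
                namespace=data.get("namespace"),
                synonyms=tuple(synonyms),
                parents=parents,
                obsolete=str(data.get("is_obsolete", "")).lower() == "true",
            )
        )
    return Ontology(terms, closure_relations)


def write_obo(o: Ontology, path: str) -> None:
    """Serialize an :class:`Ontology` back to OBO flat format.

    Stanzas are sorted by term id and keys are emitted in a fixed order, so
    the output is deterministic and ``parse_obo(write_obo(o))`` round-trips
    ids, names, namespaces, synonyms and parent edges exactly.
    """
    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: ontoprime-dump\n")
    for tid in sorted(o.terms):
        t = o.terms[tid]
        buf.write(f"\n[Term]\nid: {t.term_id}\n")
        if t.name:
            buf.write(f"name: {t.name}\n")
        if t.namespace:
            buf.write(f"namespace: {t.namespace}\n")
        for s in t.synonyms:
            buf.write(f'synonym: "{s}" EXACT []\n')
        # is_a lines first, then relationships: OBO readers group them that
        # way, which keeps dump -> parse -> dump byte-stable
        for pid, rel in t.parents:
            if rel == "is_a":
                buf.write(f"is_a: {pid}\n")
        for pid, rel in t.parents:
            if rel != "is_a":
                buf.write(f"relationship: {rel} {pid}\n")
        if t.obsolete:
            buf.write("is_obsolete: true\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def dump_edges(o: Ontology, path: str | None = None) -> str:
    """Debug dump of the parent graph as ``child TAB parent TAB relation``
    lines, sorted; returns the text and optionally writes it to ``path``."""
    rows = sorted(
        (t.term_id, pid, rel) for t in o.terms.values() for pid, rel in t.parents
    )
    text = "".join(f"{c}\t{p}\t{r}\n" for c, p, r in rows)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def ancestors(o: Ontology, term_id: str) -> frozenset[str]:
    """Module-level convenience for :meth:`Ontology.ancestors`."""
    return o.ancestors(term_id)
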