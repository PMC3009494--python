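"""The searchable corpus: annotated proteins, PPI pairs, domain tables.

All inputs are 2-3 column tab-separated files with ``#`` comment lines:

* annotations:     ``protein_id TAB term_id [TAB protein_name]``
* interactions:    ``protein_id TAB protein_id [TAB source]``
* protein-domain:  ``protein_id TAB domain_id``
* domain-domain:   ``domain_id TAB domain_id``

Interactions are undirected; the canonical form orders endpoints
lexicographically and duplicates collapse. Outputs are PSI-MI XML 2.5 and SIF.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from lxml import etree

from .errors import ExportError, LoadError, UnknownProteinError
from .ontology import Ontology

logger = logging.getLogger(__name__)

PSIMI_NS = "net:sf:psidev:mi"


@dataclass
class AnnotatedProtein:
    protein_id: str
    name: str = ""
    annotations: set[str] = field(default_factory=set)
    domains: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class Interaction:
    """An undirected protein pair, stored with ``a <= b`` lexicographically."""

    a: str
    b: str
    source: str = ""

    @staticmethod
    def canonical(x: str, y: str, source: str = "") -> "Interaction":
        return Interaction(min(x, y), max(x, y), source)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)

    @property
    def self_interaction(self) -> bool:
        return self.a == self.b


@dataclass(frozen=True)
class DomainInteraction:
    """An undirected domain pair (d1 <= d2)."""

    d1: str
    d2: str

    @staticmethod
    def canonical(x: str, y: str) -> "DomainInteraction":
        return DomainInteraction(min(x, y), max(x, y))


class InteractionStore:
    """Holds proteins (with annotations and domains), interactions, and
    domain-domain interactions; the corpus every search runs over."""

    def __init__(self) -> None:
        self.proteins: dict[str, AnnotatedProtein] = {}
        self._interactions: dict[tuple[str, str], Interaction] = {}
        self._ddis: dict[tuple[str, str], DomainInteraction] = {}

    # -- access ----------------------------------------------------------

    def protein(self, protein_id: str) -> AnnotatedProtein:
        try:
            return self.proteins[protein_id]
        except KeyError:
            raise UnknownProteinError(f"unknown protein {protein_id!r}") from None

    def add_protein(self, protein_id: str, name: str = "") -> AnnotatedProtein:
        p = self.proteins.get(protein_id)
        if p is None:
            p = AnnotatedProtein(protein_id, name)
            self.proteins[protein_id] = p
        elif name and not p.name:
            p.name = name
        return p

    @property
    def interactions(self) -> list[Interaction]:
        """Canonical interactions, sorted by endpoint pair."""
        return [self._interactions[k] for k in sorted(self._interactions)]

    @property
    def ddis(self) -> list[DomainInteraction]:
        return [self._ddis[k] for k in sorted(self._ddis)]

    @property
    def domain_ids(self) -> list[str]:
        ids = {d for p in self.proteins.values() for d in p.domains}
        ids.update(d for ddi in self._ddis.values() for d in (ddi.d1, ddi.d2))
        return sorted(ids)

    def add_interaction(self, a: str, b: str, source: str = "") -> Interaction:
        ia = Interaction.canonical(a, b, source)
        return self._interactions.setdefault(ia.pair, ia)

    def add_ddi(self, d1: str, d2: str) -> DomainInteraction:
        ddi = DomainInteraction.canonical(d1, d2)
        return self._ddis.setdefault((ddi.d1, ddi.d2), ddi)

    def interactions_of(self, protein_id: str) -> list[Interaction]:
        self.protein(protein_id)
        return [i for i in self.interactions if protein_id in i.pair]


def _read_rows(path: str, min_cols: int) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if all(not c.strip() for c in row):
                continue
            if len(row) < min_cols:
                raise LoadError(
                    f"{path}:{lineno}: expected at least {min_cols} "
                    f"tab-separated columns, got {len(row)}"
                )
            yield lineno, [c.strip() for c in row]


def load_annotations(
    path: str,
    ontology: Ontology,
    mode: str = "strict",
    store: InteractionStore | None = None,
) -> InteractionStore:
    """Load ``protein TAB term [TAB name]`` rows, aggregating per protein.

    In ``strict`` mode a term id that does not resolve to a live ontology
    term fails the load naming the row; in ``lenient`` mode the annotation is
    dropped with a logged warning and the protein is kept.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    store = store if store is not None else InteractionStore()
    for lineno, row in _read_rows(path, 2):
        pid, term_id = row[0], row[1]
        name = row[2] if len(row) > 2 else ""
        p = store.add_protein(pid, name)
        resolvable = (
            term_id in ontology and not ontology.terms[term_id].obsolete
        )
        if not resolvable:
            if mode == "strict":
                raise LoadError(
                    f"{path}:{lineno}: annotation term {term_id!r} does not "
                    f"resolve in the ontology"
                )
            logger.warning(
                "%s:%d: dropping unresolvable annotation %r on %r",
                path, lineno, term_id, pid,
            )
            continue
        p.annotations.add(term_id)
    return store


def load_interactions(
    path: str, store: InteractionStore, mode: str = "strict"
) -> list[Interaction]:
    """Load ``protein TAB protein [TAB source]`` rows into the store,
    canonicalized and deduplicated. Unknown endpoints fail the load in strict
    mode and are skipped with a warning in lenient mode; self-interactions
    are permitted (flagged via :attr:`Interaction.self_interaction`)."""
    loaded: list[Interaction] = []
    for lineno, row in _read_rows(path, 2):
        a, b = row[0], row[1]
        source = row[2] if len(row) > 2 else ""
        missing = [p for p in (a, b) if p not in store.proteins]
        if missing:
            if mode == "strict":
                raise LoadError(
                    f"{path}:{lineno}: interaction endpoint(s) "
                    f"{', '.join(repr(m) for m in missing)} not in store"
                )
            logger.warning("%s:%d: skipping interaction with unknown %s",
                           path, lineno, missing)
            continue
        loaded.append(store.add_interaction(a, b, source))
    return loaded


def load_protein_domains(path: str, store: InteractionStore) -> None:
    """Load ``protein TAB domain`` has-a rows; proteins are created on
    first sight so a domain table can stand alone (as in pure DDI-inference
    runs with no annotation corpus)."""
    for _, row in _read_rows(path, 2):
        store.add_protein(row[0]).domains.add(row[1])


def load_ddis(path: str, store: InteractionStore) -> None:
    """Load ``domain TAB domain`` interaction rows (undirected, deduplicated).
    Self-pairs are rejected: a DDI code must be a product of two distinct
    domain primes."""
    for lineno, row in _read_rows(path, 2):
        if row[0] == row[1]:
            raise LoadError(
                f"{path}:{lineno}: degenerate domain-domain pair {row[0]!r}"
            )
        store.add_ddi(row[0], row[1])


# -- export ---------------------------------------------------------------


def write_psimi(
    interactions: Sequence[Interaction],
    store: InteractionStore,
    path: str,
) -> None:
    """Write interactions as PSI-MI XML 2.5 (compact form).

    One ``entry``; each protein appears once in the interactorList (its xref
    primaryRef carries the protein id); interactions reference interactors by
    numeric id. Element order is sorted by id, so output is deterministic.
    """
    for ia in interactions:
        for pid in ia.pair:
            if pid not in store.proteins:
                raise ExportError(f"interaction endpoint {pid!r} not in store")
    nsmap = {None: PSIMI_NS}
    root = etree.Element("entrySet", nsmap=nsmap, level="2", version="5")
    entry = etree.SubElement(root, "entry")
    interactor_list = etree.SubElement(entry, "interactorList")
    pids = sorted({pid for ia in interactions for pid in ia.pair})
    ids = {pid: i + 1 for i, pid in enumerate(pids)}
    for pid in pids:
        p = store.proteins[pid]
        interactor = etree.SubElement(interactor_list, "interactor", id=str(ids[pid]))
        names = etree.SubElement(interactor, "names")
        etree.SubElement(names, "shortLabel").text = p.name or pid
        xref = etree.SubElement(interactor, "xref")
        etree.SubElement(xref, "primaryRef", db="ontoprime", id=pid)
    interaction_list = etree.SubElement(entry, "interactionList")
    ordered = sorted(set(interactions), key=lambda i: i.pair)
    next_id = len(pids) + 1
    for ia in ordered:
        el = etree.SubElement(interaction_list, "interaction", id=str(next_id))
        next_id += 1
        if ia.source:
            names = etree.SubElement(el, "names")
            etree.SubElement(names, "shortLabel").text = ia.source
        participants = etree.SubElement(el, "participantList")
        for pid in ia.pair:
            part = etree.SubElement(participants, "participant", id=str(next_id))
            next_id += 1
            etree.SubElement(part, "interactorRef").text = str(ids[pid])
    tree = etree.ElementTree(root)
    tree.write(path, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_psimi(path: str) -> list[tuple[str, str]]:
    """Re-parse a PSI-MI 2.5 document into sorted canonical protein pairs —
    the round-trip check for :func:`write_psimi` (and any compact PSI-MI file
    whose interactor xref primaryRef ids are the protein ids)."""
    tree = etree.parse(path)
    ns = {"mi": PSIMI_NS}
    by_id: dict[str, str] = {}
    for interactor in tree.iterfind(".//mi:interactorList/mi:interactor", ns):
        ref = interactor.find("mi:xref/mi:primaryRef", ns)
        if ref is None or not ref.get("id"):
            raise ExportError("interactor without a primaryRef id")
        by_id[interactor.get("id")] = ref.get("id")
    pairs: set[tuple[str, str]] = set()
    for interaction in tree.iterfind(".//mi:interactionList/mi:interaction", ns):
        refs = [
            by_id[r.text]
            for r in interaction.iterfind(".//mi:interactorRef", ns)
        ]
        if len(refs) != 2:
            raise ExportError(
                f"expected 2 participants per interaction, got {len(refs)}"
            )
        pairs.add((min(refs), max(refs)))
    return sorted(pairs)


def write_sif(
    interactions: Sequence[Interaction], path: str, relation: str = "pp"
) -> None:
    """Write a simple interaction format (SIF) edge list for network viewers."""
    with open(path, "w", encoding="utf-8") as fh:
        for ia in sorted(set(interactions), key=lambda i: i.pair):
            fh.write(f"{ia.a}\t{relation}\t{ia.b}\n")
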