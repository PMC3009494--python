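"""Ontology-aware queries over an annotated interaction corpus.

Every query reduces to divisibility of modified Gödel codes. A protein's
*annotation code* is the lcm of its annotation term codes, so a query term q
satisfies the protein iff ``prime(q)`` divides that code — equivalently, iff
q subsumes at least one of the protein's annotations. This is how a query for
'nucleotide binding' retrieves proteins annotated only with 'ATP binding':
the descendant's closure contains the ancestor's prime.

For domain-based interaction inference each protein also carries a *domain
code* (its own prime times its domains' primes) and each known domain-domain
interaction a two-prime code; a candidate pair is inferred when the product
of the two protein codes is divisible by a DDI code.

``keyword_search_baseline`` is the syntactic comparator: literal annotation
equality, no closure — retained so the ontology-vs-ID contrast can be
reproduced on any corpus.
"""

from __future__ import annotations

import bisect
import itertools
import math
from dataclasses import dataclass

from .encoding import (
    GodelCode,
    PrimeAssignment,
    encode_ontology,
    entity_code,
    infer_ppi_from_ddi,
)
from .errors import ConfigurationError, UnknownTermError
from .ontology import Ontology
from .store import Interaction, InteractionStore


@dataclass(frozen=True)
class QueryCondition:
    """One or more term ids, all of which must be satisfied (conjunction).

    ``target`` selects which side of an interaction the condition constrains:
    ``"query"`` (the query protein), ``"partner"``, or ``"either"`` (any one
    endpoint must satisfy every term).
    """

    terms: tuple[str, ...]
    target: str = "either"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a query condition needs at least one term")
        if self.target not in ("query", "partner", "either"):
            raise ValueError(f"unknown condition target {self.target!r}")


@dataclass
class SearchResult:
    """Interactions satisfying a query, with the explanation of each match:
    ``matched_proteins[pid][term]`` is the set of annotations of ``pid`` that
    the condition term subsumes."""

    interactions: list[Interaction]
    matched_proteins: dict[str, dict[str, frozenset[str]]]
    query_echo: QueryCondition | None = None

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [ia.pair for ia in self.interactions]


class SearchEngine:
    """Binds an ontology, its prime assignment and codes, and a corpus.

    All heavy integers (term codes, per-protein annotation and domain codes,
    DDI codes) are computed once at construction; queries are then pure
    integer modulo plus sorting, and repeated invocation yields identical
    ordered output.
    """

    def __init__(
        self,
        ontology: Ontology,
        pa: PrimeAssignment,
        store: InteractionStore,
        codes: dict[str, GodelCode] | None = None,
    ) -> None:
        self.ontology = ontology
        self.store = store
        self.codes = codes if codes is not None else encode_ontology(ontology, pa)
        # domains then proteins join the prime universe after the terms
        self.pa = pa.extend(store.domain_ids).extend(sorted(store.proteins))
        self._annotation_code: dict[str, GodelCode | None] = {}
        for pid, p in store.proteins.items():
            if p.annotations:
                self._annotation_code[pid] = entity_code(
                    [self.codes[t] for t in sorted(p.annotations)]
                )
            else:
                self._annotation_code[pid] = None
        self._domain_code: dict[str, int] = {
            pid: self.pa.prime(pid) * math.prod(self.pa.prime(d) for d in p.domains)
            for pid, p in store.proteins.items()
        }
        self._ddi_codes: list[tuple[GodelCode, str]] = [
            (
                GodelCode(
                    self.pa.prime(ddi.d1) * self.pa.prime(ddi.d2),
                    owner=f"{ddi.d1}--{ddi.d2}",
                    factor_set=frozenset(
                        {self.pa.prime(ddi.d1), self.pa.prime(ddi.d2)}
                    ),
                ),
                f"{ddi.d1}--{ddi.d2}",
            )
            for ddi in store.ddis
        ]

    # -- predicates ------------------------------------------------------

    def _term_code(self, term_id: str) -> GodelCode:
        try:
            return self.codes[term_id]
        except KeyError:
            raise UnknownTermError(f"term {term_id!r} is not encoded") from None

    def satisfies(self, protein_id: str, term_id: str) -> bool:
        """Does the protein carry the term or any of its descendants?"""
        code = self._annotation_code[self.store.protein(protein_id).protein_id]
        if code is None:
            return False
        return code.value % self.pa.prime(term_id) == 0

    def matching_annotations(self, protein_id: str, term_id: str) -> frozenset[str]:
        """The protein's annotations that the query term subsumes (the
        explanation of why :meth:`satisfies` holds)."""
        q = self._term_code(term_id)
        p = self.store.protein(protein_id)
        return frozenset(
            a for a in p.annotations if self.codes[a].value % q.value == 0
        )

    def _satisfies_all(self, pid: str, terms: tuple[str, ...]) -> bool:
        return all(self.satisfies(pid, t) for t in terms)

    # -- queries ---------------------------------------------------------

    def find_proteins_by_term(self, term_id: str) -> set[str]:
        """Every protein annotated with ``term_id`` or any descendant of it."""
        self._term_code(term_id)
        prime = self.pa.prime(term_id)
        return {
            pid
            for pid, code in self._annotation_code.items()
            if code is not None and code.value % prime == 0
        }

    def keyword_search_baseline(self, term_id: str) -> set[str]:
        """ID-matching comparator: literal annotation membership, no closure."""
        self._term_code(term_id)
        return {
            pid
            for pid, p in self.store.proteins.items()
            if term_id in p.annotations
        }

    def find_partners(
        self, protein_id: str, cond: QueryCondition | None = None
    ) -> SearchResult:
        """Interactions incident to ``protein_id``; with a condition, only
        those whose conditioned side satisfies every term. The conditioned
        side defaults to the partner."""
        incident = self.store.interactions_of(protein_id)
        if cond is None:
            ordered = sorted(
                incident, key=lambda ia: ia.b if ia.a == protein_id else ia.a
            )
            return SearchResult(ordered, {}, None)
        if cond.target == "either":
            cond = QueryCondition(cond.terms, "partner")
        kept: list[tuple[str, Interaction]] = []
        matched: dict[str, dict[str, frozenset[str]]] = {}
        for ia in incident:
            partner = ia.b if ia.a == protein_id else ia.a
            side = protein_id if cond.target == "query" else partner
            if self._satisfies_all(side, cond.terms):
                kept.append((partner, ia))
                matched.setdefault(
                    side,
                    {t: self.matching_annotations(side, t) for t in cond.terms},
                )
        kept.sort(key=lambda x: x[0])
        return SearchResult([ia for _, ia in kept], matched, cond)

    def multi_condition_search(self, cond: QueryCondition) -> SearchResult:
        """Interactions satisfying every condition term conjunctively.

        With ``target`` ``"query"`` or ``"partner"`` the named side must
        satisfy all terms itself. With ``"either"`` (the default) each term
        must be satisfied by at least one endpoint — not necessarily the same
        one — so the result equals, for every target, the intersection of the
        single-term searches. Each interaction is counted once even when both
        endpoints qualify.
        """
        per_term = {t: self.find_proteins_by_term(t) for t in cond.terms}
        kept: list[Interaction] = []
        matched: dict[str, dict[str, frozenset[str]]] = {}
        for ia in self.store.interactions:
            if cond.target == "query":
                sides = (ia.a,)
            elif cond.target == "partner":
                sides = (ia.b,)
            else:
                sides = ia.pair
            if all(any(s in per_term[t] for s in sides) for t in cond.terms):
                kept.append(ia)
                for s in sides:
                    hits = {
                        t: self.matching_annotations(s, t)
                        for t in cond.terms
                        if s in per_term[t]
                    }
                    if hits:
                        matched.setdefault(s, hits)
        kept.sort(key=lambda ia: ia.pair)
        return SearchResult(kept, matched, cond)

    def infer_interactions(self) -> list[Interaction]:
        """Hypothesize protein pairs from known domain-domain interactions:
        (A, B) is inferred when some DDI code divides the product of the two
        proteins' domain codes. Deduplicated; the provenance tag names the
        supporting DDI(s)."""
        if not self._ddi_codes:
            if not any(p.domains for p in self.store.proteins.values()):
                raise ConfigurationError(
                    "domain-domain inference requires protein-domain and "
                    "domain-domain tables to be loaded"
                )
            return []
        hits: dict[tuple[str, str], list[str]] = {}
        pids = sorted(self.store.proteins)
        for a, b in itertools.combinations(pids, 2):
            for ddi_code, tag in self._ddi_codes:
                if infer_ppi_from_ddi(
                    self._domain_code[a], self._domain_code[b], ddi_code
                ):
                    hits.setdefault((a, b), []).append(tag)
        return [
            Interaction(a, b, source="ddi:" + ";".join(tags))
            for (a, b), tags in sorted(hits.items())
        ]


class AutocompleteIndex:
    """Case-insensitive prefix index over term names and synonyms."""

    def __init__(self, ontology: Ontology) -> None:
        entries: list[tuple[str, str, str, str]] = []
        for t in ontology.non_obsolete():
            for label in (t.name, *t.synonyms):
                if label:
                    entries.append((label.lower(), label, t.term_id, t.name))
        entries.sort()
        self._entries = entries
        self._keys = [e[0] for e in entries]

    def complete(self, prefix: str, limit: int = 20) -> list[tuple[str, str]]:
        """Terms whose name or a synonym starts with ``prefix`` (case
        folded), as ``(term_id, matched_label)`` pairs ordered by matched
        string then term id, deduplicated by term id, truncated to ``limit``.

        An empty prefix returns nothing: the full vocabulary is not a useful
        completion and could be enormous.
        """
        if not prefix:
            return []
        key = prefix.lower()
        lo = bisect.bisect_left(self._keys, key)
        out: list[tuple[str, str]] = []
        seen: set[str] = set()
        for lowered, label, tid, _name in self._entries[lo:]:
            if not lowered.startswith(key):
                break
            if tid not in seen:
                seen.add(tid)
                out.append((tid, label))
                if len(out) >= limit:
                    break
        return out


# -- thin functional wrappers (the documented operation surface) ----------


def find_proteins_by_term(engine: SearchEngine, term_id: str) -> set[str]:
    return engine.find_proteins_by_term(term_id)


def find_partners(
    engine: SearchEngine, protein_id: str, cond: QueryCondition | None = None
) -> SearchResult:
    return engine.find_partners(protein_id, cond)


def multi_condition_search(engine: SearchEngine, cond: QueryCondition) -> SearchResult:
    return engine.multi_condition_search(cond)


def infer_interactions(engine: SearchEngine) -> list[Interaction]:
    return engine.infer_interactions()


def keyword_search_baseline(engine: SearchEngine, term_id: str) -> set[str]:
    return engine.keyword_search_baseline(term_id)


def autocomplete(
    index: AutocompleteIndex, prefix: str, limit: int = 20
) -> list[tuple[str, str]]:
    return index.complete(prefix, limit)
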