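"""Prime assignment and modified Gödel codes.

The encoding assigns each ontology term (and, downstream, each domain and
protein) a distinct prime, then represents a term by the *squarefree* product
of the primes of the term and all of its ancestors. Because the factorization
of such a code is a set, integer divisibility becomes subset containment of
ancestor closures:

    code(t) mod code(q) == 0   <=>   q is an ancestor of t, or t itself.

That single ``%`` is the subsumption primitive behind every ontology-aware
query in the package. Classic Gödel numbering (``original_godel``) is kept as
a demonstrator of why positional prime powers cannot express DAG ancestry.

All arithmetic is on Python's arbitrary-precision integers: with tens of
thousands of terms a deep term's code runs to thousands of bits, and no
fixed-width path is permitted anywhere in the divisibility chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .errors import UnknownTermError
from .ontology import Ontology


def generate_primes(n: int) -> list[int]:
    """First ``n`` primes in ascending order, by sieve of Eratosthenes.

    The sieve bound uses the standard estimate ``n (ln n + ln ln n)`` for the
    n-th prime and extends automatically if it falls short (it cannot for
    n >= 6, but the retry keeps the function self-contained for small n).
    """
    if n < 1:
        raise ValueError(f"need n >= 1 primes, got {n}")
    if n < 6:
        return [2, 3, 5, 7, 11][:n]
    limit = int(n * (math.log(n) + math.log(math.log(n)))) + 1
    while True:
        sieve = bytearray([1]) * (limit + 1)
        sieve[0] = sieve[1] = 0
        for i in range(2, math.isqrt(limit) + 1):
            if sieve[i]:
                sieve[i * i :: i] = bytearray(len(sieve[i * i :: i]))
        primes = [i for i, flag in enumerate(sieve) if flag]
        if len(primes) >= n:
            return primes[:n]
        limit *= 2


@dataclass(frozen=True)
class GodelCode:
    """A squarefree positive integer encoding a closure of terms.

    ``owner`` names the term or entity the code belongs to; ``factor_set``
    optionally caches the primes whose product equals ``value`` (the integer
    remains the source of truth — tests assert both paths agree).
    """

    value: int
    owner: str | None = None
    factor_set: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if self.value < 2:
            raise ValueError(f"Gödel code must be >= 2, got {self.value}")

    def __int__(self) -> int:
        return self.value


def _value(code: "GodelCode | int") -> int:
    v = int(code)
    if v < 1:
        raise ValueError(f"codes must be positive, got {v}")
    return v


class PrimeAssignment:
    """Injective map term/entity id -> prime.

    The i-th id in ``ordering`` receives the (skip + i)-th prime, so the
    assignment is fully determined by the ordering rule and the offset.
    ``extend`` continues the same prime sequence for additional entities
    (domains, proteins) that share the universe with the ontology's terms.
    """

    def __init__(self, ordering: Sequence[str], skip: int = 0) -> None:
        self.ordering: tuple[str, ...] = tuple(ordering)
        if len(set(self.ordering)) != len(self.ordering):
            raise ValueError("ordering contains duplicate ids")
        self._skip = skip
        if self.ordering:
            primes = generate_primes(skip + len(self.ordering))[skip:]
        else:
            primes = []
        self._prime: dict[str, int] = dict(zip(self.ordering, primes))

    @classmethod
    def for_ontology(
        cls, o: Ontology, order: str = "lex", skip: int = 0
    ) -> "PrimeAssignment":
        """Assign the first primes to the non-obsolete terms of ``o``.

        ``order`` is ``"lex"`` (sort term ids; the default, reproducible
        across loads) or ``"insertion"`` (file order).
        """
        ids = [t.term_id for t in o.non_obsolete()]
        if not ids:
            raise ValueError("ontology has no non-obsolete terms to assign")
        if order == "lex":
            ids.sort()
        elif order != "insertion":
            raise ValueError(f"unknown ordering rule {order!r}")
        return cls(ids, skip=skip)

    def extend(self, ids: Iterable[str]) -> "PrimeAssignment":
        """New assignment with ``ids`` appended after the current ordering,
        receiving the next primes in sequence."""
        return PrimeAssignment(self.ordering + tuple(ids), skip=self._skip)

    def prime(self, term_id: str) -> int:
        try:
            return self._prime[term_id]
        except KeyError:
            raise UnknownTermError(f"no prime assigned to {term_id!r}") from None

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._prime

    def __len__(self) -> int:
        return len(self._prime)

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self._prime.items())


def assign_primes(o: Ontology, order: str = "lex", skip: int = 0) -> PrimeAssignment:
    """Module-level convenience for :meth:`PrimeAssignment.for_ontology`."""
    return PrimeAssignment.for_ontology(o, order=order, skip=skip)


def modified_godel(o: Ontology, pa: PrimeAssignment, term_id: str) -> GodelCode:
    """Code of one term: product of the primes of ``{term} ∪ ancestors(term)``,
    each exactly once (squarefree even on diamond DAGs)."""
    closure = {term_id} | o.ancestors(term_id)
    factors = frozenset(pa.prime(t) for t in closure)
    return GodelCode(math.prod(factors), owner=term_id, factor_set=factors)


def encode_ontology(o: Ontology, pa: PrimeAssignment) -> dict[str, GodelCode]:
    """Codes for every non-obsolete term.

    Computed in topological order as ``prime(t) × lcm(codes of parents)``,
    which equals the closure product but costs one small multiply (plus a gcd
    per extra parent) per term — linear-ish even on deep ten-thousand-term
    chains, where re-deriving each closure product from scratch is quadratic.
    Factor sets are cached alongside so hot paths may intersect sets; the
    integers stay authoritative.
    """
    values: dict[str, int] = {}
    factors: dict[str, frozenset[int]] = {}
    for tid in o.topological_order():
        parents = o.closure_parents(tid)
        acc = 1
        for p in parents:
            acc = acc * values[p] // math.gcd(acc, values[p])
        prime = pa.prime(tid)
        values[tid] = prime * acc
        fs: set[int] = {prime}
        for p in parents:
            fs |= factors[p]
        factors[tid] = frozenset(fs)
    return {
        tid: GodelCode(values[tid], owner=tid, factor_set=factors[tid])
        for tid in values
    }


def export_code_table(
    o: Ontology, pa: PrimeAssignment, codes: dict[str, GodelCode]
) -> str:
    """TSV text ``term_id TAB prime TAB code`` (exact decimal strings), rows
    sorted by term id — the regression-snapshot format."""
    lines = ["term_id\tprime\tmodified_godel\n"]
    for tid in sorted(codes):
        lines.append(f"{tid}\t{pa.prime(tid)}\t{codes[tid].value}\n")
    return "".join(lines)


def original_godel(codes: Sequence[int]) -> int:
    """Classic Gödel number of a list of naturals: ``∏ p_k ** a_k``.

    Injective by unique factorization, but positional — it encodes one tuple,
    not a DAG closure, which is exactly the limitation the modified encoding
    removes.
    """
    if not codes:
        raise ValueError("original_godel requires a non-empty list")
    if any(a < 1 for a in codes):
        raise ValueError("all codes must be >= 1")
    primes = generate_primes(len(codes))
    return math.prod(p**a for p, a in zip(primes, codes))


def subsumes(q_code: GodelCode | int, t_code: GodelCode | int) -> bool:
    """True iff ``t_code`` is divisible by ``q_code``.

    For term codes this is exactly "q is an ancestor of t or t itself", by the
    squarefree-closure construction.
    """
    return _value(t_code) % _value(q_code) == 0


def entity_code(annotation_codes: Sequence[GodelCode | int]) -> GodelCode:
    """Code of a multi-annotated entity: the lcm of its annotation codes
    (equivalently the squarefree product of the union of their factor sets).

    A query term q then satisfies the entity iff ``prime(q)`` divides the
    entity code — i.e. q subsumes at least one annotation.
    """
    if not annotation_codes:
        raise ValueError("entity_code requires at least one annotation code")
    value = math.lcm(*[_value(c) for c in annotation_codes])
    fs = None
    sets = [c.factor_set for c in annotation_codes if isinstance(c, GodelCode)]
    if len(sets) == len(annotation_codes) and all(s is not None for s in sets):
        fs = frozenset().union(*sets)
    return GodelCode(value, factor_set=fs)


def infer_ppi_from_ddi(
    protA_code: GodelCode | int,
    protB_code: GodelCode | int,
    ddi_code: GodelCode | int,
) -> bool:
    """Test the hypothesis "protein A interacts with protein B" against one
    known domain-domain interaction.

    The protein codes are products of the protein's own prime and its domains'
    primes; the DDI code is the product of the two interacting domains'
    primes. The hypothesis holds iff the product of the protein codes is
    divisible by the DDI code — i.e. both interacting domains occur somewhere
    on the pair.
    """
    if isinstance(ddi_code, GodelCode) and ddi_code.factor_set is not None:
        if len(ddi_code.factor_set) != 2:
            raise ValueError(
                "a domain-domain interaction code must be the product of "
                f"exactly two domain primes, got {len(ddi_code.factor_set)}"
            )
    return (_value(protA_code) * _value(protB_code)) % _value(ddi_code) == 0
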