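# Methods

## Model

An ontology is a finite DAG of terms with typed parent edges. A configurable
subset of edge types — default `{is_a, part_of}` — is the *closure set*: the
relations along which annotation propagates (the true-path rule). Other edge
types (e.g. GO's `regulates`) are parsed and retained on the term but do not
contribute ancestry; the choice is exposed as `closure_relations` everywhere
an ontology is built.

Each non-obsolete term receives a distinct prime. The term's code is the
squarefree product of the primes of the term and its ancestor closure.
Soundness and completeness of the search primitive follow from unique
factorization: for squarefree integers, `b mod a = 0` iff the factor set of
`a` is a subset of that of `b`, and by construction factor sets are exactly
ancestor closures. Closures are transitively closed, which also gives the
single-prime shortcut used on hot paths: `p(q) | code(t)` iff
`code(q) | code(t)`.

Entities compose as follows:

* protein with annotations `{a₁..aₖ}` → `lcm(code(a₁)..code(aₖ))` (the
  squarefree product of the union of the closures). A query term satisfies
  the protein iff its prime divides this code, i.e. iff it subsumes at least
  one annotation. Two different annotations may satisfy two different
  condition terms of a conjunction.
* protein with domains → its own prime × its domains' primes (the has-a
  relation). Domains and proteins join the same prime universe as the
  ontology's terms: terms first (in the assignment order), then domain ids
  (sorted), then protein ids (sorted).
* domain–domain interaction → product of the two (distinct) domain primes.
  A pair (A, B) is an inferred interaction iff some DDI code divides
  `code(A) × code(B)`; equivalently, both interacting domains occur on the
  union of the pair's domain sets. Degenerate one-domain DDIs are rejected.

## Conjunctive search semantics

A multi-term condition is a conjunction; disjunction is expressed by issuing
separate queries and uniting. The condition's *target* picks the constrained
side of each interaction:

* `query` / `partner`: the named protein must satisfy **all** terms itself —
  the strict co-annotation reading (a process term and a component term on
  the same query protein, for instance).
* `either` (default): each term must be satisfied by at least one endpoint,
  not necessarily the same one. This is the unique either-side semantics for
  which `multi_condition_search(t₁..tₖ)` equals the intersection of the
  single-term searches for every input — the identity the property suite
  asserts. The strict same-endpoint reading on "either" would be strictly
  narrower and break that identity; users who want it can fix a side.

An interaction is counted once even when both endpoints qualify. Results are
ordered lexicographically by canonical endpoint pair, and every inclusion is
explained: the result maps each qualifying protein to the annotations that
each condition term subsumed.

## Parameters that matter

| parameter | default | why |
| --- | --- | --- |
| `closure_relations` | `{is_a, part_of}` | the ancestry relations of the didactic examples; other GO relations are later refinements and are excluded unless asked for |
| prime-assignment `order` | `lex` | reproducible codes independent of file row order; `insertion` preserves file order when that is the contract |
| `skip` (prime offset) | 0 | lets an entity universe start at a later prime (the worked example's domain table starts at the 5th prime, 11) |
| loader `mode` | `strict` | unresolvable annotations fail the load naming the row; `lenient` drops them with a logged warning |
| autocomplete `limit` | 20 | bounds response size; an empty prefix returns nothing rather than the entire vocabulary |

## Numerical choices

* All codes are Python `int`s (arbitrary precision). There is no fixed-width
  arithmetic anywhere on the divisibility path; at 10 000 terms the deepest
  closure code in the scale test is ~2 000 bits.
* The sieve bound is the standard `n(ln n + ln ln n)` overestimate of the
  n-th prime, doubled and retried in the (theoretically impossible for
  n ≥ 6) event of a shortfall.
* Bulk encoding runs in topological order and computes each code as
  `prime(t) × lcm(parent codes)` — one big-integer multiply and a gcd per
  extra parent — rather than re-multiplying the whole closure per term,
  which is quadratic on deep chains. The per-term closure product
  (`modified_godel`) is kept as the direct definition and the two are
  asserted equal in tests.
* Ancestor closures are memoized frozensets computed with an explicit stack,
  so 10⁴-deep chains don't hit the recursion limit. Diamonds contribute each
  shared ancestor once (set union), matching the squarefree codes; the
  literal per-parent recursion of the naive formulation would revisit shared
  ancestors exponentially often on dense diamonds.
* Factor sets are cached next to each integer so membership tests may use
  set intersection, but the integers remain the source of truth and the test
  suite asserts the two representations agree by trial division.
* Ties everywhere break lexicographically (term ids, protein pairs,
  autocomplete labels), making every command and query deterministic and
  snapshots byte-stable.

## Degenerate inputs

Cycles among closure edges, dangling parent references, and closure edges
into obsolete terms are rejected at load with the offending ids named.
Obsolete terms are parsed and flagged but receive no prime and cannot be
queried. Self-interactions are stored and flagged. Empty interaction or DDI
tables are valid (empty results); an inference run with neither domains nor
DDIs anywhere is a configuration error rather than a silent empty answer.

## What the synthetic corpora emulate — and what they don't

The generator grows a DAG by giving each new term 1..`max_parents` parents
drawn among earlier terms of its namespace, so acyclicity holds by
construction and `max_parents ≥ 2` produces the diamond topologies that
stress the squarefree encoding. Annotations are leaf-biased by default (70%
of draws from leaves), mimicking curators' preference for specific terms —
the regime where ontology-aware search visibly beats ID matching.
Interactions, domains and DDIs are uniform random. Generation uses only the
stdlib integer RNG, so a seed reproduces byte-identical files across
platforms.

These corpora do not reproduce GO's real topology statistics (depth
distribution, branching, namespace sizes) or any curated PPI corpus's
annotation biases. Passing the property suite therefore certifies the
*logic* — divisibility ⇔ reachability, monotonicity, baseline containment,
inference equivalence — on arbitrary DAGs, not the absolute retrieval counts
of any particular database, which depend on that database's annotation
snapshot and are out of scope here.

## Problem sizes used in the test suite

Property tests run on 100 random DAGs up to 500 terms (sampled query pairs
against a networkx reachability oracle), search properties on corpora of
40–80 terms and 25–40 proteins over several seeds, and the scale test on one
10 000-term ontology with 500 sampled divisibility queries. The worked
examples are exact and instantaneous.

## Known limitations

* Re-encoding is full, not incremental: editing the ontology invalidates all
  codes (prime assignment is positional in the term order).
* No semantic-similarity scoring (Resnik/Lin-style); retrieval is exact
  subsumption, unranked.
* PSI-MI output is the compact 2.5 dialect with identity xrefs only.
* OWL, OBO typedef semantics and cross-ontology `xref` links are not parsed.
* Codes grow with closure depth; they compress well as factor sets but no
  compressed storage is implemented.
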