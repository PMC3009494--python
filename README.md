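# ontoprime

Ontology-aware search over protein–protein interaction (PPI) data, powered by
a prime-number encoding of the ontology DAG.

## The problem

Keyword or ID matching against a PPI database is purely syntactic: a query
for *nucleotide binding* misses every interaction whose proteins are
annotated only with the more specific *ATP binding*, even though the Gene
Ontology (GO) says every ATP binder is a nucleotide binder. Retrieval that
respects the ontology must expand each query term to its full set of
descendants — and do it exactly, for ~26 000 terms, on every query.

## The encoding

`ontoprime` makes that expansion a single integer operation. Each term *t* of
the ontology receives a distinct prime *p(t)* (terms in deterministic order,
primes from a sieve of Eratosthenes). A term is then represented by its
**modified Gödel number**: the squarefree product over its ancestor closure,

    code(t) = ∏ p(u),   u ∈ {t} ∪ ancestors(t),

where ancestry follows the `is_a` and `part_of` edges (configurable) and each
prime appears exactly once even when a diamond in the DAG provides several
paths to a shared ancestor. Because the factorization of a squarefree integer
is a *set*, divisibility is subset containment:

    code(t) mod code(q) = 0   ⇔   q ∈ {t} ∪ ancestors(t).

A protein annotated with several terms gets the lcm of their codes, so
"protein satisfies query term q" is one modulo by *p(q)*. Known
domain–domain interactions (DDIs) get the product of the two domain primes,
a protein with domains gets its own prime times its domains' primes, and the
hypothesis "A interacts with B" is confirmed by one more modulo:
`(code(A) × code(B)) mod code(DDI) = 0`. All arithmetic is
arbitrary-precision; nothing is approximated.

The classic positional Gödel numbering (`original_godel`, ∏ pₖ^aₖ) is kept as
a demonstrator of why prime *powers* at list positions cannot express DAG
ancestry, which is what motivates the squarefree closure form.

## Worked example

The four-term teaching ontology (Term2 is_a Term1; Term3 part_of Term2;
Term4 is_a Term2) with primes 2, 3, 5, 7:

```sh
$ ontoprime encode --obo four_term.obo
# ontoprime encode config-hash=a9830ad5f179
# closure_relations=is_a,part_of
# obo=four_term.obo
# order=lex
term_id	prime	modified_godel
Term1	2	2
Term2	3	6
Term3	5	30
Term4	7	42
```

Term4's code 42 = 7 × 3 × 2 carries the primes of Term4, Term2 *and* the
root Term1, so `42 mod 6 = 0` proves Term4 descends from Term2 without any
graph traversal. For inference, with domainA = 11, domainB = 13,
ProteinA = 17 (has domainA), ProteinB = 19 (has domainB), the DDI code is
11 × 13 = 143, the protein codes are 187 and 247, and since
187 × 247 = 46 189 ≡ 0 (mod 143) the interaction ProteinA–ProteinB is
inferred:

```sh
$ ontoprime infer --domains pd.tsv --ddis ddi.tsv
# ontoprime infer config-hash=25cfd7bf4e53
# ddis=ddi.tsv
# domains=pd.tsv
# format=tsv
protein_a	protein_b	supporting_ddi
ProteinA	ProteinB	ddi:domainA--domainB
```

(`pd.tsv` holds the has-a rows `ProteinA TAB domainA`, `ProteinB TAB
domainB`; `ddi.tsv` the single row `domainA TAB domainB`. Seeded test
corpora come from `ontoprime fixtures --seed 5 --outdir fx`.)

In Python:

```python
from ontoprime import parse_obo, assign_primes, encode_ontology, SearchEngine
from ontoprime.store import load_annotations, load_interactions

o = parse_obo("go_subset.obo")
pa = assign_primes(o)
store = load_annotations("annotations.tsv", o)
load_interactions("interactions.tsv", store)
engine = SearchEngine(o, pa, store)

engine.find_proteins_by_term("GO:0000166")    # nucleotide binding + descendants
engine.keyword_search_baseline("GO:0000166")  # literal matches only (⊆ the above)
engine.find_partners("HPRD_01368")
```

Search results export as TSV, SIF, or PSI-MI 2.5 XML; `ontoprime complete`
autocompletes partial term names and synonyms.

## Layout

| module | contents |
| --- | --- |
| `ontoprime.ontology` | OBO parsing, DAG validation, ancestor closures |
| `ontoprime.encoding` | primes, Gödel codes, the divisibility primitive |
| `ontoprime.store` | annotation/interaction/domain tables, PSI-MI & SIF |
| `ontoprime.search` | term search, partner search, conjunctions, DDI inference, autocomplete |
| `ontoprime.fixtures` | seeded synthetic corpora and the worked examples |
| `ontoprime.cli` | `ontoprime encode / search / infer / complete / fixtures` |
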