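# Methods

## The interoperability model

`annolink` treats a JSON-LD context as the single source of semantics for
an API: a finite tree of term definitions whose IRI-bearing leaves
correspond one-to-one with dotted field paths in the API's response
documents. Everything else in the package is derived from that artifact.

Only the JSON-LD 1.0 subset these contexts actually use is supported: a
term maps to `{"@id": <absolute IRI>}` (or an IRI string shorthand)
and/or scopes a nested `@context` for its object value. Every other
JSON-LD keyword (`@type`, `@container`, `@vocab`, `@base`, `@reverse`,
`@graph`, ...) is rejected with an error naming the term. The rationale
is fail-loudly: silently ignoring a keyword could invert a context into a
mapping that no conformant processor would produce. Term names containing
`.` are rejected because they would be ambiguous with dotted path
rendering. IRIs outside identifiers.org (schema.org, Bio2RDF, ...) are
treated as opaque — the machinery only ever compares them for equality.

**Inversion.** `invert_context` walks the term tree pre-order and
collects, per concept IRI, every path carrying it. Two invariants are
property-tested: every inverted path resolves back to its IRI
(`uri_for_path` round trip), and the union of all path sets equals the
set of IRI-bearing leaves counted by an independent tree walk.

**Extraction.** `resolve_path` descends a document segment by segment;
arrays at any level are traversed element-wise in document order, and a
path landing on an array of scalars yields its elements. `extract_values`
is the composition of inversion and resolution; its correctness oracle in
the tests is a brute-force scan that walks *every* leaf of the document
and keeps those whose full dotted path maps to the queried IRI — a
different computational route through the same definition.

**RDF expansion.** One quad per context-mapped scalar leaf; the predicate
is the leaf's IRI, the object a plain string literal. Numbers are
rendered in shortest-decimal form so `3077` and `"3077"` are one value;
no typed literals are emitted, because identifier namespaces dominate
these payloads and datatype dialects add risk without adding meaning.
Subjects: documents carrying an entity ID get
`<prefix><percent-encoded id>` (prefix configurable,
`http://example.org/entity/` by default — the upstream services do not
publish a subject scheme, so none is hard-coded); anonymous documents get
blank nodes `_:b<i>` numbered by ingestion order for determinism. The
N-Quads writer is a direct implementation of the line grammar (escaping
`\\`, `"`, newline, carriage return, tab, and other control characters as
`\uXXXX`); tests round-trip its output through rdflib's parser. Since an
RDF graph is a statement *set*, duplicate statements legitimately
collapse on re-parse; the writer itself is checked to emit one line per
quad.

## Registry and routing

An endpoint is typed by one input concept IRI and a set of output concept
IRIs, plus a `{id}` query template and a batch size. Route search runs
breadth-first over concept IRIs to find the minimal number of legs, then
a depth-limited, distance-pruned DFS that scans endpoints in registry
order (and an endpoint's output types in sorted order) reconstructs the
lexicographically earliest-registered chain of that minimal length. This
two-phase scheme makes the tie-break exactly reproducible, which the
tests exploit by comparing against exhaustive enumeration of all chains
on random registries. `max_hops` defaults to 3: blind search should stay
cheap, and longer chains are better specified explicitly.

Deliberately redundant routes — the drug-discovery chain revisits the
NCBI Gene type because pathway membership *expands* the gene set — would
never be found by shortest-path search, so `Route` objects are
first-class: constructed leg by leg and validated against the registry.

**Translation.** `translate_ids` picks the first capable endpoint in
registry order, fetches per batch, extracts the output concept through
the endpoint's context, stringifies and deduplicates values
(first-occurrence order). `execute_route` pools each leg's deduplicated
outputs into the next leg's inputs and re-attributes results to the
original IDs afterwards; provenance keeps one record per (leg, input,
value) so any final value can be traced back through the chain. Batch
size must not affect results (tested for sizes 1 vs 1000). The live HTTP
fetcher (stdlib `urllib`, configurable timeout/retries) is opt-in and
never runs in the suite.

## Discrepancy checks

Source attribution is the first segment of the originating field path,
matching the source-keyed top level of aggregated annotation documents.
The categorical check flags an entity when ≥ 2 sources report the concept
and ≥ 2 distinct values appear after whitespace trimming; comparison is
case-sensitive, since aggressive normalization could mask real
discrepancies in case-stable identifiers like rsids. The numeric check
takes one representative value per source (first value by default, mean
optional) and computes the relative range `(max − min)/max`, which is 0
when all values are equal (or all zero) and lies in [0, 1] for
non-negative inputs; an entity is flagged when ≥ 2 sources are present
and the metric exceeds the threshold (default 0.5). "Varies by more than
50%" is not a uniquely defined phrase, so the metric is configurable: an
absolute-range alternative (`max − min`) is provided for callers who mean
percentage points rather than relative change.

## What the synthetic corpus emulates — and what it does not

`generate_corpus` emulates the *shape* of aggregated variant annotation:
per-source branches (`dbsnp`, `dbnsfp`, `clinvar` by default), each with
an rsid and an allele-frequency leaf under source-specific field names
unified only by the context; allele frequency carries a synthetic vocab
IRI (`http://example.org/vocab/allele_frequency`) because identifiers.org
has no namespace for it. Baseline documents agree on the rsid and jitter
allele frequencies within ±10% (relative range ≤ 0.19, safely below the
0.5 threshold); an injected rsid conflict rewrites one source's rsid, and
an injected frequency conflict scales one source to 10–45% of the
others', forcing the relative range above 0.55. Conflicts are injected in
*exact* counts rather than Bernoulli rates so recovery tests assert set
equality, and generation is a pure function of the spec (same seed ⇒
byte-identical corpus).

What passing these tests shows: the context-driven pipeline recovers
every planted conflict and nothing else under clean separation between
agreeing and conflicting documents. What it does not show: performance on
real aggregated builds, where discrepancy counts depend on the loaded
database releases, frequencies come from different population panels, and
borderline variability sits near any threshold. Real-corpus counts are
therefore out of scope by design.

The worked-example bundle wires three mock APIs (variant, gene, chemical)
across four registry endpoints — the gene API appears twice because it
answers two differently-typed questions (annotate a gene ID; list a
pathway's member genes) and typed routing requires one endpoint per input
type. The two variants `chr6:g.26093141G>A` / `chr12:g.111351981C>T` and
their gene IDs 3077 / 4633 are real; every pathway, UniProt and drug
identifier downstream is synthetic (InChIKeys are shape-valid 14-10-1
uppercase blocks with no chemical meaning).

## Problem sizes and numerical choices

The randomized checks use 500 extraction documents, 250 random
registries of ≤ 6 endpoints, and 100 corpus seeds at 1000 documents with
25 + 15 injected conflicts — sizes at which the independent oracles
(whole-tree walk, exhaustive chain enumeration) remain exact and the full
suite runs in seconds. Floating-point comparisons in the variability
metric are exact arithmetic on the parsed values; no tolerance is applied
because flagging is a strict inequality against the threshold and the
generator keeps a wide margin (≤ 0.19 vs ≥ 0.55) on either side.

## Known limitations

* JSON-LD coverage is intentionally the BioThings dialect; contexts using
  `@vocab`, `@type` coercion, `@container` or remote context resolution
  are rejected, not approximated.
* Quad objects are untyped string literals; consumers needing
  `xsd:decimal` semantics must coerce downstream.
* Route search assumes endpoint output types are reachable for *every*
  input value; it cannot model endpoints that answer only a subset of an
  ID namespace.
* The discrepancy scanner holds flagged records in memory; corpora with
  very high conflict rates scale with the number of flags, not documents.
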