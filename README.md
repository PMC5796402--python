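# annolink

Semantic annotation, cross-linking and quality control for JSON-based
biomedical annotation APIs.

## The problem

Gene, variant and chemical annotation services (MyGene.info-style APIs)
all speak JSON, but each one invents its own field layout: one API keeps
the dbSNP identifier at `dbsnp.rsid`, another at `dbnsfp.rsid`, and an
OMIM disease ID may hide at `clinvar.rcv.conditions.identifiers.omim`.
Anyone integrating several such services must memorise every schema, and
every schema change breaks their client code.

JSON-LD fixes this with a single artifact: a *context*, itself a JSON
document, that maps each response field to a concept URI — by convention
an identifiers.org namespace URI such as `http://identifiers.org/dbsnp/`.
Two APIs that reference the same URI are talking about the same concept,
whatever their field names. `annolink` implements the whole pattern on
top of that one artifact:

* **Context handling** — parse nested JSON-LD contexts into a term tree
  and invert them into a concept-URI → field-path mapping
  (`load_context`, `invert_context`, `uri_for_path`).
* **Structure-neutral queries** — extract every value of a concept URI
  from a document without knowing where any source stores it
  (`extract_values`).
* **RDF export** — expand documents into subject–predicate–object
  statements and serialize N-Quads for the Linked Data cloud
  (`expand_to_quads`, `write_nquads`).
* **Typed API registry** — describe endpoints by their input/output
  concept URIs and discover the shortest endpoint chain converting one
  identifier type into another (`find_endpoints`, `find_route`).
* **ID translation** — push an ID list through a single endpoint or a
  multi-leg route, with batching, pooling and full provenance
  (`translate_ids`, `execute_route`); document retrieval is pluggable
  (offline fixture bundle or live HTTP).
* **Discrepancy checking** — flag entities whose sources disagree on a
  categorical concept (different rsids for one variant) or whose numeric
  values vary beyond a threshold (allele-frequency relative range
  `(max − min)/max > 0.5`), driven purely by the context
  (`check_categorical`, `check_numeric_variability`, `scan_corpus`).
* **Synthetic fixtures** — a seeded corpus generator with exact injected
  conflict counts, plus a fully offline worked-example bundle of three
  mock APIs (`annolink.fixtures`).

## Worked example

Two missense variants implicated in a rare Mendelian disease are chained
through variant → gene → pathway → member genes → protein → drug,
entirely offline against the packaged bundle:

```python
from annolink import FixtureFetcher, execute_route, translate_ids
from annolink.fixtures import IRI, variant_to_drug_route, worked_example_bundle

registry, bundle, contexts = worked_example_bundle()
fetch = FixtureFetcher(bundle)
variants = ["chr6:g.26093141G>A", "chr12:g.111351981C>T"]

genes = translate_ids(variants, IRI.HGVS, IRI.NCBIGENE, registry, fetch, contexts)
print(genes.mapping)
# {'chr6:g.26093141G>A': ['3077'], 'chr12:g.111351981C>T': ['4633']}

drugs = execute_route(variants, variant_to_drug_route(), registry, fetch, contexts)
print(drugs.mapping)
# {'chr6:g.26093141G>A': ['AAAAAAAAAAAAAA-BBBBBBBBBB-C',
#                         'GGGGGGGGGGGGGG-HHHHHHHHHH-I',
#                         'JJJJJJJJJJJJJJ-KKKKKKKKKK-L'],
#  'chr12:g.111351981C>T': ['DDDDDDDDDDDDDD-EEEEEEEEEE-F',
#                           'MMMMMMMMMMMMMM-NNNNNNNNNN-O']}
```

The first call answers "which genes do these variants fall in": NCBI Gene
3077 and 4633, extracted from the `dbsnp.gene.geneid` field purely via its
concept URI. The second executes the five-leg route; each variant ends
with the InChIKeys of the drugs targeting proteins in its gene's pathways
(the keys are shape-valid synthetic identifiers from the bundle).
Provenance (`drugs.provenance`) records, per value, the leg, endpoint and
immediate input ID that produced it.

The same flows are available on the command line:

```bash
annolink route --from http://identifiers.org/hgvs/ --to http://identifiers.org/ncbigene/
# leg 0: http://identifiers.org/hgvs/ -> http://identifiers.org/ncbigene/ via variant

annolink simulate --n 1000 --rsid-conflicts 25 --af-conflicts 15 --seed 1 \
    -o corpus.jsonl --truth truth.json --context-out ctx.json
annolink check --context ctx.json \
    --categorical http://identifiers.org/dbsnp/ \
    --numeric http://example.org/vocab/allele_frequency \
    -o report.csv corpus.jsonl
# flagged 40 record(s) across 2 concept(s); 0 unreadable document(s)
```

See `annolink --help` for the remaining subcommands (`invert`, `extract`,
`nquads`, `translate`, `bundle`).

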