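"""Synthetic annotation corpora and an offline worked-example bundle.

Real aggregated variant-annotation services merge hundreds of millions of
documents from sources such as dbSNP, dbNSFP and ClinVar; their absolute
discrepancy counts depend on the exact database releases loaded.  For
hermetic testing this module generates corpora with the same *shape* —
per-source branches carrying rsid and allele-frequency leaves under a
MyVariant-style JSON-LD context — and a known, exact number of injected
cross-source conflicts, so recovery can be asserted as equality rather
than approximation.

It also packages a miniature three-API world (variant, gene and chemical
annotation services with their contexts and response documents) wiring the
classic drug-repurposing chain: variant HGVS ID → NCBI Gene ID →
WikiPathways ID → member gene IDs → UniProt accessions → drug InChIKeys.
The two variants and their gene IDs (3077 and 4633) are real; every
pathway, protein and drug identifier downstream is synthetic (InChIKeys
are shape-valid 14-10-1 uppercase blocks with no chemical meaning).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .context import ContextDocument, load_context
from .errors import AnnolinkError
from .registry import APIEndpoint, Registry, Route, RouteLeg
from .semantic import AnnotationDocument

__all__ = [
    "IRI",
    "FixtureSpec",
    "GroundTruth",
    "corpus_context",
    "generate_corpus",
    "worked_example_bundle",
    "variant_to_drug_route",
    "VARIANT_GENES",
]


class IRI:
    """Concept IRIs used across the fixtures (identifiers.org namespaces,
    plus one synthetic vocab term for allele frequency, which has no
    identifiers.org namespace)."""

    HGVS = "http://identifiers.org/hgvs/"
    DBSNP = "http://identifiers.org/dbsnp/"
    NCBIGENE = "http://identifiers.org/ncbigene/"
    WIKIPATHWAYS = "http://identifiers.org/wikipathways/"
    UNIPROT = "http://identifiers.org/uniprot/"
    INCHIKEY = "http://identifiers.org/inchikey/"
    OMIM = "http://identifiers.org/omim/"
    ALLELE_FREQ = "http://example.org/vocab/allele_frequency"


#: MyVariant-style context for the synthetic corpus: three source branches,
#: each reporting an rsid and an allele frequency under its own field names.
_CORPUS_CONTEXT = {
    "@context": {
        "dbsnp": {
            "@context": {
                "rsid": {"@id": IRI.DBSNP},
                "alt_freq": {"@id": IRI.ALLELE_FREQ},
                "gene": {"@context": {"geneid": {"@id": IRI.NCBIGENE}}},
            }
        },
        "dbnsfp": {
            "@context": {
                "rsid": {"@id": IRI.DBSNP},
                "af": {"@id": IRI.ALLELE_FREQ},
            }
        },
        "clinvar": {
            "@context": {
                "rsid": {"@id": IRI.DBSNP},
                "allele_freq": {"@id": IRI.ALLELE_FREQ},
                "rcv": {
                    "@context": {
                        "conditions": {
                            "@context": {
                                "identifiers": {
                                    "@context": {"omim": {"@id": IRI.OMIM}}
                                }
                            }
                        }
                    }
                },
            }
        },
    }
}


def corpus_context() -> ContextDocument:
    """The JSON-LD context the synthetic corpus documents conform to."""
    return load_context(_CORPUS_CONTEXT, origin="annolink.fixtures.corpus")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus; generation is a pure function of
    this spec (same spec ⇒ byte-identical corpus)."""

    n_docs: int
    sources: tuple[str, ...] = ("dbsnp", "dbnsfp", "clinvar")
    rsid_conflict_count: int = 0
    af_conflict_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1:
            raise AnnolinkError("n_docs must be positive")
        if len(self.sources) < 2:
            raise AnnolinkError("need at least two sources to inject conflicts")
        if self.rsid_conflict_count > self.n_docs or self.af_conflict_count > self.n_docs:
            raise AnnolinkError("conflict counts cannot exceed n_docs")
        if self.rsid_conflict_count < 0 or self.af_conflict_count < 0:
            raise AnnolinkError("conflict counts must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Entity IDs of the injected conflicts (the sets to recover)."""

    rsid_conflicts: frozenset[str]
    af_conflicts: frozenset[str]


# per-source field names for the allele-frequency leaf (sources disagree on
# naming in the wild; the context is what unifies them)
_AF_FIELD = {"dbsnp": "alt_freq", "dbnsfp": "af", "clinvar": "allele_freq"}

_BASES = "ACGT"


def _hgvs_id(rng: random.Random, used: set[str]) -> str:
    while True:
        chrom = rng.randint(1, 22)
        pos = rng.randint(10_000, 200_000_000)
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        hgvs = f"chr{chrom}:g.{pos}{ref}>{alt}"
        if hgvs not in used:
            used.add(hgvs)
            return hgvs


def generate_corpus(spec: FixtureSpec) -> tuple[list[AnnotationDocument], GroundTruth]:
    """Generate a corpus with exactly the requested conflict counts.

    Every document has one branch per source, each with an rsid and an
    allele frequency.  In conflict-free documents all sources agree on the
    rsid and their allele frequencies are jittered within ±10% (relative
    range ≤ 0.19, safely under the 0.5 flagging threshold).  An rsid
    conflict gives one source a different rsid; an allele-frequency
    conflict scales one source's value down to 10–45% of the others',
    pushing the relative range above 0.55.
    """
    rng = random.Random(spec.seed)
    used_ids: set[str] = set()

    docs: list[AnnotationDocument] = []
    rsid_idx = set(rng.sample(range(spec.n_docs), spec.rsid_conflict_count))
    af_idx = set(rng.sample(range(spec.n_docs), spec.af_conflict_count))
    rsid_flagged: set[str] = set()
    af_flagged: set[str] = set()

    for i in range(spec.n_docs):
        entity_id = _hgvs_id(rng, used_ids)
        base_rsid = f"rs{rng.randint(1_000, 99_999_999)}"
        base_af = round(rng.uniform(0.05, 0.5), 6)

        rsids = {s: base_rsid for s in spec.sources}
        afs = {s: round(base_af * rng.uniform(0.9, 1.1), 6) for s in spec.sources}

        if i in rsid_idx:
            culprit = rng.choice(spec.sources)
            rsids[culprit] = f"rs{rng.randint(1_000, 99_999_999)}"
            while rsids[culprit] == base_rsid:
                rsids[culprit] = f"rs{rng.randint(1_000, 99_999_999)}"
            rsid_flagged.add(entity_id)
        if i in af_idx:
            culprit = rng.choice(spec.sources)
            others_min = min(v for s, v in afs.items() if s != culprit)
            afs[culprit] = round(others_min * rng.uniform(0.10, 0.45), 6)
            af_flagged.add(entity_id)

        body: dict = {"_id": entity_id}
        for s in spec.sources:
            branch: dict = {"rsid": rsids[s], _AF_FIELD.get(s, "af"): afs[s]}
            if s == "clinvar":
                branch["rcv"] = {
                    "conditions": {"identifiers": {"omim": str(rng.randint(100_000, 620_000))}}
                }
            body[s] = branch
        docs.append(AnnotationDocument(body=body, entity_id=entity_id))

    return docs, GroundTruth(
        rsid_conflicts=frozenset(rsid_flagged), af_conflicts=frozenset(af_flagged)
    )


# ---------------------------------------------------------------------------
# worked-example bundle: a miniature variant/gene/chem API world
# ---------------------------------------------------------------------------

#: the two variants of the worked example and the genes they fall in
VARIANT_GENES = {"chr6:g.26093141G>A": "3077", "chr12:g.111351981C>T": "4633"}

_VARIANT_CONTEXT = {
    "@context": {
        "dbsnp": {
            "@context": {
                "rsid": {"@id": IRI.DBSNP},
                "gene": {"@context": {"geneid": {"@id": IRI.NCBIGENE}}},
            }
        },
        "clinvar": {
            "@context": {
                "rcv": {
                    "@context": {
                        "conditions": {
                            "@context": {
                                "identifiers": {
                                    "@context": {"omim": {"@id": IRI.OMIM}}
                                }
                            }
                        }
                    }
                }
            }
        },
    }
}

_GENE_CONTEXT = {
    "@context": {
        "entrezgene": {"@id": IRI.NCBIGENE},
        "pathway": {
            "@context": {
                "wikipathways": {"@context": {"id": {"@id": IRI.WIKIPATHWAYS}}}
            }
        },
        "uniprot": {"@context": {"swissprot": {"@id": IRI.UNIPROT}}},
    }
}

_CHEM_CONTEXT = {
    "@context": {
        "drugbank": {
            "@context": {
                "inchi_key": {"@id": IRI.INCHIKEY},
                "targets": {"@context": {"uniprot": {"@id": IRI.UNIPROT}}},
            }
        }
    }
}


def _gene_doc(geneid: str, pathways: list[str], uniprot: str) -> dict:
    return {
        "_id": geneid,
        "entrezgene": int(geneid),
        "pathway": {"wikipathways": [{"id": wp} for wp in pathways]},
        "uniprot": {"swissprot": uniprot},
    }


def _drug_doc(inchikey: str, target: str) -> dict:
    return {
        "_id": inchikey,
        "drugbank": {"inchi_key": inchikey, "targets": {"uniprot": target}},
    }


# gene 3077 sits in two pathways; pathway membership pulls in the synthetic
# partner genes 1111 and 2222, whose proteins are druggable too
_GENES = {
    "3077": _gene_doc("3077", ["WP1111", "WP2222"], "P10001"),
    "4633": _gene_doc("4633", ["WP3333"], "P10002"),
    "1111": _gene_doc("1111", ["WP1111"], "P10003"),
    "2222": _gene_doc("2222", ["WP3333"], "P10004"),
}

_PATHWAY_MEMBERS = {
    "WP1111": ["3077", "1111"],
    "WP2222": ["3077"],
    "WP3333": ["4633", "2222"],
}

_DRUGS = {
    "P10001": [_drug_doc("AAAAAAAAAAAAAA-BBBBBBBBBB-C", "P10001")],
    "P10002": [_drug_doc("DDDDDDDDDDDDDD-EEEEEEEEEE-F", "P10002")],
    "P10003": [
        _drug_doc("GGGGGGGGGGGGGG-HHHHHHHHHH-I", "P10003"),
        _drug_doc("JJJJJJJJJJJJJJ-KKKKKKKKKK-L", "P10003"),
    ],
    "P10004": [_drug_doc("MMMMMMMMMMMMMM-NNNNNNNNNN-O", "P10004")],
}


def worked_example_bundle() -> tuple[
    Registry, dict[str, dict[str, list[dict]]], dict[str, ContextDocument]
]:
    """The offline three-API world: a registry, a document bundle for the
    fixture fetcher, and the per-API JSON-LD contexts.

    Four endpoints model three mock APIs — the gene API is registered
    twice because it answers two differently-typed questions (annotate a
    gene ID; list the genes belonging to a pathway ID), and typed routing
    needs one endpoint per input type.
    """
    registry = Registry(
        endpoints=(
            APIEndpoint(
                name="variant",
                input_type=IRI.HGVS,
                output_types=frozenset({IRI.NCBIGENE, IRI.DBSNP, IRI.OMIM}),
                query_template="https://myvariant.info/v1/variant/{id}",
                context_ref="variant",
                batch_size=10,
            ),
            APIEndpoint(
                name="gene",
                input_type=IRI.NCBIGENE,
                output_types=frozenset({IRI.WIKIPATHWAYS, IRI.UNIPROT}),
                query_template="https://mygene.info/v3/gene/{id}",
                context_ref="gene",
                batch_size=10,
            ),
            APIEndpoint(
                name="pathway",
                input_type=IRI.WIKIPATHWAYS,
                output_types=frozenset({IRI.NCBIGENE}),
                query_template="https://mygene.info/v3/query?q=pathway.wikipathways.id:{id}",
                context_ref="gene",
                batch_size=10,
            ),
            APIEndpoint(
                name="chem",
                input_type=IRI.UNIPROT,
                output_types=frozenset({IRI.INCHIKEY}),
                query_template="https://mychem.info/v1/query?q=drugbank.targets.uniprot:{id}",
                context_ref="chem",
                batch_size=10,
            ),
        )
    )

    variant_docs = {
        hgvs: [
            {
                "_id": hgvs,
                "dbsnp": {"rsid": f"rs10{i}", "gene": {"geneid": int(gene)}},
                "clinvar": {
                    "rcv": {"conditions": {"identifiers": {"omim": f"61{i}000"}}}
                },
            }
        ]
        for i, (hgvs, gene) in enumerate(VARIANT_GENES.items())
    }

    bundle: dict[str, dict[str, list[dict]]] = {
        "variant": variant_docs,
        "gene": {gid: [doc] for gid, doc in _GENES.items()},
        "pathway": {
            wp: [_GENES[gid] for gid in members]
            for wp, members in _PATHWAY_MEMBERS.items()
        },
        "chem": dict(_DRUGS),
    }

    contexts = {
        "variant": load_context(_VARIANT_CONTEXT, origin="annolink.fixtures.variant"),
        "gene": load_context(_GENE_CONTEXT, origin="annolink.fixtures.gene"),
        "chem": load_context(_CHEM_CONTEXT, origin="annolink.fixtures.chem"),
    }
    return registry, bundle, contexts


def variant_to_drug_route() -> Route:
    """The five-leg drug-discovery chain: variant HGVS ID → NCBI Gene ID →
    WikiPathways ID → member NCBI Gene IDs → UniProt ID → drug InChIKey."""
    return Route(
        legs=(
            RouteLeg(IRI.HGVS, IRI.NCBIGENE, "variant"),
            RouteLeg(IRI.NCBIGENE, IRI.WIKIPATHWAYS, "gene"),
            RouteLeg(IRI.WIKIPATHWAYS, IRI.NCBIGENE, "pathway"),
            RouteLeg(IRI.NCBIGENE, IRI.UNIPROT, "gene"),
            RouteLeg(IRI.UNIPROT, IRI.INCHIKEY, "chem"),
        )
    )
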