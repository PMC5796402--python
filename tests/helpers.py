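"""Shared oracles and randomized-input generators for the test suite.

The oracles here deliberately take a different computational route from
the library code they check: extraction is re-done as a whole-tree walk
testing every leaf's full path, and route search is re-done as exhaustive
chain enumeration.
"""

from __future__ import annotations

import random
from itertools import product

from annolink.context import ContextDocument, FieldPath, load_context, uri_for_path
from annolink.registry import APIEndpoint, Registry

_SCALARS = (str, int, float, bool)

DBSNP = "http://identifiers.org/dbsnp/"
OMIM = "http://identifiers.org/omim/"
NCBIGENE = "http://identifiers.org/ncbigene/"
AF = "http://example.org/vocab/allele_frequency"

#: a MyVariant-style context rich enough to exercise shared IRIs (three
#: sources report the rsid concept), deep nesting and sibling branches
RICH_CONTEXT = {
    "@context": {
        "dbsnp": {
            "@context": {
                "rsid": {"@id": DBSNP},
                "alt_freq": {"@id": AF},
                "gene": {"@context": {"geneid": {"@id": NCBIGENE}}},
            }
        },
        "dbnsfp": {
            "@context": {"rsid": {"@id": DBSNP}, "af": {"@id": AF}}
        },
        "clinvar": {
            "@context": {
                "rsid": {"@id": DBSNP},
                "rcv": {
                    "@context": {
                        "conditions": {
                            "@context": {
                                "identifiers": {
                                    "@context": {"omim": {"@id": OMIM}}
                                }
                            }
                        }
                    }
                },
            }
        },
    }
}

RICH_URIS = (DBSNP, OMIM, NCBIGENE, AF)


def rich_context() -> ContextDocument:
    return load_context(RICH_CONTEXT)


def random_document(rng: random.Random) -> dict:
    """A random annotation document loosely following RICH_CONTEXT: some
    branches present, some absent, values sometimes arrays, plus unmapped
    decoy fields that must never contribute to extraction."""
    body: dict = {}
    if rng.random() < 0.5:
        body["_id"] = f"chr{rng.randint(1, 22)}:g.{rng.randint(1, 10**8)}A>G"
    if rng.random() < 0.9:
        dbsnp: dict = {"rsid": f"rs{rng.randint(1, 10**7)}"}
        if rng.random() < 0.7:
            dbsnp["alt_freq"] = round(rng.random(), 4)
        if rng.random() < 0.6:
            geneid = rng.randint(1, 10**5)
            dbsnp["gene"] = (
                {"geneid": geneid}
                if rng.random() < 0.5
                else [{"geneid": geneid}, {"geneid": rng.randint(1, 10**5)}]
            )
        if rng.random() < 0.3:
            dbsnp["decoy"] = "not-mapped"
        body["dbsnp"] = dbsnp
    if rng.random() < 0.7:
        rsid = (
            f"rs{rng.randint(1, 10**7)}"
            if rng.random() < 0.5
            else body.get("dbsnp", {}).get("rsid", "rs1")
        )
        body["dbnsfp"] = {"rsid": rsid, "af": round(rng.random(), 4)}
    if rng.random() < 0.6:
        conditions = [
            {"identifiers": {"omim": str(rng.randint(100000, 620000))}}
            for _ in range(rng.randint(1, 3))
        ]
        body["clinvar"] = {
            "rsid": f"rs{rng.randint(1, 10**7)}",
            "rcv": {"conditions": conditions}
            if rng.random() < 0.5
            else [{"conditions": conditions}, {"conditions": []}],
        }
    if rng.random() < 0.4:
        body["cadd"] = {"phred": round(rng.random() * 50, 2)}  # unmapped source
    return body


def brute_force_extract(body: dict, ctx: ContextDocument, concept: str) -> list:
    """Independent extraction oracle: walk EVERY leaf of the document and
    keep those whose full dotted path maps to *concept*."""
    out: list = []

    def walk(node: object, prefix: tuple[str, ...]) -> None:
        if isinstance(node, dict):
            for key, value in node.items():
                if key and "." not in key:
                    walk(value, prefix + (key,))
        elif isinstance(node, list):
            for item in node:
                walk(item, prefix)
        elif isinstance(node, _SCALARS) and prefix:
            if uri_for_path(ctx, FieldPath(prefix)) == concept:
                out.append(node)

    walk(body, ())
    return out


def count_mapped_leaves(body: dict, ctx: ContextDocument) -> int:
    """Independent counting oracle for quad expansion."""
    return sum(len(brute_force_extract(body, ctx, uri)) for uri in RICH_URIS)


def random_registry(rng: random.Random, max_endpoints: int = 6) -> Registry:
    """A random registry over a small concept pool, for route-search tests."""
    concepts = [f"http://example.org/type/{c}" for c in "abcdefgh"]
    n = rng.randint(1, max_endpoints)
    endpoints = []
    for i in range(n):
        input_type = rng.choice(concepts)
        outputs = rng.sample([c for c in concepts if c != input_type], rng.randint(1, 3))
        endpoints.append(
            APIEndpoint(
                name=f"ep{i}",
                input_type=input_type,
                output_types=frozenset(outputs),
                query_template="https://example.org/{id}",
            )
        )
    return Registry(endpoints=tuple(endpoints))


def enumerate_routes(
    reg: Registry, input_type: str, output_type: str, max_hops: int
) -> list[list[tuple[int, str, str, str]]]:
    """Every chain of ≤ max_hops legs from input to output, exhaustively.

    Each leg is (endpoint registry index, input type, output type,
    endpoint name); the lexicographic order of [(index, output type), ...]
    defines the deterministic tie-break among equally short chains.
    """
    results: list[list[tuple[int, str, str, str]]] = []

    def extend(current: str, chain: list[tuple[int, str, str, str]]) -> None:
        if len(chain) >= max_hops:
            return
        for idx, ep in enumerate(reg.endpoints):
            if ep.input_type != current:
                continue
            for out in sorted(ep.output_types):
                leg = (idx, current, out, ep.name)
                if out == output_type:
                    results.append(chain + [leg])
                extend(out, chain + [leg])

    extend(input_type, [])
    return results


def best_route_by_enumeration(
    reg: Registry, input_type: str, output_type: str, max_hops: int
):
    """Shortest chain, earliest-registered tie-break, or None."""
    if input_type == output_type:
        return []
    chains = enumerate_routes(reg, input_type, output_type, max_hops)
    if not chains:
        return None
    shortest = min(len(c) for c in chains)
    return min(
        (c for c in chains if len(c) == shortest),
        key=lambda c: [(idx, out) for idx, _inp, out, _name in c],
    )
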