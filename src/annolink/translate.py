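"""Execute single-leg and multi-leg identifier translations.

This is the workhorse behind workflows like "given these two missense
variants, which drugs target the affected pathways?": a list of input IDs
is pushed through an endpoint (or a whole route of endpoints), fetching the
annotation document for each ID and extracting the output concept's values
through the endpoint's JSON-LD context.  Document retrieval is abstracted
behind a fetcher contract so the same code runs against live HTTP APIs or
a packaged offline document bundle.

Pooling intermediate IDs between route legs would lose per-input
attribution, so every produced value is recorded with full provenance:
which original input, which leg, which endpoint and which immediate input
ID yielded it.
"""

from __future__ import annotations

import json
import urllib.request
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence
from urllib.parse import quote

from .context import ContextDocument
from .errors import RoutingError, TransportError
from .registry import APIEndpoint, Registry, Route, RouteLeg, find_endpoints
from .semantic import AnnotationDocument, extract_values, render_scalar

__all__ = [
    "Fetcher",
    "FixtureFetcher",
    "LiveFetcher",
    "ProvenanceEntry",
    "TranslationResult",
    "translate_ids",
    "execute_route",
]


class Fetcher(Protocol):
    """Contract for document retrieval.

    Implementations return an entry (possibly an empty list) for every
    requested ID and never invent IDs that were not asked for.
    """

    def fetch(
        self, endpoint: APIEndpoint, ids: Sequence[str]
    ) -> Mapping[str, list[AnnotationDocument]]: ...


class FixtureFetcher:
    """Offline fetcher backed by a bundle of pre-built documents.

    *bundle* maps endpoint name → {query ID → list of raw JSON documents}.
    Deterministic by construction: the same bundle always returns the same
    documents, which makes multi-leg translations byte-reproducible.
    """

    def __init__(self, bundle: Mapping[str, Mapping[str, list[dict]]]):
        self._bundle = bundle

    def fetch(
        self, endpoint: APIEndpoint, ids: Sequence[str]
    ) -> dict[str, list[AnnotationDocument]]:
        docs_by_id = self._bundle.get(endpoint.name, {})
        return {
            i: [AnnotationDocument.from_json(d) for d in docs_by_id.get(i, [])]
            for i in ids
        }


class LiveFetcher:
    """HTTP fetcher filling the endpoint's query template verbatim with the
    URL-encoded ID.  Opt-in only — never exercised by the test suite."""

    def __init__(self, timeout: float = 10.0, retries: int = 2):
        self.timeout = timeout
        self.retries = retries

    def _get(self, url: str) -> object:
        last: Optional[Exception] = None
        for _ in range(self.retries + 1):
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                    return json.loads(resp.read().decode("utf-8"))
            except Exception as exc:  # noqa: BLE001 — retried, then re-raised
                last = exc
        raise last  # type: ignore[misc]

    def fetch(
        self, endpoint: APIEndpoint, ids: Sequence[str]
    ) -> dict[str, list[AnnotationDocument]]:
        out: dict[str, list[AnnotationDocument]] = {}
        for i in ids:
            url = endpoint.query_template.replace("{id}", quote(str(i), safe=""))
            try:
                data = self._get(url)
            except Exception as exc:
                raise TransportError(endpoint.name, [i], exc) from exc
            docs = data if isinstance(data, list) else [data]
            out[i] = [AnnotationDocument.from_json(d) for d in docs if isinstance(d, dict)]
        return out


@dataclass(frozen=True)
class ProvenanceEntry:
    """Back-pointer for one produced value: the ID that entered the leg,
    the leg index within the route, the endpoint used, and the value
    extracted.  Chaining entries across consecutive legs (value of leg k =
    leg_input of leg k+1) reconstructs the full original-input→output
    attribution."""

    input_id: str
    leg_index: int
    endpoint: str
    leg_input: str
    value: str


@dataclass
class TranslationResult:
    """Output of a translation: per original input ID the ordered set of
    output values (first-occurrence order, deduplicated), plus provenance
    for every (input, value) pair."""

    mapping: dict[str, list[str]] = field(default_factory=dict)
    provenance: list[ProvenanceEntry] = field(default_factory=list)

    def values_for(self, input_id: str) -> list[str]:
        return self.mapping.get(input_id, [])

    def to_tsv(self) -> str:
        lines = ["input_id\toutput_id"]
        for input_id, values in self.mapping.items():
            for v in values:
                lines.append(f"{input_id}\t{v}")
        return "".join(line + "\n" for line in lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mapping": self.mapping,
                "provenance": [vars(p) for p in self.provenance],
            },
            indent=2,
            sort_keys=True,
        )


def _dedup(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for i in ids:
        if i not in seen:
            seen.add(i)
            out.append(i)
    return out


def _batches(ids: Sequence[str], size: int):
    for start in range(0, len(ids), size):
        yield ids[start : start + size]


def _contexts_or_fail(
    endpoint: APIEndpoint, contexts: Mapping[str, ContextDocument]
) -> ContextDocument:
    ref = endpoint.context_ref or endpoint.name
    if ref not in contexts:
        raise RoutingError(
            endpoint.input_type,
            "?",
            f"no context registered under {ref!r} for endpoint {endpoint.name!r}",
        )
    return contexts[ref]


def translate_ids(
    ids: Sequence[str],
    input_type: str,
    output_type: str,
    reg: Registry,
    fetch: Fetcher,
    contexts: Mapping[str, ContextDocument],
    leg_index: int = 0,
) -> TranslationResult:
    """Translate IDs one leg: pick the first capable endpoint, fetch each
    ID's documents (batched per the endpoint's batch size) and extract the
    output concept's values through the endpoint's context.

    Output values are stringified (so the gene ID ``3077`` and ``"3077"``
    pool identically), deduplicated and order-stable.  IDs with no hits map
    to empty lists.  Raises :class:`RoutingError` when no endpoint can
    perform the conversion and :class:`TransportError` on fetch failure.
    """
    candidates = find_endpoints(reg, input_type, output_type)
    if not candidates:
        raise RoutingError(input_type, output_type)
    endpoint = candidates[0]
    ctx = _contexts_or_fail(endpoint, contexts)
    ids = _dedup([str(i) for i in ids])

    result = TranslationResult(mapping={i: [] for i in ids})
    for batch in _batches(ids, endpoint.batch_size):
        try:
            docs_by_id = fetch.fetch(endpoint, batch)
        except TransportError:
            raise
        except Exception as exc:
            raise TransportError(endpoint.name, list(batch), exc) from exc
        for input_id in batch:
            for doc in docs_by_id.get(input_id, []):
                for _path, value in extract_values(doc, ctx, output_type):
                    rendered = render_scalar(value)
                    if rendered not in result.mapping[input_id]:
                        result.mapping[input_id].append(rendered)
                    result.provenance.append(
                        ProvenanceEntry(
                            input_id=input_id,
                            leg_index=leg_index,
                            endpoint=endpoint.name,
                            leg_input=input_id,
                            value=rendered,
                        )
                    )
    return result


def execute_route(
    ids: Sequence[str],
    route: Route,
    reg: Registry,
    fetch: Fetcher,
    contexts: Mapping[str, ContextDocument],
) -> TranslationResult:
    """Execute a multi-leg route: feed each leg's pooled outputs to the
    next leg, keeping the final mapping keyed by the ORIGINAL input IDs.

    Equivalent to composing :func:`translate_ids` leg by leg; provenance
    records every leg traversed, including intermediate IDs, so each final
    value can be traced back through the whole chain.  A leg yielding zero
    intermediate IDs simply produces empty final sets.
    """
    route.validate(reg)
    original = _dedup([str(i) for i in ids])

    # current frontier per original ID; a zero-leg route is the identity
    frontier: dict[str, list[str]] = {i: [i] for i in original}
    all_prov: list[ProvenanceEntry] = []

    for leg_index, leg in enumerate(route.legs):
        pooled = _dedup([v for i in original for v in frontier[i]])
        try:
            step = translate_ids(
                pooled, leg.input_type, leg.output_type, reg, fetch, contexts,
                leg_index=leg_index,
            )
        except TransportError as exc:
            raise TransportError(
                exc.endpoint_name, exc.batch,
                Exception(f"while executing route leg {leg_index}"),
            ) from exc
        # re-attribute pooled outputs to each original input
        next_frontier: dict[str, list[str]] = {}
        for i in original:
            outs: list[str] = []
            for mid in frontier[i]:
                for v in step.values_for(mid):
                    if v not in outs:
                        outs.append(v)
            next_frontier[i] = outs
        reachable = {mid for i in original for mid in frontier[i]}
        for p in step.provenance:
            if p.leg_input in reachable:
                all_prov.append(p)
        frontier = next_frontier

    return TranslationResult(mapping=frontier, provenance=all_prov)
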