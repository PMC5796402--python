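"""A typed API registry and route discovery over concept IRIs.

Each endpoint is described by the concept IRI it accepts as input, the
concept IRIs extractable from its response documents, and a query template.
Given that typing, converting one kind of identifier into another reduces
to graph search: find an endpoint (or chain of endpoints) whose input type
matches what you have and whose output types contain what you want —
e.g. HGVS variant ID → NCBI Gene ID via a variant-annotation endpoint,
then NCBI Gene ID → UniProt accession via a gene-annotation endpoint.

Route search is breadth-first over concept IRIs with registry-order
tie-breaking, so the shortest chain wins and results are deterministic.
Longer deliberately-redundant chains (such as a pathway-membership
expansion that revisits the gene ID type) are first-class too: construct a
:class:`Route` leg by leg and validate it with :meth:`Route.validate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import yaml

from .errors import RegistryError
from .context import _is_absolute_iri

__all__ = [
    "APIEndpoint",
    "Registry",
    "Route",
    "RouteLeg",
    "load_registry",
    "find_endpoints",
    "find_route",
]

DEFAULT_MAX_HOPS = 3


@dataclass(frozen=True)
class APIEndpoint:
    """A typed description of one API endpoint."""

    name: str
    input_type: str
    output_types: frozenset[str]
    query_template: str
    context_ref: Optional[str] = None
    batch_size: int = 100

    def __post_init__(self) -> None:
        object.__setattr__(self, "output_types", frozenset(self.output_types))
        if not self.name:
            raise RegistryError("endpoint name must be non-empty")
        if not _is_absolute_iri(self.input_type):
            raise RegistryError(
                f"endpoint {self.name!r}: input_type {self.input_type!r} is not an absolute IRI"
            )
        if not self.output_types:
            raise RegistryError(f"endpoint {self.name!r}: output_types must be non-empty")
        for iri in self.output_types:
            if not _is_absolute_iri(iri):
                raise RegistryError(
                    f"endpoint {self.name!r}: output type {iri!r} is not an absolute IRI"
                )
        if "{id}" not in self.query_template and "{ids}" not in self.query_template:
            raise RegistryError(
                f"endpoint {self.name!r}: query_template must contain an "
                "'{id}' (or '{ids}') placeholder"
            )
        if self.batch_size < 1:
            raise RegistryError(f"endpoint {self.name!r}: batch_size must be positive")


@dataclass(frozen=True)
class Registry:
    """An ordered collection of endpoints with unique names."""

    endpoints: tuple[APIEndpoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "endpoints", tuple(self.endpoints))
        seen: set[str] = set()
        for ep in self.endpoints:
            if ep.name in seen:
                raise RegistryError(f"duplicate endpoint name {ep.name!r}")
            seen.add(ep.name)

    def __len__(self) -> int:
        return len(self.endpoints)

    def __getitem__(self, name: str) -> APIEndpoint:
        for ep in self.endpoints:
            if ep.name == name:
                return ep
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(ep.name == name for ep in self.endpoints)


@dataclass(frozen=True)
class RouteLeg:
    input_type: str
    output_type: str
    endpoint: str


@dataclass(frozen=True)
class Route:
    """An ordered chain of translation legs; consecutive legs must chain
    (each leg's output type is the next leg's input type)."""

    legs: tuple[RouteLeg, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "legs",
            tuple(leg if isinstance(leg, RouteLeg) else RouteLeg(*leg) for leg in self.legs),
        )
        for a, b in zip(self.legs, self.legs[1:]):
            if a.output_type != b.input_type:
                raise RegistryError(
                    f"route legs do not chain: {a.output_type!r} != {b.input_type!r}"
                )

    def __len__(self) -> int:
        return len(self.legs)

    def validate(self, reg: Registry) -> None:
        """Check every leg's endpoint exists, accepts the leg's input type
        and emits its output type."""
        for i, leg in enumerate(self.legs):
            if leg.endpoint not in reg:
                raise RegistryError(f"leg {i}: unknown endpoint {leg.endpoint!r}")
            ep = reg[leg.endpoint]
            if ep.input_type != leg.input_type:
                raise RegistryError(
                    f"leg {i}: endpoint {ep.name!r} accepts <{ep.input_type}>, "
                    f"not <{leg.input_type}>"
                )
            if leg.output_type not in ep.output_types:
                raise RegistryError(
                    f"leg {i}: endpoint {ep.name!r} does not emit <{leg.output_type}>"
                )


def load_registry(text: str | bytes | list | dict) -> Registry:
    """Parse a registry config (JSON or YAML).

    The config is either a bare list of endpoint objects or an object with
    an ``"endpoints"`` list; each endpoint object carries ``name``,
    ``input_type``, ``output_types``, ``query_template`` and optionally
    ``context`` and ``batch_size``.  All endpoint invariants are validated;
    errors name the offending endpoint.
    """
    if isinstance(text, (str, bytes)):
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise RegistryError(f"malformed registry config: {exc}") from exc
    else:
        data = text
    if isinstance(data, dict):
        data = data.get("endpoints", [])
    if data is None:
        data = []
    if not isinstance(data, list):
        raise RegistryError("registry config must be a list of endpoints")
    endpoints = []
    for item in data:
        if not isinstance(item, dict):
            raise RegistryError("each endpoint entry must be an object")
        try:
            endpoints.append(
                APIEndpoint(
                    name=item.get("name", ""),
                    input_type=item.get("input_type", ""),
                    output_types=frozenset(item.get("output_types", ())),
                    query_template=item.get("query_template", ""),
                    context_ref=item.get("context"),
                    batch_size=int(item.get("batch_size", 100)),
                )
            )
        except RegistryError:
            raise
        except (TypeError, ValueError) as exc:
            raise RegistryError(
                f"invalid endpoint entry {item.get('name', '<unnamed>')!r}: {exc}"
            ) from exc
    return Registry(endpoints=tuple(endpoints))


def find_endpoints(reg: Registry, input_type: str, output_type: str) -> list[APIEndpoint]:
    """All endpoints converting *input_type* to *output_type*, in registry
    order; empty when none match."""
    return [
        ep
        for ep in reg.endpoints
        if ep.input_type == input_type and output_type in ep.output_types
    ]


def find_route(
    reg: Registry, input_type: str, output_type: str, max_hops: int = DEFAULT_MAX_HOPS
) -> Optional[Route]:
    """Shortest chain of legs from *input_type* to *output_type*.

    Breadth-first search over concept IRIs; among equally short chains the
    one using earliest-registered endpoints wins, so results depend only on
    the registry text.  Returns ``None`` when the output type is not
    reachable within *max_hops* legs; a zero-leg route when the two types
    are equal.
    """
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    if input_type == output_type:
        return Route(legs=())

    # backward BFS: minimal number of legs from each concept to the goal
    dist: dict[str, int] = {output_type: 0}
    frontier = {output_type}
    for d in range(1, max_hops + 1):
        nxt = {
            ep.input_type
            for ep in reg.endpoints
            if ep.input_type not in dist and ep.output_types & frontier
        }
        for t in nxt:
            dist[t] = d
        if not nxt:
            break
        frontier = nxt
    length = dist.get(input_type)
    if length is None or length > max_hops:
        return None

    # depth-limited DFS at the exact minimal length, scanning endpoints in
    # registry order (and an endpoint's output types in sorted order), so
    # the first chain found is the lexicographically earliest-registered
    # one among all minimal-length chains; the distance map prunes every
    # branch that cannot finish in time.
    def dfs(current: str, remaining: int) -> Optional[tuple[RouteLeg, ...]]:
        if remaining == 0:
            return () if current == output_type else None
        for ep in reg.endpoints:
            if ep.input_type != current:
                continue
            for out in sorted(ep.output_types):
                if dist.get(out, max_hops + 1) <= remaining - 1:
                    rest = dfs(out, remaining - 1)
                    if rest is not None:
                        return (RouteLeg(current, out, ep.name),) + rest
        return None

    legs = dfs(input_type, length)
    return Route(legs=legs) if legs is not None else None
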