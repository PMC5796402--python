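"""JSON-LD context handling for JSON-based annotation APIs.

A *context* maps the field names of an API's JSON response documents to
concept IRIs — in the BioThings convention, identifiers.org URIs such as
``http://identifiers.org/dbsnp/``.  Nested objects in the response are
described by nested ``@context`` blocks, so a context is a finite tree of
term definitions whose IRI-bearing leaves correspond to dotted field paths
like ``clinvar.rcv.conditions.identifiers.omim``.

Only the JSON-LD 1.0 subset actually used by these contexts is supported:
a term may map to an ``{"@id": <absolute IRI>}`` object (or an IRI string
shorthand) and/or carry a nested ``"@context"`` object.  Every other
JSON-LD keyword (``@type``, ``@container``, ``@vocab``, ``@base``,
``@reverse``, ...) is rejected loudly rather than silently ignored, so a
context that relies on unsupported semantics cannot be misread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional
from urllib.parse import urlsplit

from .errors import ContextError

__all__ = [
    "TermDefinition",
    "ContextDocument",
    "FieldPath",
    "SemanticMapping",
    "load_context",
    "load_context_file",
    "invert_context",
    "uri_for_path",
]

#: JSON-LD keywords that are valid in full JSON-LD but outside the dialect
#: handled here.  They are rejected explicitly (fail loudly, never guess).
_UNSUPPORTED_KEYWORDS = frozenset(
    {"@type", "@container", "@vocab", "@base", "@reverse", "@language",
     "@version", "@graph", "@list", "@set", "@index", "@nest", "@prefix",
     "@protected", "@propagate", "@import"}
)


def _is_absolute_iri(value: str) -> bool:
    """An IRI is absolute when it carries a scheme (RFC 3987)."""
    if not isinstance(value, str) or not value:
        return False
    parts = urlsplit(value)
    return bool(parts.scheme)


@dataclass(frozen=True)
class TermDefinition:
    """One term of a context: an optional leaf IRI and/or a nested context.

    At least one of *iri* / *children* is present; both may be (a term can
    name a concept and still scope a sub-context for its object value).
    """

    iri: Optional[str] = None
    children: Optional[Mapping[str, "TermDefinition"]] = None

    def __post_init__(self) -> None:
        if self.iri is None and self.children is None:
            raise ContextError("term definition carries neither an IRI nor children")
        if self.iri is not None and not _is_absolute_iri(self.iri):
            raise ContextError(f"IRI {self.iri!r} is not absolute")


@dataclass(frozen=True)
class ContextDocument:
    """A parsed JSON-LD context: a finite tree of term definitions."""

    terms: Mapping[str, TermDefinition]
    origin: Optional[str] = None

    def walk(self) -> Iterator[tuple["FieldPath", TermDefinition]]:
        """Yield every term definition with its full path, pre-order."""

        def _walk(prefix: tuple[str, ...], terms: Mapping[str, TermDefinition]):
            for name, term in terms.items():
                path = prefix + (name,)
                yield FieldPath(path), term
                if term.children:
                    yield from _walk(path, term.children)

        yield from _walk((), self.terms)


@dataclass(frozen=True)
class FieldPath:
    """A dotted field path into a JSON document, e.g. ``dbsnp.rsid``."""

    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("field path needs at least one segment")
        for seg in self.segments:
            if not seg:
                raise ValueError("field path segment must be non-empty")
            if "." in seg:
                raise ValueError(f"field path segment {seg!r} contains '.'")
        # normalize to a plain tuple even if a list sneaks in
        object.__setattr__(self, "segments", tuple(self.segments))

    @classmethod
    def parse(cls, dotted: str) -> "FieldPath":
        return cls(tuple(dotted.split(".")))

    def __str__(self) -> str:
        return ".".join(self.segments)

    def __lt__(self, other: "FieldPath") -> bool:
        return self.segments < other.segments


@dataclass(frozen=True)
class SemanticMapping:
    """Inverted context: concept IRI → all field paths carrying it."""

    by_iri: Mapping[str, tuple[FieldPath, ...]]

    def paths_for(self, iri: str) -> tuple[FieldPath, ...]:
        return self.by_iri.get(iri, ())

    def __contains__(self, iri: str) -> bool:
        return iri in self.by_iri


def _parse_terms(obj: object, where: str) -> dict[str, TermDefinition]:
    if not isinstance(obj, dict):
        raise ContextError(f"context at {where!r} is not a JSON object")
    terms: dict[str, TermDefinition] = {}
    for name, value in obj.items():
        if name in _UNSUPPORTED_KEYWORDS:
            raise ContextError(
                f"unsupported JSON-LD keyword {name!r} at {where!r}; "
                "only '@id' term maps and nested '@context' blocks are handled"
            )
        if name.startswith("@"):
            raise ContextError(f"unexpected keyword {name!r} at {where!r}")
        if not name:
            raise ContextError(f"empty term name at {where!r}")
        if "." in name:
            raise ContextError(
                f"term name {name!r} at {where!r} contains '.', which is "
                "ambiguous with dotted path rendering"
            )
        here = f"{where}.{name}" if where else name
        terms[name] = _parse_term(value, here)
    return terms


def _parse_term(value: object, where: str) -> TermDefinition:
    if isinstance(value, str):
        # string shorthand: "term": "http://..."
        if not _is_absolute_iri(value):
            raise ContextError(f"term {where!r} maps to non-absolute IRI {value!r}")
        return TermDefinition(iri=value)
    if not isinstance(value, dict):
        raise ContextError(f"term {where!r} definition must be an object or IRI string")
    iri: Optional[str] = None
    children: Optional[dict[str, TermDefinition]] = None
    for key, sub in value.items():
        if key == "@id":
            if not isinstance(sub, str) or not _is_absolute_iri(sub):
                raise ContextError(f"term {where!r} has non-absolute '@id' {sub!r}")
            iri = sub
        elif key == "@context":
            children = _parse_terms(sub, where)
        elif key in _UNSUPPORTED_KEYWORDS:
            raise ContextError(
                f"unsupported JSON-LD keyword {key!r} in term {where!r}"
            )
        else:
            raise ContextError(f"unexpected key {key!r} in term {where!r}")
    if iri is None and children is None:
        raise ContextError(f"term {where!r} defines neither '@id' nor '@context'")
    return TermDefinition(iri=iri, children=children)


def load_context(text: str | bytes | dict, origin: Optional[str] = None) -> ContextDocument:
    """Parse a JSON-LD context from JSON text (or an already-decoded object).

    The document may wrap the term map in a top-level ``"@context"`` member
    (the published layout) or *be* the term map itself.  Terms absent from
    the context are simply absent — nothing is synthesized.

    Raises
    ------
    ContextError
        On malformed JSON, non-absolute leaf IRIs (naming the offending
        term), term names containing ``.``, or unsupported JSON-LD keywords.
    """
    if isinstance(text, (str, bytes)):
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ContextError(f"malformed JSON context: {exc}") from exc
    else:
        data = text
    if not isinstance(data, dict):
        raise ContextError("context document root must be a JSON object")
    if "@context" in data:
        data = data["@context"]
    return ContextDocument(terms=_parse_terms(data, ""), origin=origin)


def load_context_file(path: str) -> ContextDocument:
    """Load a context from a local JSON file (offline by design)."""
    with open(path, "r", encoding="utf-8") as fh:
        return load_context(fh.read(), origin=path)


def invert_context(ctx: ContextDocument) -> SemanticMapping:
    """Invert a context into concept IRI → field paths.

    Every IRI-bearing node contributes its path; paths sharing an IRI are
    all listed, in context (pre-order) walk order.  An empty context yields
    an empty mapping.
    """
    by_iri: dict[str, list[FieldPath]] = {}
    for path, term in ctx.walk():
        if term.iri is not None:
            by_iri.setdefault(term.iri, []).append(path)
    return SemanticMapping(by_iri={iri: tuple(paths) for iri, paths in by_iri.items()})


def uri_for_path(ctx: ContextDocument, path: FieldPath | str) -> Optional[str]:
    """Return the concept IRI a field path is mapped to, or ``None``.

    >>> ctx = load_context('{"@context":{"dbsnp":{"@context":'
    ...                    '{"rsid":{"@id":"http://identifiers.org/dbsnp/"}}}}}')
    >>> uri_for_path(ctx, "dbsnp.rsid")
    'http://identifiers.org/dbsnp/'
    """
    if isinstance(path, str):
        path = FieldPath.parse(path)
    terms: Optional[Mapping[str, TermDefinition]] = ctx.terms
    term: Optional[TermDefinition] = None
    for seg in path.segments:
        if terms is None or seg not in terms:
            return None
        term = terms[seg]
        terms = term.children
    return term.iri if term is not None else None
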