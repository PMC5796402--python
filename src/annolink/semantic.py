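"""Apply a JSON-LD context to annotation documents.

Three operations hang together here: *resolve_path* descends a dotted field
path through a JSON tree (traversing arrays element-wise); *extract_values*
answers data-structure-neutral queries — give me every value of the concept
``http://identifiers.org/omim/`` regardless of which source branch carries
it; and *expand_to_quads* / *write_nquads* turn a document plus its context
into RDF statements for integration with the Linked Data cloud.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional
from urllib.parse import quote

from .context import ContextDocument, FieldPath, invert_context
from .errors import AnnolinkError

__all__ = [
    "AnnotationDocument",
    "Quad",
    "resolve_path",
    "extract_values",
    "expand_to_quads",
    "write_nquads",
    "render_scalar",
]

_SCALARS = (str, int, float, bool)

#: default base for minting subject IRIs from a document's entity ID
DEFAULT_SUBJECT_PREFIX = "http://example.org/entity/"


@dataclass(frozen=True)
class AnnotationDocument:
    """One annotation object, e.g. the response for a variant HGVS ID.

    The body is the JSON object tree as returned by an API; *entity_id* is
    the document key (the ``_id`` field in BioThings-style documents, e.g.
    an HGVS string like ``chr6:g.26093141G>A``).
    """

    body: dict
    entity_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not isinstance(self.body, dict):
            raise AnnolinkError("annotation document body must be a JSON object")

    @classmethod
    def from_json(cls, obj: dict | str | bytes) -> "AnnotationDocument":
        """Build from a decoded JSON object or JSON text; ``_id`` becomes
        the entity ID (and stays in the body, where it is simply an
        unmapped leaf unless the context says otherwise)."""
        if isinstance(obj, (str, bytes)):
            obj = json.loads(obj)
        if not isinstance(obj, dict):
            raise AnnolinkError("annotation document root must be a JSON object")
        eid = obj.get("_id")
        return cls(body=obj, entity_id=str(eid) if eid is not None else None)


@dataclass(frozen=True)
class Quad:
    """One RDF statement. *subject* is an IRI or a blank-node label
    (``_:b0``); *object* is a plain string literal unless *object_is_iri*."""

    subject: str
    predicate: str
    object: str
    object_is_iri: bool = False
    graph: Optional[str] = None


def render_scalar(value: object) -> str:
    """Render a JSON scalar as the literal string used in quads and ID
    pooling: numbers via their shortest decimal form (so the gene ID 3077
    and the string "3077" compare equal), booleans as JSON booleans."""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _iter_scalars(node: object) -> Iterator[object]:
    """All scalars under *node*, arrays traversed element-wise in order."""
    if isinstance(node, _SCALARS):
        yield node
    elif isinstance(node, list):
        for item in node:
            yield from _iter_scalars(item)
    # dicts and None contribute nothing once the path is exhausted


def _descend(node: object, segments: tuple[str, ...]) -> Iterator[object]:
    if not segments:
        yield from _iter_scalars(node)
        return
    if isinstance(node, dict):
        if segments[0] in node:
            yield from _descend(node[segments[0]], segments[1:])
    elif isinstance(node, list):
        for item in node:
            yield from _descend(item, segments)


def resolve_path(doc: AnnotationDocument, path: FieldPath | str) -> list[object]:
    """All scalar values reached by descending *path* through the body.

    Arrays encountered at any level are traversed element-wise; values come
    back in document order; missing branches contribute nothing.

    >>> doc = AnnotationDocument({"dbsnp": {"gene": {"geneid": 3077}}})
    >>> resolve_path(doc, "dbsnp.gene.geneid")
    [3077]
    """
    if isinstance(path, str):
        path = FieldPath.parse(path)
    return list(_descend(doc.body, path.segments))


def extract_values(
    doc: AnnotationDocument, ctx: ContextDocument, concept: str
) -> list[tuple[FieldPath, object]]:
    """Query a document by concept IRI instead of by field location.

    Returns every (path, value) pair for every field path the context maps
    to *concept* — e.g. querying ``http://identifiers.org/dbsnp/`` returns
    the rsid reported by every source branch that carries one.  An unknown
    concept yields an empty list.
    """
    mapping = invert_context(ctx)
    out: list[tuple[FieldPath, object]] = []
    for path in mapping.paths_for(concept):
        for value in resolve_path(doc, path):
            out.append((path, value))
    return out


def expand_to_quads(
    doc: AnnotationDocument,
    ctx: ContextDocument,
    subject_prefix: str = DEFAULT_SUBJECT_PREFIX,
    blank_index: int = 0,
) -> list[Quad]:
    """Expand a document into one quad per context-mapped scalar leaf.

    The predicate is the leaf's concept IRI and the object is the scalar
    rendered as a plain string literal.  Leaves whose path the context does
    not map are dropped.  The subject is minted as *subject_prefix* +
    percent-encoded entity ID when the document has one, otherwise a blank
    node ``_:b<blank_index>`` (callers expanding a corpus pass the
    document's ingestion index to keep labels distinct and deterministic).
    """
    if doc.entity_id is not None:
        subject = subject_prefix + quote(doc.entity_id, safe="")
    else:
        subject = f"_:b{blank_index}"
    # walk the document tree once, in document order, testing each leaf path
    quads = [
        Quad(subject=subject, predicate=iri, object=render_scalar(value))
        for iri, value in _walk_mapped_leaves(doc.body, (), ctx)
    ]
    return quads


def _walk_mapped_leaves(
    node: object, prefix: tuple[str, ...], ctx: ContextDocument
) -> Iterator[tuple[str, object]]:
    from .context import uri_for_path

    if isinstance(node, dict):
        for key, value in node.items():
            if "." in key or not key:
                continue  # cannot correspond to any context term
            yield from _walk_mapped_leaves(value, prefix + (key,), ctx)
    elif isinstance(node, list):
        for item in node:
            yield from _walk_mapped_leaves(item, prefix, ctx)
    elif isinstance(node, _SCALARS) and prefix:
        iri = uri_for_path(ctx, FieldPath(prefix))
        if iri is not None:
            yield iri, node


def _escape_literal(text: str) -> str:
    out = []
    for ch in text:
        if ch == "\\":
            out.append("\\\\")
        elif ch == '"':
            out.append('\\"')
        elif ch == "\n":
            out.append("\\n")
        elif ch == "\r":
            out.append("\\r")
        elif ch == "\t":
            out.append("\\t")
        elif ord(ch) < 0x20:
            out.append(f"\\u{ord(ch):04X}")
        else:
            out.append(ch)
    return "".join(out)


def _render_term(term: str, is_iri: bool) -> str:
    if term.startswith("_:"):
        return term
    if is_iri:
        return f"<{term}>"
    return f'"{_escape_literal(term)}"'


def write_nquads(quads: Iterable[Quad]) -> str:
    """Serialize quads as N-Quads: one ``subject predicate object [graph] .``
    line per statement, IRIs angle-bracketed, literals escaped per the
    N-Quads grammar.  The output parses back (e.g. with rdflib) to an equal
    multiset of statements."""
    lines = []
    for q in quads:
        parts = [
            _render_term(q.subject, True),
            f"<{q.predicate}>",
            _render_term(q.object, q.object_is_iri),
        ]
        if q.graph is not None:
            parts.append(f"<{q.graph}>")
        lines.append(" ".join(parts) + " .")
    return "".join(line + "\n" for line in lines)
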