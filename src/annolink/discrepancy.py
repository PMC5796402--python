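"""Context-driven cross-source quality control.

Aggregated variant-annotation documents carry per-source branches (dbsnp,
dbnsfp, clinvar, ...) that sometimes disagree: two sources may report
different rsids for the same genomic position (a known symptom of
assembly-liftover errors), or report allele frequencies that differ far
more than panel sampling explains.  Because a JSON-LD context names the
concept behind every field, such checks need no knowledge of each source's
layout: ask for every value of the rsid concept URI, group the hits by the
source branch they came from, and compare.

Two checks are offered per entity × concept:

* categorical — flag when ≥ 2 sources report ≥ 2 distinct values (after
  whitespace trimming; comparison stays case-sensitive so real
  discrepancies are never masked);
* numeric variability — flag when the relative range (max − min) / max of
  one representative value per source exceeds a threshold (0.5 by
  default); an absolute range metric is available as an alternative.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

from .context import ContextDocument
from .semantic import AnnotationDocument, extract_values

__all__ = [
    "DiscrepancyRecord",
    "DiscrepancyReport",
    "ConceptCheck",
    "collect_by_source",
    "check_categorical",
    "check_numeric_variability",
    "scan_corpus",
]

logger = logging.getLogger(__name__)

MetricKind = Literal["relative-range", "absolute-range"]
Representative = Literal["first", "mean"]


@dataclass(frozen=True)
class DiscrepancyRecord:
    """Verdict for one entity × concept: the per-source values seen,
    whether they constitute a discrepancy, and the numeric variability
    metric when applicable."""

    entity_id: str
    concept: str
    per_source: Mapping[str, tuple]
    flagged: bool
    metric: Optional[float] = None
    skipped_values: int = 0


@dataclass
class DiscrepancyReport:
    """Flagged records plus per-concept summary counts."""

    rows: list[DiscrepancyRecord] = field(default_factory=list)
    summary: dict[str, int] = field(default_factory=dict)
    unreadable_documents: int = 0

    @property
    def total(self) -> int:
        return sum(self.summary.values())

    def flagged_entities(self, concept: str) -> set[str]:
        return {r.entity_id for r in self.rows if r.concept == concept}

    def to_csv(self) -> str:
        """Long-form CSV: one row per (entity, concept, source, value)."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["entity_id", "concept", "source", "value", "flagged", "metric"])
        for rec in self.rows:
            metric = "" if rec.metric is None else repr(rec.metric)
            for source in sorted(rec.per_source):
                for value in rec.per_source[source]:
                    writer.writerow(
                        [rec.entity_id, rec.concept, source, value,
                         str(rec.flagged).lower(), metric]
                    )
        return buf.getvalue()


@dataclass(frozen=True)
class ConceptCheck:
    """One concept to scan: its IRI, the check kind and, for numeric
    checks, the variability threshold."""

    concept: str
    kind: Literal["categorical", "numeric"]
    threshold: float = 0.5
    metric_kind: MetricKind = "relative-range"


def collect_by_source(
    doc: AnnotationDocument, ctx: ContextDocument, concept: str
) -> dict[str, list]:
    """Group a concept's values by source branch.

    The source label is the first segment of the field path that produced
    each value — aggregated documents are keyed by source at the top level,
    so ``dbsnp.rsid`` and ``dbnsfp.rsid`` attribute to ``dbsnp`` and
    ``dbnsfp`` respectively.
    """
    grouped: dict[str, list] = {}
    for path, value in extract_values(doc, ctx, concept):
        grouped.setdefault(path.segments[0], []).append(value)
    return grouped


def _normalize(value: object) -> str:
    return str(value).strip()


def check_categorical(
    doc: AnnotationDocument, ctx: ContextDocument, concept: str
) -> DiscrepancyRecord:
    """Flag when at least two sources report the concept and, across them,
    at least two distinct normalized values appear."""
    grouped = collect_by_source(doc, ctx, concept)
    distinct = {_normalize(v) for values in grouped.values() for v in values}
    flagged = len(grouped) >= 2 and len(distinct) >= 2
    return DiscrepancyRecord(
        entity_id=doc.entity_id or "",
        concept=concept,
        per_source={s: tuple(v) for s, v in grouped.items()},
        flagged=flagged,
    )


def _representative(values: Sequence[float], how: Representative) -> float:
    if how == "mean":
        return sum(values) / len(values)
    return values[0]


def check_numeric_variability(
    doc: AnnotationDocument,
    ctx: ContextDocument,
    concept: str,
    threshold: float = 0.5,
    metric_kind: MetricKind = "relative-range",
    representative: Representative = "first",
) -> DiscrepancyRecord:
    """Flag when per-source numeric values spread beyond *threshold*.

    One representative value per source (the source's first value by
    default, optionally the mean) enters the spread; the default metric is
    the relative range (max − min) / max, which lives in [0, 1] for
    non-negative values and is 0 when all values (or all maxima) are zero.
    Values that do not parse as numbers are skipped and counted.
    """
    if not 0 < threshold <= 1 and metric_kind == "relative-range":
        raise ValueError("relative-range threshold must be in (0, 1]")
    grouped = collect_by_source(doc, ctx, concept)
    per_source_nums: dict[str, list[float]] = {}
    skipped = 0
    for source, values in grouped.items():
        nums: list[float] = []
        for v in values:
            try:
                if isinstance(v, bool):
                    raise TypeError
                nums.append(float(v))
            except (TypeError, ValueError):
                skipped += 1
        if nums:
            per_source_nums[source] = nums
    reps = {
        s: _representative(nums, representative) for s, nums in per_source_nums.items()
    }
    metric: Optional[float] = None
    flagged = False
    if reps:
        hi, lo = max(reps.values()), min(reps.values())
        if metric_kind == "absolute-range":
            metric = hi - lo
        else:
            metric = (hi - lo) / hi if hi > 0 else 0.0
        flagged = len(reps) >= 2 and metric > threshold
    return DiscrepancyRecord(
        entity_id=doc.entity_id or "",
        concept=concept,
        per_source={s: tuple(v) for s, v in grouped.items()},
        flagged=flagged,
        metric=metric,
        skipped_values=skipped,
    )


def scan_corpus(
    docs: Iterable[AnnotationDocument | dict | str],
    ctx: ContextDocument,
    checks: Sequence[ConceptCheck],
) -> DiscrepancyReport:
    """Run every check over every document, streaming (memory is bounded
    in the number of flagged records, not corpus size).

    Documents may be :class:`AnnotationDocument` objects, raw JSON objects
    or JSON-lines strings; unreadable ones are logged, skipped and counted.
    Rows are sorted by entity ID; summary counts flagged entities per
    concept.
    """
    report = DiscrepancyReport(summary={c.concept: 0 for c in checks})
    for raw in docs:
        try:
            if isinstance(raw, AnnotationDocument):
                doc = raw
            else:
                doc = AnnotationDocument.from_json(raw)
        except Exception as exc:  # noqa: BLE001 — corrupt corpus line
            logger.warning("skipping unreadable document: %s", exc)
            report.unreadable_documents += 1
            continue
        for check in checks:
            if check.kind == "categorical":
                rec = check_categorical(doc, ctx, check.concept)
            else:
                rec = check_numeric_variability(
                    doc, ctx, check.concept,
                    threshold=check.threshold, metric_kind=check.metric_kind,
                )
            if rec.flagged:
                report.rows.append(rec)
                report.summary[check.concept] += 1
    report.rows.sort(key=lambda r: (r.entity_id, r.concept))
    return report
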