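"""Surface- and protein-mode coreference scoring.

Surface mode scores the annotated anaphora -> antecedent links directly.
Protein mode -- the primary evaluation perspective -- first *traces* each
chain of surface links until an antecedent embedding a protein name is
found, generating (anaphora, protein) links; intermediate antecedents and
links that reach no protein are ignored.

Markable (expression) matching is partial: a response expression is correct
when its span covers the gold expression's minimal boundary (its head) and
is included in the gold expression's maximal boundary (the full annotated
span).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .metrics import ScoreReport, ScoreRow
from .standoff import CorefRelation, Document, Span, TextBound

__all__ = [
    "Markable",
    "SurfaceLink",
    "ProteinLink",
    "markable_match",
    "surface_links",
    "score_surface",
    "build_protein_links",
    "score_protein",
    "score_by_anaphora_type",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Markable:
    """A coreference expression with maximal and minimal (head) boundaries."""

    id: str
    max_span: Span
    min_span: Span

    @classmethod
    def from_text_bound(cls, tb: TextBound) -> "Markable":
        return cls(tb.id, tb.span, tb.min_span or tb.span)


@dataclass(frozen=True)
class SurfaceLink:
    anaphora: Markable
    antecedent: Markable


@dataclass(frozen=True)
class ProteinLink:
    anaphora: Markable
    protein: str  # Protein text-bound identifier (shared gold protein set)


def markable_match(response: Markable, gold: Markable) -> bool:
    """Partial-match criterion: the response span covers the gold minimal
    boundary and is included in the gold maximal boundary."""
    return response.max_span.contains(gold.min_span) and gold.max_span.contains(
        response.max_span
    )


def _markable(doc: Document, ref: str) -> Markable:
    return Markable.from_text_bound(doc.text_bounds[ref])


def surface_links(doc: Document) -> list[SurfaceLink]:
    return [
        SurfaceLink(_markable(doc, rel.anaphora), _markable(doc, rel.antecedent))
        for rel in doc.coref_relations.values()
    ]


def _link_match(resp: SurfaceLink, gold: SurfaceLink) -> bool:
    return markable_match(resp.anaphora, gold.anaphora) and markable_match(
        resp.antecedent, gold.antecedent
    )


def score_surface(
    gold_links: Sequence[SurfaceLink], response_links: Sequence[SurfaceLink]
) -> ScoreRow:
    """Score surface coreference links; existence-based recall/precision."""
    row = ScoreRow("Surface")
    for g in gold_links:
        row.gold_count += 1
        if any(_link_match(r, g) for r in response_links):
            row.recall_matched += 1
    for r in response_links:
        row.answer_count += 1
        if any(_link_match(r, g) for g in gold_links):
            row.precision_matched += 1
    return row


# ---------------------------------------------------------------------------
# protein-mode chain tracing


def _embedded_proteins(
    rel: CorefRelation, antecedent: TextBound, doc: Document
) -> tuple[str, ...]:
    """Proteins embedded in an antecedent: the relation's bracketed list when
    stated, otherwise recomputed from Protein spans inside the antecedent."""
    if rel.proteins:
        return rel.proteins
    return tuple(
        tb.id
        for tb in doc.proteins()
        if antecedent.span.contains(tb.span)
    )


def build_protein_links(doc: Document) -> list[ProteinLink]:
    """Generate protein coreference links by tracing surface-link chains.

    For each anaphor, the chain of surface links is followed until an
    antecedent embedding a protein name is found (a direct protein antecedent
    after one link, an indirect one after several); the trace stops there.
    Anaphors whose chains reach no protein-embedding antecedent yield no
    links.  Cycles in the antecedent chain terminate the trace with a
    logged warning.
    """
    rels_by_ana: dict[str, list[CorefRelation]] = {}
    for rel in doc.coref_relations.values():
        rels_by_ana.setdefault(rel.anaphora, []).append(rel)

    links: list[ProteinLink] = []
    seen: set[tuple[str, str]] = set()

    def trace(rel: CorefRelation, visited: set[str]) -> set[str]:
        ant_id = rel.antecedent
        if ant_id in visited:
            logger.warning(
                "%s: cycle in coreference chain at %s", doc.doc_id, ant_id
            )
            return set()
        antecedent = doc.text_bounds[ant_id]
        prots = _embedded_proteins(rel, antecedent, doc)
        if prots:
            return set(prots)
        found: set[str] = set()
        for nxt in rels_by_ana.get(ant_id, ()):
            found |= trace(nxt, visited | {ant_id})
        return found

    for rel in doc.coref_relations.values():
        for pid in sorted(trace(rel, {rel.anaphora})):
            key = (rel.anaphora, pid)
            if key not in seen:
                seen.add(key)
                links.append(ProteinLink(_markable(doc, rel.anaphora), pid))
    return links


def _protein_link_match(resp: ProteinLink, gold: ProteinLink) -> bool:
    return resp.protein == gold.protein and markable_match(
        resp.anaphora, gold.anaphora
    )


def score_protein(gold_doc: Document, response_doc: Document) -> ScoreRow:
    """Score one document's protein coreference links (primary mode).

    A response link is correct iff its anaphor matches a gold link's anaphor
    under the partial markable criterion and the protein references are
    identical (proteins are the given gold set on both sides).
    """
    gold_links = build_protein_links(gold_doc)
    resp_links = build_protein_links(response_doc)
    row = ScoreRow("Protein")
    for g in gold_links:
        row.gold_count += 1
        if any(_protein_link_match(r, g) for r in resp_links):
            row.recall_matched += 1
    for r in resp_links:
        row.answer_count += 1
        if any(_protein_link_match(r, g) for g in gold_links):
            row.precision_matched += 1
    return row


def evaluate_coref(
    gold: Mapping[str, Document],
    response: Mapping[str, Document],
    mode: str = "protein",
) -> ScoreReport:
    """Corpus-level coreference evaluation in surface or protein mode."""
    if set(gold) != set(response):
        raise ValueError("gold/response document sets differ")
    report = ScoreReport(mode=f"coref[{mode}]", decimals=1)
    total = report.row("All")
    for doc_id in sorted(gold):
        if mode == "surface":
            row = score_surface(
                surface_links(gold[doc_id]), surface_links(response[doc_id])
            )
        elif mode == "protein":
            row = score_protein(gold[doc_id], response[doc_id])
        else:
            raise ValueError(f"unknown coreference mode {mode!r}")
        total.add(row)
    return report


def score_by_anaphora_type(
    gold: Mapping[str, Document],
    response: Mapping[str, Document],
    type_labels: Mapping[tuple[str, str], str] | None = None,
) -> ScoreReport:
    """Protein-mode scores broken down by anaphora type.

    ``type_labels`` maps ``(doc_id, anaphor_id)`` of *gold* anaphors to a
    label (e.g. "Relative pronoun", "Pronoun", "DNP"); labels are consumed
    as supplied, never inferred from the text.  Response links are attributed
    to the type of the gold anaphor they match; when several gold anaphors
    match one response anaphor, the one with the largest span overlap wins
    (tie: earliest offset).  Response links matching no gold anaphor count
    only toward All precision.  Without labels only the All row is produced.
    """
    if set(gold) != set(response):
        raise ValueError("gold/response document sets differ")
    type_labels = type_labels or {}
    report = ScoreReport(mode="coref[protein,by-anaphora-type]", decimals=1)
    labels_in_use = sorted(set(type_labels.values()))
    for lab in labels_in_use:
        report.row(lab)
    all_row = report.row("All")

    for doc_id in sorted(gold):
        gold_doc, resp_doc = gold[doc_id], response[doc_id]
        gold_links = build_protein_links(gold_doc)
        resp_links = build_protein_links(resp_doc)

        def label_of(ana: Markable) -> str | None:
            return type_labels.get((doc_id, ana.id))

        def best_gold_anaphor(resp_ana: Markable) -> Markable | None:
            candidates = {g.anaphora for g in gold_links if markable_match(resp_ana, g.anaphora)}
            if not candidates:
                return None
            return max(
                candidates,
                key=lambda a: (a.max_span.overlap(resp_ana.max_span), -a.max_span.beg),
            )

        for g in gold_links:
            matched = any(_protein_link_match(r, g) for r in resp_links)
            rows = [all_row]
            lab = label_of(g.anaphora)
            if lab is not None:
                rows.append(report.row(lab))
            for row in rows:
                row.gold_count += 1
                if matched:
                    row.recall_matched += 1
        for r in resp_links:
            matched = any(_protein_link_match(r, g) for g in gold_links)
            rows = [all_row]
            paired = best_gold_anaphor(r.anaphora)
            lab = label_of(paired) if paired is not None else None
            if lab is not None:
                rows.append(report.row(lab))
            for row in rows:
                row.answer_count += 1
                if matched:
                    row.precision_matched += 1
    return report
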