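"""Scoring of predicted vs gold event annotation for Tasks 1, 2 and 3.

Matched counting is existence-based and computed independently for recall
and precision: a gold unit is recall-matched iff *some* predicted unit in the
same document equals it under the configured matching mode, and a predicted
unit is precision-matched iff some gold unit equals it.  Group rows (Simple
Event / Binding / Regulation / All) micro-average the member-type counts.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Mapping

from .matching import (
    MatchConfig,
    decompose,
    event_match,
    strip_secondary,
    text_bound_match,
)
from .metrics import ScoreReport, ScoreRow, compute_fscore
from .standoff import (
    Document,
    EventFrame,
    EVENT_TYPES,
    REGULATION_TYPES,
    SECONDARY_ROLES,
    SIMPLE_TYPES,
)

__all__ = [
    "score_task1",
    "score_task2",
    "score_task3",
    "compute_fscore",
    "GROUPS",
]

# group rows are bracketed to keep them distinct from per-type rows
# (the "Regulation" group aggregates the whole regulation family)
GROUPS: dict[str, tuple[str, ...]] = {
    "[Simple Event]": SIMPLE_TYPES,
    "[Binding]": ("Binding",),
    "[Regulation]": REGULATION_TYPES,
    "[All]": EVENT_TYPES,
}


class DocumentSetMismatch(ValueError):
    def __init__(self, missing_in_pred: set, missing_in_gold: set):
        self.missing_in_pred = sorted(missing_in_pred)
        self.missing_in_gold = sorted(missing_in_gold)
        super().__init__(
            "gold/prediction document sets differ; "
            f"missing in predictions: {self.missing_in_pred}; "
            f"missing in gold: {self.missing_in_gold}"
        )


def _paired_docs(
    gold: Mapping[str, Document],
    pred: Mapping[str, Document],
    section: str | None,
) -> list[tuple[Document, Document]]:
    if set(gold) != set(pred):
        raise DocumentSetMismatch(set(gold) - set(pred), set(pred) - set(gold))
    pairs = [(gold[d], pred[d]) for d in sorted(gold)]
    if section is not None:
        pairs = [(g, p) for g, p in pairs if g.section == section]
    return pairs


def _scoring_units(doc: Document, config: MatchConfig) -> list[EventFrame]:
    events: Iterable[EventFrame] = doc.events.values()
    if config.task_level == "task1":
        events = [strip_secondary(e) for e in events]
    if config.decomposition:
        return decompose(events)
    return list(events)


def _add_group_rows(report: ScoreReport) -> None:
    for group, members in GROUPS.items():
        row = ScoreRow(group)
        for t in members:
            if t in report.rows:
                row.add(report.rows[t])
        report.rows[group] = row


def score_task1(
    gold: Mapping[str, Document],
    pred: Mapping[str, Document],
    config: MatchConfig | None = None,
    section: str | None = None,
) -> ScoreReport:
    """Score core event extraction (typed events with primary arguments).

    The headline reporting mode is approximate recursive matching with
    approximate spans, which is the default ``MatchConfig``.
    """
    config = config or MatchConfig()
    if config.task_level != "task1":
        config = replace(config, task_level="task1")
    report = ScoreReport(mode=f"task1[{config.describe()}]")
    for t in EVENT_TYPES:
        report.row(t)
    for gold_doc, pred_doc in _paired_docs(gold, pred, section):
        gold_units = _scoring_units(gold_doc, config)
        pred_units = _scoring_units(pred_doc, config)
        for g in gold_units:
            row = report.row(g.ev_type)
            row.gold_count += 1
            if any(
                event_match(p, g, config, pred_doc, gold_doc) for p in pred_units
            ):
                row.recall_matched += 1
        for p in pred_units:
            row = report.row(p.ev_type)
            row.answer_count += 1
            if any(
                event_match(p, g, config, pred_doc, gold_doc) for g in gold_units
            ):
                row.precision_matched += 1
    _add_group_rows(report)
    return report


# ---------------------------------------------------------------------------
# Task 2: secondary arguments


def _secondary_category(role: str) -> str:
    return "Sites" if role in ("Site", "CSite") else "Locations"


def _site_host_category(ev_type: str) -> str | None:
    if ev_type == "Phosphorylation":
        return "Sites:Phosphorylation"
    if ev_type == "Binding":
        return "Sites:Binding"
    if ev_type in REGULATION_TYPES:
        return "Sites:Regulation"
    return None


def _secondary_args(ev: EventFrame) -> list[tuple[str, str]]:
    return [(r, t) for r, t in ev.args if r in SECONDARY_ROLES]


def score_task2(
    gold: Mapping[str, Document],
    pred: Mapping[str, Document],
    config: MatchConfig | None = None,
    section: str | None = None,
) -> ScoreReport:
    """Score event enrichment: one scoring unit per gold secondary argument.

    A gold secondary argument is recall-matched iff a predicted event
    matching its host event under Task-1 criteria carries a secondary
    argument with the same role and an equal entity; precision is the mirror
    image over predicted secondary arguments.  Categories: Sites (Site and
    CSite), Locations (AtLoc and ToLoc), All, plus Site rows broken down by
    host event type.
    """
    config = config or MatchConfig()
    host_config = replace(config, task_level="task1", decomposition=False)
    report = ScoreReport(mode=f"task2[span={config.span_mode},recursive={config.recursive_mode}]")
    categories = [
        "Sites",
        "Locations",
        "All",
        "Sites:Phosphorylation",
        "Sites:Binding",
        "Sites:Regulation",
    ]
    for c in categories:
        report.row(c)

    def entity_equal(pred_ref: str, gold_ref: str, pred_doc, gold_doc) -> bool:
        return text_bound_match(
            pred_doc.text_bounds[pred_ref],
            gold_doc.text_bounds[gold_ref],
            config.span_mode,
            gold_doc.text,
        )

    for gold_doc, pred_doc in _paired_docs(gold, pred, section):
        gold_events = list(gold_doc.events.values())
        pred_events = list(pred_doc.events.values())
        for g in gold_events:
            for role, target in _secondary_args(g):
                cats = ["All", _secondary_category(role)]
                host_cat = _site_host_category(g.ev_type)
                if role in ("Site", "CSite") and host_cat:
                    cats.append(host_cat)
                matched = any(
                    event_match(p, g, host_config, pred_doc, gold_doc)
                    and any(
                        pr == role
                        and entity_equal(pt, target, pred_doc, gold_doc)
                        for pr, pt in _secondary_args(p)
                    )
                    for p in pred_events
                )
                for c in cats:
                    report.row(c).gold_count += 1
                    if matched:
                        report.row(c).recall_matched += 1
        for p in pred_events:
            for role, target in _secondary_args(p):
                cats = ["All", _secondary_category(role)]
                host_cat = _site_host_category(p.ev_type)
                if role in ("Site", "CSite") and host_cat:
                    cats.append(host_cat)
                matched = any(
                    event_match(p, g, host_config, pred_doc, gold_doc)
                    and any(
                        gr == role
                        and entity_equal(target, gt, pred_doc, gold_doc)
                        for gr, gt in _secondary_args(g)
                    )
                    for g in gold_events
                )
                for c in cats:
                    report.row(c).answer_count += 1
                    if matched:
                        report.row(c).precision_matched += 1
    return report


# ---------------------------------------------------------------------------
# Task 3: negation / speculation


def score_task3(
    gold: Mapping[str, Document],
    pred: Mapping[str, Document],
    config: MatchConfig | None = None,
    section: str | None = None,
) -> ScoreReport:
    """Score negation/speculation detection over extracted events.

    A gold modification is recall-matched iff a predicted modification of the
    same type attaches to an event matching the gold modification's event;
    precision analogous.  Rows: Negation, Speculation, All.
    """
    config = config or MatchConfig()
    host_config = replace(config, task_level="task1", decomposition=False)
    report = ScoreReport(mode=f"task3[span={config.span_mode},recursive={config.recursive_mode}]")
    for c in ("Negation", "Speculation", "All"):
        report.row(c)
    for gold_doc, pred_doc in _paired_docs(gold, pred, section):
        gold_mods = list(gold_doc.modifications.values())
        pred_mods = list(pred_doc.modifications.values())
        for gm in gold_mods:
            g_ev = gold_doc.events[gm.event]
            matched = any(
                pm.mod_type == gm.mod_type
                and event_match(
                    pred_doc.events[pm.event], g_ev, host_config, pred_doc, gold_doc
                )
                for pm in pred_mods
            )
            for c in ("All", gm.mod_type):
                report.row(c).gold_count += 1
                if matched:
                    report.row(c).recall_matched += 1
        for pm in pred_mods:
            p_ev = pred_doc.events[pm.event]
            matched = any(
                pm.mod_type == gm.mod_type
                and event_match(
                    p_ev, gold_doc.events[gm.event], host_config, pred_doc, gold_doc
                )
                for gm in gold_mods
            )
            for c in ("All", pm.mod_type):
                report.row(c).answer_count += 1
                if matched:
                    report.row(c).precision_matched += 1
    return report
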