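"""Event and entity equality calculus with its relaxed variants.

Exact equality of a predicted event against a gold event requires the same
event type, an equal trigger (a text entity: same type, same span) and a
perfect one-to-one mapping between the two argument sets in which paired
arguments carry the same role and equal targets; equality is recursive for
event-valued arguments.  Two relaxations are supported:

* **approximate span matching** -- a predicted text-entity span counts as
  equal to a gold span when it is entirely contained within the gold span
  extended by one word to the left and to the right;
* **approximate recursive matching** -- an event appearing in *argument
  position* is matched by a relaxed criterion (same type, matching trigger,
  matching Theme arguments only), so a nesting event can be credited even
  when its referred event differs in non-Theme arguments.

**Event decomposition** splits each multi-argument event into single-argument
units sharing the trigger and type; the units are scored as separate events,
awarding partial credit for partially correct complex events.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx

from .standoff import (
    Document,
    EventFrame,
    SECONDARY_ROLES,
    Span,
    TextBound,
)

__all__ = [
    "MatchConfig",
    "WordExtendedSpan",
    "extend_span",
    "span_match",
    "text_bound_match",
    "arguments_match",
    "event_match",
    "decompose",
    "strip_secondary",
]

# a "word" is a maximal run of non-whitespace, non-punctuation characters
_WORD_RE = re.compile(r"[^\s%s]+" % re.escape(string.punctuation))


@dataclass(frozen=True)
class MatchConfig:
    """Evaluation-mode switches.

    task1 strips secondary arguments (Site, CSite, AtLoc, ToLoc) from both
    gold and predicted events before matching; task2 retains them.
    """

    span_mode: str = "approximate"  # {strict, approximate}
    recursive_mode: str = "approximate"  # {strict, approximate}
    decomposition: bool = False
    task_level: str = "task1"  # {task1, task2}

    def __post_init__(self) -> None:
        if self.span_mode not in ("strict", "approximate"):
            raise ValueError(f"bad span_mode {self.span_mode!r}")
        if self.recursive_mode not in ("strict", "approximate"):
            raise ValueError(f"bad recursive_mode {self.recursive_mode!r}")
        if self.task_level not in ("task1", "task2"):
            raise ValueError(f"bad task_level {self.task_level!r}")

    def describe(self) -> str:
        bits = [
            f"span={self.span_mode}",
            f"recursive={self.recursive_mode}",
            f"decomposition={'on' if self.decomposition else 'off'}",
            self.task_level,
        ]
        return ",".join(bits)


STRICT = MatchConfig(span_mode="strict", recursive_mode="strict")
DEFAULT = MatchConfig()  # approximate span + approximate recursive


@dataclass(frozen=True)
class WordExtendedSpan:
    ebeg: int
    eend: int
    source: Span


def extend_span(gold_span: Span, text: str) -> WordExtendedSpan:
    """Extend a gold span by one word to the left and to the right.

    The extension reaches the start of the nearest word beginning before the
    span and the end of the nearest word ending after it; at document edges
    (no adjacent word) the boundary clamps to the gold span's own boundary.
    """
    ebeg, eend = gold_span.beg, gold_span.end
    prev_start = None
    for m in _WORD_RE.finditer(text):
        if m.start() < gold_span.beg:
            prev_start = m.start()
        if m.end() > gold_span.end:
            eend = m.end()
            break
    if prev_start is not None:
        ebeg = prev_start
    return WordExtendedSpan(ebeg, eend, gold_span)


def span_match(pred: Span, gold: Span, mode: str, text: str | None) -> bool:
    if mode == "strict" or text is None:
        return pred == gold
    ext = extend_span(gold, text)
    return pred.beg >= ext.ebeg and pred.end <= ext.eend


def text_bound_match(
    pred: TextBound, gold: TextBound, mode: str, text: str | None
) -> bool:
    """Text entity equality: same entity type and (possibly relaxed) span."""
    return pred.ann_type == gold.ann_type and span_match(
        pred.span, gold.span, mode, text
    )


# ---------------------------------------------------------------------------
# argument matching


def _perfect_matching(n: int, compat: list[tuple[int, int]]) -> bool:
    """True iff the bipartite graph on n+n nodes admits a perfect matching."""
    if n == 0:
        return True
    if not compat:
        return False
    g = nx.Graph()
    g.add_nodes_from(("p", i) for i in range(n))
    g.add_nodes_from(("g", j) for j in range(n))
    g.add_edges_from((("p", i), ("g", j)) for i, j in compat)
    matching = nx.bipartite.hopcroft_karp_matching(g, [("p", i) for i in range(n)])
    return len(matching) == 2 * n


def _target_match(
    pred_ref: str,
    gold_ref: str,
    config: MatchConfig,
    pred_doc: Document,
    gold_doc: Document,
) -> bool:
    pred_t = pred_doc.resolve(pred_ref)
    gold_t = gold_doc.resolve(gold_ref)
    if isinstance(pred_t, TextBound) and isinstance(gold_t, TextBound):
        return text_bound_match(pred_t, gold_t, config.span_mode, gold_doc.text)
    if isinstance(pred_t, EventFrame) and isinstance(gold_t, EventFrame):
        if config.recursive_mode == "approximate":
            return _relaxed_event_match(pred_t, gold_t, config, pred_doc, gold_doc)
        return event_match(pred_t, gold_t, config, pred_doc, gold_doc)
    return False


def _effective_args(ev: EventFrame, config: MatchConfig) -> tuple[tuple[str, str], ...]:
    if config.task_level == "task1":
        return tuple((r, t) for r, t in ev.args if r not in SECONDARY_ROLES)
    return ev.args


def arguments_match(
    pred_args: Sequence[tuple[str, str]],
    gold_args: Sequence[tuple[str, str]],
    config: MatchConfig,
    pred_doc: Document,
    gold_doc: Document,
) -> bool:
    """Full matching of two argument multisets.

    True iff a perfect one-to-one correspondence exists pairing arguments
    with equal roles and equal targets, found via maximum bipartite matching
    over the precomputed compatibility graph.
    """
    if len(pred_args) != len(gold_args):
        return False
    compat = [
        (i, j)
        for i, (pr, pt) in enumerate(pred_args)
        for j, (gr, gt) in enumerate(gold_args)
        if pr == gr and _target_match(pt, gt, config, pred_doc, gold_doc)
    ]
    return _perfect_matching(len(pred_args), compat)


def _relaxed_event_match(
    pred: EventFrame,
    gold: EventFrame,
    config: MatchConfig,
    pred_doc: Document,
    gold_doc: Document,
) -> bool:
    """Relaxed equality for events in argument position.

    Same type, matching trigger, and matching Theme arguments only; applied
    recursively to Theme targets that are themselves events.
    """
    if pred.ev_type != gold.ev_type:
        return False
    if not text_bound_match(
        pred_doc.text_bounds[pred.trigger],
        gold_doc.text_bounds[gold.trigger],
        config.span_mode,
        gold_doc.text,
    ):
        return False
    pred_themes = [(r, t) for r, t in pred.args if r == "Theme"]
    gold_themes = [(r, t) for r, t in gold.args if r == "Theme"]
    return arguments_match(pred_themes, gold_themes, config, pred_doc, gold_doc)


def event_match(
    pred: EventFrame,
    gold: EventFrame,
    config: MatchConfig,
    pred_doc: Document,
    gold_doc: Document,
) -> bool:
    """Event equality under the configured modes.

    Types equal, triggers equal as text entities, and the (task-level
    filtered) argument sets fully matched.  The relaxation of
    ``recursive_mode='approximate'`` applies only to events in argument
    position; the top-level argument sets must still fully match.
    """
    if pred.ev_type != gold.ev_type:
        return False
    if not text_bound_match(
        pred_doc.text_bounds[pred.trigger],
        gold_doc.text_bounds[gold.trigger],
        config.span_mode,
        gold_doc.text,
    ):
        return False
    return arguments_match(
        _effective_args(pred, config),
        _effective_args(gold, config),
        config,
        pred_doc,
        gold_doc,
    )


# ---------------------------------------------------------------------------
# event decomposition


def decompose(events: Iterable[EventFrame]) -> list[EventFrame]:
    """Split each multi-argument event into single-argument units.

    Each event with k >= 1 arguments yields k units sharing the original
    trigger and type; zero-argument events are preserved unchanged.  Nested
    argument targets are left intact (they still reference the original,
    undecomposed events of the document).  Idempotent.
    """
    units: list[EventFrame] = []
    for ev in events:
        if len(ev.args) <= 1:
            units.append(ev)
        else:
            for k, arg in enumerate(ev.args, start=1):
                units.append(replace(ev, id=f"{ev.id}.{k}", args=(arg,)))
    return units


def strip_secondary(ev: EventFrame) -> EventFrame:
    """Drop Site/CSite/AtLoc/ToLoc arguments from an event frame."""
    kept = tuple((r, t) for r, t in ev.args if r not in SECONDARY_ROLES)
    return ev if kept == ev.args else replace(ev, args=kept)
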