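"""Descriptive statistics over a standoff corpus.

Counts per annotation category plus the derived annotation densities
(proteins per word P/W, events per word E/W, events per protein E/P, as
percentages) and the event-coordination ratio E/T (events per distinct
event trigger; a trigger anchoring several events signals coordinated
event mentions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .metrics import round_half_away
from .standoff import Document, EVENT_TYPES

__all__ = ["CorpusProfile", "profile_corpus", "ratio_percent", "coordination_ratio"]


def ratio_percent(numerator: int, denominator: int, decimals: int = 2) -> float | None:
    """100 * numerator / denominator, rounded half away from zero.

    Returns ``None`` (the undefined marker) when the denominator is 0.
    """
    if denominator < 0:
        raise ValueError("denominator must be >= 0")
    if denominator == 0:
        return None
    return round_half_away(100.0 * numerator / denominator, decimals)


def coordination_ratio(events: int, triggers: int) -> float | None:
    """Events per distinct trigger, rounded to 2 decimals.

    Triggers are counted as distinct trigger text-bounds referenced by at
    least one event, so events > 0 with triggers = 0 is an integrity
    violation.
    """
    if triggers == 0:
        if events > 0:
            raise ValueError("events without any trigger: integrity violation")
        return None
    return round_half_away(events / triggers, 2)


@dataclass
class CorpusProfile:
    words: int = 0
    proteins: int = 0
    triggers: int = 0
    events_total: int = 0
    events_by_type: dict[str, int] = field(default_factory=dict)
    coreferences: int = 0
    coreferences_by_type: dict[str, int] = field(default_factory=dict)

    @property
    def density_p_w(self) -> float | None:
        return ratio_percent(self.proteins, self.words)

    @property
    def density_e_w(self) -> float | None:
        return ratio_percent(self.events_total, self.words)

    @property
    def density_e_p(self) -> float | None:
        return ratio_percent(self.events_total, self.proteins)

    @property
    def coordination(self) -> float | None:
        return coordination_ratio(self.events_total, self.triggers)

    def add(self, other: "CorpusProfile") -> None:
        self.words += other.words
        self.proteins += other.proteins
        self.triggers += other.triggers
        self.events_total += other.events_total
        self.coreferences += other.coreferences
        for t, n in other.events_by_type.items():
            self.events_by_type[t] = self.events_by_type.get(t, 0) + n
        for t, n in other.coreferences_by_type.items():
            self.coreferences_by_type[t] = self.coreferences_by_type.get(t, 0) + n

    def as_dict(self) -> dict:
        return {
            "words": self.words,
            "proteins": self.proteins,
            "event_triggers": self.triggers,
            "events": self.events_total,
            "events_by_type": dict(self.events_by_type),
            "coreferences": self.coreferences,
            "coreferences_by_type": dict(self.coreferences_by_type),
            "density_P/W": self.density_p_w,
            "density_E/W": self.density_e_w,
            "density_E/P": self.density_e_p,
            "avg_coordination_E/T": self.coordination,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2) + "\n"

    def to_tsv(self) -> str:
        d = self.as_dict()
        lines = []
        for key, value in d.items():
            if isinstance(value, dict):
                for sub, n in value.items():
                    lines.append(f"{key}.{sub}\t{n}")
            else:
                lines.append(f"{key}\t{'-' if value is None else value}")
        return "\n".join(lines) + "\n"


def profile_corpus(
    docs: Mapping[str, Document] | Iterable[Document],
    section: str | None = None,
    anaphora_labels: Mapping[tuple[str, str], str] | None = None,
) -> CorpusProfile:
    """Profile a parsed corpus, optionally restricted to one section label.

    Word counting uses whitespace-delimited tokens of the raw text.  The
    coreference breakdown per anaphora type is produced only when an
    external label table is supplied.
    """
    if isinstance(docs, Mapping):
        docs = docs.values()
    profile = CorpusProfile(events_by_type={t: 0 for t in EVENT_TYPES})
    for doc in docs:
        if section is not None and doc.section != section:
            continue
        if doc.text is not None:
            profile.words += len(doc.text.split())
        profile.proteins += len(doc.proteins())
        trigger_ids = {ev.trigger for ev in doc.events.values()}
        profile.triggers += len(trigger_ids)
        for ev in doc.events.values():
            profile.events_total += 1
            profile.events_by_type[ev.ev_type] = (
                profile.events_by_type.get(ev.ev_type, 0) + 1
            )
        profile.coreferences += len(doc.coref_relations)
        if anaphora_labels:
            for rel in doc.coref_relations.values():
                lab = anaphora_labels.get((doc.doc_id, rel.anaphora))
                if lab is not None:
                    profile.coreferences_by_type[lab] = (
                        profile.coreferences_by_type.get(lab, 0) + 1
                    )
    return profile
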