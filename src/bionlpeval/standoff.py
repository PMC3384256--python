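"""Reader/writer for the BioNLP-ST standoff annotation dialect.

A document is a plain-text file plus standoff annotation lines that reference
it by character offset (0-based, end-exclusive):

* ``T`` lines -- text-bound annotations: proteins, generic entities, event
  triggers, and coreference markables (type ``Exp``).  Markable lines may carry
  a second offset pair giving the minimal (head) span.
* ``E`` lines -- events: a type, a trigger reference and role-labelled
  arguments that target text-bounds or other events (recursively).
* ``M`` lines -- event modifications (Negation / Speculation).
* ``R`` lines -- coreference relations: anaphora -> antecedent, optionally
  listing the protein mentions embedded in the antecedent.

On disk, protein annotations conventionally live in ``<doc>.a1`` and all
target annotations (triggers, entities, events, modifications, coreference)
in ``<doc>.a2``; :func:`read_document` / :func:`write_document` follow that
split, while :func:`parse_document` accepts any iterable of lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Span",
    "TextBound",
    "EventFrame",
    "EventModification",
    "CorefRelation",
    "Document",
    "StandoffError",
    "parse_document",
    "serialize_document",
    "read_document",
    "write_document",
    "read_corpus",
    "write_corpus",
    "EVENT_TYPES",
    "SIMPLE_TYPES",
    "REGULATION_TYPES",
    "PRIMARY_ROLES",
    "SECONDARY_ROLES",
]

#: The nine event types of the Genia event typology.
SIMPLE_TYPES = (
    "Gene_expression",
    "Transcription",
    "Protein_catabolism",
    "Phosphorylation",
    "Localization",
)
REGULATION_TYPES = ("Regulation", "Positive_regulation", "Negative_regulation")
EVENT_TYPES = SIMPLE_TYPES + ("Binding",) + REGULATION_TYPES

PRIMARY_ROLES = ("Theme", "Cause")
SECONDARY_ROLES = ("Site", "CSite", "AtLoc", "ToLoc")
_ALL_ROLES = PRIMARY_ROLES + SECONDARY_ROLES

_ROLE_RE = re.compile(r"^(Theme|Cause|Site|CSite|AtLoc|ToLoc)(\d*)$")
_MOD_TYPES = ("Negation", "Speculation")


class StandoffError(ValueError):
    """Raised for malformed or inconsistent standoff annotation."""

    def __init__(self, message: str, line: str | None = None):
        self.line = line
        if line is not None:
            message = f"{message} [line: {line!r}]"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class Span:
    """A character span, 0-based begin, exclusive end."""

    beg: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.beg < self.end):
            raise StandoffError(f"invalid span [{self.beg},{self.end})")

    def contains(self, other: "Span") -> bool:
        return self.beg <= other.beg and other.end <= self.end

    def overlap(self, other: "Span") -> int:
        return max(0, min(self.end, other.end) - max(self.beg, other.beg))


@dataclass(frozen=True)
class TextBound:
    """A typed text span: protein, entity, event trigger or markable."""

    id: str
    ann_type: str
    span: Span
    text: str | None = None
    min_span: Span | None = None

    def __post_init__(self) -> None:
        if self.min_span is not None and not self.span.contains(self.min_span):
            raise StandoffError(
                f"{self.id}: minimal span {self.min_span} not inside {self.span}"
            )
        # a minimal span equal to the full span carries no information; store
        # the canonical form so serialization round-trips structurally
        if self.min_span == self.span:
            object.__setattr__(self, "min_span", None)


@dataclass(frozen=True)
class EventFrame:
    """A typed event: trigger plus role-labelled arguments.

    ``args`` is an ordered tuple of ``(role, target_id)`` pairs but carries
    multiset semantics: argument order never matters for equality or matching.
    Targets are annotation identifiers, resolved against the owning document
    (``T*`` for text-bounds, ``E*`` for events).
    """

    id: str
    ev_type: str
    trigger: str
    args: tuple[tuple[str, str], ...] = ()

    def themes(self) -> tuple[str, ...]:
        return tuple(t for r, t in self.args if r == "Theme")

    def arity(self) -> int:
        return len(self.args)


@dataclass(frozen=True)
class EventModification:
    id: str
    mod_type: str
    event: str


@dataclass(frozen=True)
class CorefRelation:
    """An anaphora -> antecedent surface link.

    ``proteins`` lists the Protein text-bounds embedded in the antecedent,
    when the annotation states them (the bracketed list of R lines).
    """

    id: str
    anaphora: str
    antecedent: str
    proteins: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.anaphora == self.antecedent:
            raise StandoffError(f"{self.id}: anaphora equals antecedent")


@dataclass
class Document:
    doc_id: str
    text: str | None = None
    text_bounds: dict[str, TextBound] = field(default_factory=dict)
    events: dict[str, EventFrame] = field(default_factory=dict)
    modifications: dict[str, EventModification] = field(default_factory=dict)
    coref_relations: dict[str, CorefRelation] = field(default_factory=dict)
    section: str | None = None
    unknown_lines: list[str] = field(default_factory=list)

    # -- convenience views ------------------------------------------------
    def proteins(self) -> list[TextBound]:
        return [t for t in self.text_bounds.values() if t.ann_type == "Protein"]

    def markables(self) -> list[TextBound]:
        return [t for t in self.text_bounds.values() if t.ann_type == "Exp"]

    def resolve(self, ref: str) -> TextBound | EventFrame:
        if ref in self.text_bounds:
            return self.text_bounds[ref]
        if ref in self.events:
            return self.events[ref]
        raise StandoffError(f"{self.doc_id}: dangling reference {ref}")

    def validate(self) -> None:
        """Check referential integrity, span/text agreement and acyclicity."""
        for tb in self.text_bounds.values():
            if self.text is not None:
                if tb.span.end > len(self.text):
                    raise StandoffError(
                        f"{tb.id}: span {tb.span} beyond document end"
                    )
                actual = self.text[tb.span.beg : tb.span.end]
                if tb.text is not None and tb.text != actual:
                    raise StandoffError(
                        f"{tb.id}: text {tb.text!r} != document substring {actual!r}"
                    )
        for ev in self.events.values():
            trig = self.text_bounds.get(ev.trigger)
            if trig is None:
                raise StandoffError(f"{ev.id}: dangling trigger {ev.trigger}")
            if trig.ann_type != ev.ev_type:
                raise StandoffError(
                    f"{ev.id}: trigger type {trig.ann_type} != event type {ev.ev_type}"
                )
            for role, target in ev.args:
                if role not in _ALL_ROLES:
                    raise StandoffError(f"{ev.id}: unknown role {role}")
                if target not in self.text_bounds and target not in self.events:
                    raise StandoffError(f"{ev.id}: dangling argument {target}")
        for mod in self.modifications.values():
            if mod.event not in self.events:
                raise StandoffError(f"{mod.id}: dangling event {mod.event}")
        for rel in self.coref_relations.values():
            for ref in (rel.anaphora, rel.antecedent) + rel.proteins:
                if ref not in self.text_bounds:
                    raise StandoffError(f"{rel.id}: dangling reference {ref}")
            ant = self.text_bounds[rel.antecedent]
            for pid in rel.proteins:
                if not ant.span.contains(self.text_bounds[pid].span):
                    raise StandoffError(
                        f"{rel.id}: protein {pid} not embedded in antecedent {ant.id}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS with colouring over event->event argument edges
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {eid: WHITE for eid in self.events}

        def visit(eid: str) -> None:
            colour[eid] = GREY
            for _, target in self.events[eid].args:
                if target in self.events:
                    if colour[target] == GREY:
                        raise StandoffError(
                            f"cyclic event reference through {eid} -> {target}"
                        )
                    if colour[target] == WHITE:
                        visit(target)
            colour[eid] = BLACK

        for eid in self.events:
            if colour[eid] == WHITE:
                visit(eid)


# ---------------------------------------------------------------------------
# parsing


def _normalize_role(role: str, line: str) -> str:
    m = _ROLE_RE.match(role)
    if m is None:
        raise StandoffError(f"unknown argument role {role!r}", line)
    return m.group(1)


def _split_ref(token: str, line: str) -> tuple[str, str]:
    if ":" not in token:
        raise StandoffError(f"expected KEY:REF token, got {token!r}", line)
    key, ref = token.split(":", 1)
    return key, ref


_MIN_SPAN_RE = re.compile(r"^(?P<text>.*\S)\s+(?P<b>\d+)\s+(?P<e>\d+)(?:\s+(?P<h>.*))?$")


def _parse_textbound(line: str, text: str | None) -> TextBound:
    parts = line.split("\t")
    if len(parts) >= 2 and re.match(r"^\S+ \d+ \d+$", parts[1]):
        # tab-delimited (brat-style): id \t "type beg end" \t text [\t "b e" \t head]
        tid = parts[0]
        ann_type, beg_s, end_s = parts[1].split(" ")
        span = Span(int(beg_s), int(end_s))
        surface = parts[2] if len(parts) > 2 else None
        min_span = None
        if len(parts) > 3:
            m = re.match(r"^(\d+) (\d+)$", parts[3])
            if m is None:
                raise StandoffError("expected minimal-span offsets", line)
            min_span = Span(int(m.group(1)), int(m.group(2)))
        return TextBound(tid, ann_type, span, surface, min_span)
    # space-delimited form: id type beg end [text [min_beg min_end [head]]]
    tokens = line.split(" ")
    if len(tokens) < 4:
        raise StandoffError("too few fields in text-bound line", line)
    tid, ann_type = tokens[0], tokens[1]
    try:
        span = Span(int(tokens[2]), int(tokens[3]))
    except ValueError as exc:
        raise StandoffError(f"malformed offsets: {exc}", line) from exc
    rest = " ".join(tokens[4:]).strip()
    if not rest:
        surface = None
        if text is not None:
            if span.end > len(text):
                raise StandoffError("span beyond document end", line)
            surface = text[span.beg : span.end]
        return TextBound(tid, ann_type, span, surface)
    # a trailing "<min_beg> <min_end> [head]" group inside the full span marks
    # the minimal (head) span of a coreference markable
    m = _MIN_SPAN_RE.match(rest)
    if m is not None:
        b, e = int(m.group("b")), int(m.group("e"))
        if span.beg <= b < e <= span.end:
            return TextBound(tid, ann_type, span, m.group("text"), Span(b, e))
    return TextBound(tid, ann_type, span, rest)


def _parse_event(line: str) -> EventFrame:
    body = line.replace("\t", " ")
    tokens = [t for t in body.split(" ") if t]
    if len(tokens) < 2:
        raise StandoffError("too few fields in event line", line)
    eid = tokens[0]
    ev_type, trigger = _split_ref(tokens[1], line)
    args = []
    for token in tokens[2:]:
        role, target = _split_ref(token, line)
        args.append((_normalize_role(role, line), target))
    return EventFrame(eid, ev_type, trigger, tuple(args))


def _parse_modification(line: str) -> EventModification:
    tokens = [t for t in line.replace("\t", " ").split(" ") if t]
    if len(tokens) != 3:
        raise StandoffError("modification line must be 'M<id> <type> E<id>'", line)
    mid, mod_type, event = tokens
    if mod_type not in _MOD_TYPES:
        raise StandoffError(f"unknown modification type {mod_type!r}", line)
    return EventModification(mid, mod_type, event)


_R_RE = re.compile(
    r"^(?P<id>R\S*)[\t ]+Coref[\t ]+Ana(?:phora)?:(?P<ana>\S+)[\t ]+"
    r"Ant(?:ecedent)?:(?P<ant>\S+)(?:[\t ]+\[(?P<prots>[^\]]*)\])?\s*$"
)


def _parse_relation(line: str) -> CorefRelation:
    m = _R_RE.match(line)
    if m is None:
        raise StandoffError("malformed coreference relation line", line)
    prots: tuple[str, ...] = ()
    if m.group("prots"):
        prots = tuple(p.strip() for p in m.group("prots").split(",") if p.strip())
    return CorefRelation(m.group("id"), m.group("ana"), m.group("ant"), prots)


def parse_document(
    text: str | None,
    annotation_lines: Iterable[str],
    doc_id: str = "doc",
    section: str | None = None,
) -> Document:
    """Parse standoff annotation lines against a document text.

    ``text`` may be ``None`` when only the annotation structure is of
    interest (span/text agreement then goes unchecked).  Unknown line kinds
    are retained on ``Document.unknown_lines`` rather than silently dropped.
    Duplicate identifiers, dangling references and cyclic event references
    raise :class:`StandoffError` naming the offending annotation.
    """
    doc = Document(doc_id=doc_id, text=text, section=section)

    def _add(collection: dict, obj, line: str) -> None:
        if obj.id in doc.text_bounds or obj.id in doc.events \
                or obj.id in doc.modifications or obj.id in doc.coref_relations:
            raise StandoffError(f"duplicate identifier {obj.id}", line)
        collection[obj.id] = obj

    for raw in annotation_lines:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        kind = line[0]
        if kind == "T":
            _add(doc.text_bounds, _parse_textbound(line, text), line)
        elif kind == "E":
            _add(doc.events, _parse_event(line), line)
        elif kind == "M":
            _add(doc.modifications, _parse_modification(line), line)
        elif kind == "R":
            _add(doc.coref_relations, _parse_relation(line), line)
        else:
            doc.unknown_lines.append(line)
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# serialization


def _format_textbound(tb: TextBound, text: str | None) -> str:
    surface = tb.text
    if surface is None and text is not None:
        surface = text[tb.span.beg : tb.span.end]
    line = f"{tb.id}\t{tb.ann_type} {tb.span.beg} {tb.span.end}"
    if surface is not None:
        line += f"\t{surface}"
    if tb.min_span is not None and tb.min_span != tb.span:
        head = ""
        if surface is not None:
            head = surface[tb.min_span.beg - tb.span.beg : tb.min_span.end - tb.span.beg]
        line += f"\t{tb.min_span.beg} {tb.min_span.end}\t{head}"
    return line


def serialize_document(doc: Document) -> list[str]:
    """Serialize a document's annotations to standoff lines.

    ``parse_document(doc.text, serialize_document(doc))`` reproduces the
    document (round-trip identity up to line order).
    """
    lines: list[str] = []
    for tb in doc.text_bounds.values():
        lines.append(_format_textbound(tb, doc.text))
    for ev in doc.events.values():
        parts = [f"{ev.ev_type}:{ev.trigger}"] + [f"{r}:{t}" for r, t in ev.args]
        lines.append(f"{ev.id}\t" + " ".join(parts))
    for mod in doc.modifications.values():
        lines.append(f"{mod.id}\t{mod.mod_type} {mod.event}")
    for rel in doc.coref_relations.values():
        line = f"{rel.id}\tCoref Ana:{rel.anaphora} Ant:{rel.antecedent}"
        if rel.proteins:
            line += " [" + ", ".join(rel.proteins) + "]"
        lines.append(line)
    lines.extend(doc.unknown_lines)
    return lines


# ---------------------------------------------------------------------------
# file-system layout (.txt / .a1 / .a2)


def write_document(doc: Document, directory: str | Path) -> None:
    """Write ``<doc_id>.txt``, ``.a1`` (Proteins) and ``.a2`` (the rest)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if doc.text is not None:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text, encoding="utf-8")
    a1_ids = {tb.id for tb in doc.proteins()}
    all_lines = serialize_document(doc)
    a1 = [ln for ln in all_lines if ln.split("\t", 1)[0] in a1_ids]
    a2 = [ln for ln in all_lines if ln.split("\t", 1)[0] not in a1_ids]
    (directory / f"{doc.doc_id}.a1").write_text(
        "".join(ln + "\n" for ln in a1), encoding="utf-8"
    )
    (directory / f"{doc.doc_id}.a2").write_text(
        "".join(ln + "\n" for ln in a2), encoding="utf-8"
    )


def read_document(directory: str | Path, doc_id: str) -> Document:
    directory = Path(directory)
    txt = directory / f"{doc_id}.txt"
    text = txt.read_text(encoding="utf-8") if txt.exists() else None
    lines: list[str] = []
    for suffix in (".a1", ".a2"):
        path = directory / f"{doc_id}{suffix}"
        if path.exists():
            lines.extend(path.read_text(encoding="utf-8").splitlines())
    return parse_document(text, lines, doc_id=doc_id)


def read_corpus(directory: str | Path) -> dict[str, Document]:
    """Read every ``<doc_id>.txt`` (or orphan ``.a1``) document in a directory."""
    directory = Path(directory)
    doc_ids = sorted(
        {p.stem for p in directory.iterdir() if p.suffix in (".txt", ".a1", ".a2")}
    )
    return {doc_id: read_document(directory, doc_id) for doc_id in doc_ids}


def write_corpus(docs: Iterable[Document], directory: str | Path) -> None:
    for doc in docs:
        write_document(doc, directory)
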