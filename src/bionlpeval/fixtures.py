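"""Seeded synthetic standoff corpora with controlled-error predictions.

The generator builds small documents from a vocabulary of gene-symbol-like
tokens and trigger nominalizations, one construct per sentence (a simple
event, a multi-Theme binding, a regulation with a nested regulation
argument, or a coreference chain), so every scorer has inputs whose correct
scores are known by construction.  :func:`perturb` applies a controlled
error budget to a copy of the gold corpus and returns, alongside the
perturbed predictions, the closed-form expected count table for every
matching-mode combination -- the central oracle for the scorer test suite.

Each perturbation is engineered to be *local*: constructs live in separate
sentences, every event has its own trigger span, and approximate span
matching only ever reaches one word beyond a gold span, so an injected error
changes exactly the matches its bookkeeping says it changes.
"""

from __future__ import annotations

import copy
import random
from dataclasses import dataclass, field, replace
from typing import Iterable

from .standoff import (
    CorefRelation,
    Document,
    EventFrame,
    EventModification,
    EVENT_TYPES,
    REGULATION_TYPES,
    SIMPLE_TYPES,
    Span,
    TextBound,
)

__all__ = [
    "FixtureParams",
    "ErrorBudget",
    "FixtureCorpus",
    "ExpectedScores",
    "Counts",
    "FixtureError",
    "generate_gold",
    "perturb",
    "TASK1_COMBOS",
    "PAIR_COMBOS",
]


class FixtureError(ValueError):
    """Raised for infeasible generator parameters or error budgets."""


# span/recursive mode pairs, and the full task-1 combination grid
PAIR_COMBOS: tuple[tuple[str, str], ...] = tuple(
    (s, r)
    for s in ("strict", "approximate")
    for r in ("strict", "approximate")
)
TASK1_COMBOS: tuple[tuple[str, str, bool], ...] = tuple(
    (s, r, d) for s, r in PAIR_COMBOS for d in (False, True)
)

_PROTEINS = [
    "p65", "p50", "STAT1", "IkBa", "TRAF2", "IL2RA", "FOXP3", "GATA3",
    "NFKB1", "RELA", "JUNB", "CREB1", "TNFA", "IFNG", "CD28", "LCK",
]
_TRIGGERS = {
    "Gene_expression": ["expression", "production", "synthesis"],
    "Transcription": ["transcription", "transcribing"],
    "Protein_catabolism": ["degradation", "proteolysis"],
    "Phosphorylation": ["phosphorylation"],
    "Localization": ["translocation", "secretion"],
    "Binding": ["binding", "interaction", "association"],
    "Regulation": ["regulation", "modulation", "control"],
    "Positive_regulation": ["activation", "induction", "upregulation"],
    "Negative_regulation": ["inhibition", "suppression", "downregulation"],
}
_SITES = ["Ser32", "Tyr701", "Thr180", "Lys48"]
_LOCATIONS = ["nucleus", "cytoplasm", "membrane"]

# default event-type proportions follow the make-up of an abstract-collection
# training corpus: expression/binding/regulation dominate, catabolism is rare
_DEFAULT_MIX = {
    "Gene_expression": 0.202,
    "Transcription": 0.067,
    "Protein_catabolism": 0.013,
    "Phosphorylation": 0.020,
    "Localization": 0.031,
    "Binding": 0.103,
    "Regulation": 0.112,
    "Positive_regulation": 0.330,
    "Negative_regulation": 0.122,
}


@dataclass(frozen=True)
class FixtureParams:
    seed: int = 0
    n_docs: int = 6
    events_per_doc: tuple[int, int] = (4, 8)
    type_mix: dict[str, float] | None = None
    nesting_prob: float = 0.4
    secondary_arg_prob: float = 0.15
    negation_prob: float = 0.06
    speculation_prob: float = 0.05
    coref_links_per_doc: tuple[int, int] = (1, 3)
    protein_antecedent_prob: float = 0.6
    chain_length: tuple[int, int] = (1, 2)

    def mix(self) -> dict[str, float]:
        mix = dict(self.type_mix or _DEFAULT_MIX)
        unknown = set(mix) - set(EVENT_TYPES)
        if unknown:
            raise FixtureError(f"unknown event types in mix: {sorted(unknown)}")
        total = sum(mix.values())
        if total <= 0 or abs(total - 1.0) > 1e-6:
            raise FixtureError("type_mix proportions must sum to 1")
        return mix

    def validate(self) -> None:
        self.mix()
        for name in (
            "nesting_prob",
            "secondary_arg_prob",
            "negation_prob",
            "speculation_prob",
            "protein_antecedent_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureError(f"{name} must be in [0,1], got {v}")
        for name in ("events_per_doc", "coref_links_per_doc", "chain_length"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise FixtureError(f"bad range for {name}: ({lo},{hi})")
        if self.n_docs < 1:
            raise FixtureError("n_docs must be >= 1")
        if self.events_per_doc[1] == 0 and self.nesting_prob > 0:
            raise FixtureError("nesting requested with zero events per doc")
        if self.chain_length[0] < 1:
            raise FixtureError("chain_length must start at 1")


@dataclass(frozen=True)
class ErrorBudget:
    """Counts of controlled errors to inject into a prediction corpus."""

    drop_events: int = 0
    spurious_events: int = 0
    span_shift_within_word: int = 0
    span_shift_beyond_word: int = 0
    type_swaps: int = 0
    theme_drops: int = 0
    nested_cause_perturbations: int = 0
    mod_drops: int = 0
    secondary_swaps: int = 0
    wrong_antecedents: int = 0
    dropped_links: int = 0


# ---------------------------------------------------------------------------
# bookkeeping containers


@dataclass
class Counts:
    gold: int = 0
    answer: int = 0
    rmatch: int = 0
    pmatch: int = 0

    def bump(self, d_gold=0, d_answer=0, d_rmatch=0, d_pmatch=0) -> None:
        self.gold += d_gold
        self.answer += d_answer
        self.rmatch += d_rmatch
        self.pmatch += d_pmatch

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.gold, self.answer, self.rmatch, self.pmatch)


@dataclass
class ExpectedScores:
    """Closed-form expected count tables per task and mode combination.

    ``task1`` is keyed by ``(span_mode, recursive_mode, decomposition)`` and
    maps event type -> Counts; ``task2``/``task3`` are keyed by
    ``(span_mode, recursive_mode)``.  Coreference expectations cover both
    surface and protein modes (plus a per-anaphora-type breakdown).
    """

    task1: dict[tuple[str, str, bool], dict[str, Counts]] = field(default_factory=dict)
    task2: dict[tuple[str, str], dict[str, Counts]] = field(default_factory=dict)
    task3: dict[tuple[str, str], dict[str, Counts]] = field(default_factory=dict)
    coref_surface: Counts = field(default_factory=Counts)
    coref_protein: Counts = field(default_factory=Counts)
    coref_protein_by_label: dict[str, Counts] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# construct registry


@dataclass
class EventConstruct:
    doc_id: str
    kind: str  # simple | binding | regulation | nested | spare
    ev_type: str
    event_id: str | None
    trigger_id: str | None
    clean: bool = True
    mod_id: str | None = None
    has_secondary: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class CorefConstruct:
    doc_id: str
    relation_ids: list[str]  # chain order; first links the base anaphor
    anaphor_ids: list[str]
    labels: list[str]
    protein_ids: list[str]  # embedded in the ultimate antecedent
    decoy_id: str


@dataclass
class FixtureCorpus:
    docs: dict[str, Document]
    params: FixtureParams
    event_constructs: list[EventConstruct] = field(default_factory=list)
    coref_constructs: list[CorefConstruct] = field(default_factory=list)
    anaphora_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    #: exact annotation counts for corpus-statistics recovery tests
    counts: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# document builder


class _DocBuilder:
    def __init__(self, doc_id: str, section: str | None = None):
        self.doc_id = doc_id
        self.section = section
        self.tokens: list[str] = []
        self.pos = 0
        self._n = {"T": 0, "E": 0, "M": 0, "R": 0}
        self.text_bounds: dict[str, TextBound] = {}
        self.events: dict[str, EventFrame] = {}
        self.modifications: dict[str, EventModification] = {}
        self.coref_relations: dict[str, CorefRelation] = {}

    def _next(self, prefix: str) -> str:
        self._n[prefix] += 1
        return f"{prefix}{self._n[prefix]}"

    def word(self, token: str) -> Span:
        if self.tokens:
            self.pos += 1  # separating space
        beg = self.pos
        self.tokens.append(token)
        self.pos += len(token)
        return Span(beg, self.pos)

    def words(self, tokens: Iterable[str]) -> list[Span]:
        return [self.word(t) for t in tokens]

    def tb(self, ann_type: str, span: Span, min_span: Span | None = None) -> str:
        tid = self._next("T")
        self.text_bounds[tid] = TextBound(tid, ann_type, span, None, min_span)
        return tid

    def event(self, ev_type: str, trigger: str, args: Iterable[tuple[str, str]]) -> str:
        eid = self._next("E")
        self.events[eid] = EventFrame(eid, ev_type, trigger, tuple(args))
        return eid

    def mod(self, mod_type: str, event: str) -> str:
        mid = self._next("M")
        self.modifications[mid] = EventModification(mid, mod_type, event)
        return mid

    def relation(self, ana: str, ant: str, proteins: tuple[str, ...] = ()) -> str:
        rid = self._next("R")
        self.coref_relations[rid] = CorefRelation(rid, ana, ant, proteins)
        return rid

    def finish(self) -> Document:
        text = " ".join(self.tokens)
        bounds = {
            tid: replace(tb, text=text[tb.span.beg : tb.span.end])
            for tid, tb in self.text_bounds.items()
        }
        doc = Document(
            doc_id=self.doc_id,
            text=text,
            text_bounds=bounds,
            events=self.events,
            modifications=self.modifications,
            coref_relations=self.coref_relations,
            section=self.section,
        )
        doc.validate()
        return doc


# ---------------------------------------------------------------------------
# gold generation


def _choose_type(rng: random.Random, mix: dict[str, float]) -> str:
    types = list(mix)
    return rng.choices(types, weights=[mix[t] for t in types], k=1)[0]


def _gen_event_construct(
    b: _DocBuilder, rng: random.Random, params: FixtureParams, ev_type: str
) -> EventConstruct:
    trig_word = rng.choice(_TRIGGERS[ev_type])
    p1 = rng.choice(_PROTEINS)

    if ev_type in REGULATION_TYPES and rng.random() < params.nesting_prob:
        # regulation with a nested regulation argument plus a spare protein
        # (the spare supports a Cause-retargeting perturbation)
        g_word = rng.choice(_TRIGGERS["Positive_regulation"])
        p2, p3 = rng.sample(_PROTEINS, 2)
        spans = b.words(
            ["the", trig_word, "of", "the", g_word, "of", p1, "by", p2,
             "near", p3, "was", "seen", "."]
        )
        r_trig = b.tb(ev_type, spans[1])
        g_trig = b.tb("Positive_regulation", spans[4])
        tp1 = b.tb("Protein", spans[6])
        tp2 = b.tb("Protein", spans[8])
        tp3 = b.tb("Protein", spans[10])
        g_ev = b.event("Positive_regulation", g_trig, [("Theme", tp1), ("Cause", tp2)])
        r_ev = b.event(ev_type, r_trig, [("Theme", g_ev)])
        return EventConstruct(
            b.doc_id, "nested", ev_type, r_ev, r_trig,
            meta={"sub_event": g_ev, "spare_protein": tp3},
        )

    if ev_type == "Binding":
        n_themes = rng.choice([2, 2, 3])
        prots = rng.sample(_PROTEINS, n_themes)
        tokens = ["indeed", "the", trig_word, "of", prots[0]]
        for p in prots[1:]:
            tokens += ["and", p]
        has_site = rng.random() < params.secondary_arg_prob
        if has_site:
            site = rng.choice(_SITES)
            tokens += ["at", site]
        tokens += ["was", "seen", "."]
        spans = b.words(tokens)
        trig = b.tb(ev_type, spans[2])
        theme_ids = []
        idx = 4
        theme_ids.append(b.tb("Protein", spans[idx]))
        for _ in prots[1:]:
            idx += 2
            theme_ids.append(b.tb("Protein", spans[idx]))
        args: list[tuple[str, str]] = [("Theme", t) for t in theme_ids]
        if has_site:
            ent = b.tb("Entity", spans[idx + 2])
            args.append(("Site", ent))
        ev = b.event(ev_type, trig, args)
        con = EventConstruct(
            b.doc_id, "binding", ev_type, ev, trig,
            clean=not has_site, has_secondary=has_site,
            meta={"themes": theme_ids, "within": spans[1], "beyond": spans[0]},
        )
        return _maybe_modify(b, rng, params, con)

    if ev_type in REGULATION_TYPES:
        # flat regulation: protein Theme, optional protein Cause, optional Site
        has_cause = rng.random() < 0.5
        has_site = rng.random() < params.secondary_arg_prob
        tokens = ["indeed", "the", trig_word, "of", p1]
        if has_cause:
            p2 = rng.choice([p for p in _PROTEINS if p != p1])
            tokens += ["by", p2]
        if has_site:
            tokens += ["at", rng.choice(_SITES)]
        tokens += ["was", "seen", "."]
        spans = b.words(tokens)
        trig = b.tb(ev_type, spans[2])
        args = [("Theme", b.tb("Protein", spans[4]))]
        idx = 4
        if has_cause:
            idx += 2
            args.append(("Cause", b.tb("Protein", spans[idx])))
        if has_site:
            idx += 2
            args.append(("Site", b.tb("Entity", spans[idx])))
        ev = b.event(ev_type, trig, args)
        con = EventConstruct(
            b.doc_id, "regulation", ev_type, ev, trig,
            clean=not has_site, has_secondary=has_site,
            meta={"within": spans[1], "beyond": spans[0]},
        )
        return _maybe_modify(b, rng, params, con)

    # simple unary-Theme event, optional type-appropriate secondary argument
    secondary: tuple[str, str] | None = None
    tokens = ["indeed", "the", trig_word, "of", p1]
    if ev_type == "Phosphorylation" and rng.random() < params.secondary_arg_prob:
        secondary = ("Site", rng.choice(_SITES))
        tokens += ["at", secondary[1]]
    elif ev_type == "Localization" and rng.random() < params.secondary_arg_prob:
        role = rng.choice(["AtLoc", "ToLoc"])
        secondary = (role, rng.choice(_LOCATIONS))
        tokens += ["into" if role == "ToLoc" else "in", "the", secondary[1]]
    tokens += ["was", "seen", "."]
    spans = b.words(tokens)
    trig = b.tb(ev_type, spans[2])
    args = [("Theme", b.tb("Protein", spans[4]))]
    if secondary is not None:
        ent_idx = 6 if secondary[0] == "Site" else 7
        args.append((secondary[0], b.tb("Entity", spans[ent_idx])))
    ev = b.event(ev_type, trig, args)
    con = EventConstruct(
        b.doc_id, "simple", ev_type, ev, trig,
        clean=secondary is None, has_secondary=secondary is not None,
        meta={"within": spans[1], "beyond": spans[0]},
    )
    return _maybe_modify(b, rng, params, con)


def _maybe_modify(
    b: _DocBuilder, rng: random.Random, params: FixtureParams, con: EventConstruct
) -> EventConstruct:
    if rng.random() < params.negation_prob:
        con.mod_id = b.mod("Negation", con.event_id)
    elif rng.random() < params.speculation_prob:
        con.mod_id = b.mod("Speculation", con.event_id)
    if con.mod_id is not None:
        con.clean = False
    return con


def _gen_spare(b: _DocBuilder, rng: random.Random) -> EventConstruct:
    """A sentence whose trigger word is left unannotated in the gold corpus;
    predictions may annotate it to create a spurious event."""
    p = rng.choice(_PROTEINS)
    spans = b.words(
        ["separately", "marked", "expression", "of", p, "near", "Ser99",
         "was", "noted", "."]
    )
    prot = b.tb("Protein", spans[4])
    ent = b.tb("Entity", spans[6])
    return EventConstruct(
        b.doc_id, "spare", "Gene_expression", None, None,
        meta={"trigger_span": spans[2], "protein": prot, "entity": ent},
    )


_ANAPHOR_STYLES = {
    "DNP": (["this", "complex", "was", "stable", "."], (0, 2), (1, 2)),
    "Relative pronoun": (["which", "was", "active", "."], (0, 1), (0, 1)),
    "Pronoun": (["it", "remained", "there", "."], (0, 1), (0, 1)),
}


def _gen_coref_chain(
    b: _DocBuilder, rng: random.Random, params: FixtureParams
) -> CorefConstruct:
    with_protein = rng.random() < params.protein_antecedent_prob
    protein_ids: list[str] = []
    if with_protein:
        n_prot = rng.choice([1, 2])
        prots = rng.sample(_PROTEINS, n_prot)
        tokens = ["the", prots[0]]
        for p in prots[1:]:
            tokens += ["and", p]
        tokens += ["protein", "complex", "formed", "quickly", "."]
        spans = b.words(tokens)
        for i in range(n_prot):
            protein_ids.append(b.tb("Protein", spans[1 + 2 * i]))
        head_idx = 1 + 2 * (n_prot - 1) + 2  # the "complex" token
        ant_span = Span(spans[0].beg, spans[head_idx].end)
        ant_id = b.tb("Exp", ant_span, min_span=spans[head_idx])
    else:
        spans = b.words(["the", "earlier", "procedure", "was", "repeated", "."])
        ant_span = Span(spans[0].beg, spans[2].end)
        ant_id = b.tb("Exp", ant_span, min_span=spans[2])

    chain_len = rng.randint(*params.chain_length)
    anaphor_ids: list[str] = []
    labels: list[str] = []
    relation_ids: list[str] = []
    prev = ant_id
    for k in range(chain_len):
        style = rng.choice(["DNP", "Relative pronoun"]) if k == 0 else "Pronoun"
        tokens, (lo, hi), (mlo, mhi) = _ANAPHOR_STYLES[style]
        spans = b.words(tokens)
        ana_span = Span(spans[lo].beg, spans[hi - 1].end)
        min_span = Span(spans[mlo].beg, spans[mhi - 1].end)
        ana_id = b.tb("Exp", ana_span, min_span=min_span)
        prots = tuple(protein_ids) if prev == ant_id and with_protein else ()
        relation_ids.append(b.relation(ana_id, prev, prots))
        anaphor_ids.append(ana_id)
        labels.append(style)
        prev = ana_id

    # a protein-free decoy markable, available as a wrong antecedent
    spans = b.words(["a", "novel", "method", "was", "used", "."])
    decoy_id = b.tb("Exp", Span(spans[0].beg, spans[2].end), min_span=spans[2])
    return CorefConstruct(
        b.doc_id, relation_ids, anaphor_ids, labels, protein_ids, decoy_id
    )


def generate_gold(params: FixtureParams) -> FixtureCorpus:
    """Generate a schema-valid gold corpus; identical params give identical output."""
    params.validate()
    rng = random.Random(params.seed)
    mix = params.mix()
    corpus = FixtureCorpus(docs={}, params=params)
    counts = {
        "words": 0,
        "proteins": 0,
        "triggers": 0,
        "events": 0,
        "events_by_type": {t: 0 for t in EVENT_TYPES},
        "coreferences": 0,
    }
    for d in range(params.n_docs):
        doc_id = f"FIX{d:03d}"
        b = _DocBuilder(doc_id)
        n_events = rng.randint(*params.events_per_doc)
        for _ in range(n_events):
            con = _gen_event_construct(b, rng, params, _choose_type(rng, mix))
            corpus.event_constructs.append(con)
        corpus.event_constructs.append(_gen_spare(b, rng))
        n_chains = rng.randint(*params.coref_links_per_doc)
        for _ in range(n_chains):
            chain = _gen_coref_chain(b, rng, params)
            corpus.coref_constructs.append(chain)
            for ana, lab in zip(chain.anaphor_ids, chain.labels):
                corpus.anaphora_labels[(doc_id, ana)] = lab
        doc = b.finish()
        corpus.docs[doc_id] = doc
        counts["words"] += len(doc.text.split())
        counts["proteins"] += len(doc.proteins())
        counts["triggers"] += len({e.trigger for e in doc.events.values()})
        counts["events"] += len(doc.events)
        for ev in doc.events.values():
            counts["events_by_type"][ev.ev_type] += 1
        counts["coreferences"] += len(doc.coref_relations)
    corpus.counts = counts
    return corpus


# ---------------------------------------------------------------------------
# perturbation with expected-score bookkeeping


def _primary_arity(ev: EventFrame) -> int:
    from .standoff import SECONDARY_ROLES

    return max(1, sum(1 for r, _ in ev.args if r not in SECONDARY_ROLES))


def _baseline_expected(corpus: FixtureCorpus) -> ExpectedScores:
    exp = ExpectedScores()
    type_counts = {t: 0 for t in EVENT_TYPES}
    unit_counts = {t: 0 for t in EVENT_TYPES}
    for doc in corpus.docs.values():
        for ev in doc.events.values():
            type_counts[ev.ev_type] += 1
            unit_counts[ev.ev_type] += _primary_arity(ev)
    for combo in TASK1_COMBOS:
        source = unit_counts if combo[2] else type_counts
        exp.task1[combo] = {
            t: Counts(n, n, n, n) for t, n in source.items()
        }

    t2_cats = ["Sites", "Locations", "All", "Sites:Phosphorylation",
               "Sites:Binding", "Sites:Regulation"]
    t2_counts = {c: 0 for c in t2_cats}
    t3_counts = {c: 0 for c in ("Negation", "Speculation", "All")}
    for doc in corpus.docs.values():
        for ev in doc.events.values():
            for role, _ in ev.args:
                if role in ("Site", "CSite"):
                    t2_counts["Sites"] += 1
                    t2_counts["All"] += 1
                    if ev.ev_type == "Phosphorylation":
                        t2_counts["Sites:Phosphorylation"] += 1
                    elif ev.ev_type == "Binding":
                        t2_counts["Sites:Binding"] += 1
                    elif ev.ev_type in REGULATION_TYPES:
                        t2_counts["Sites:Regulation"] += 1
                elif role in ("AtLoc", "ToLoc"):
                    t2_counts["Locations"] += 1
                    t2_counts["All"] += 1
        for mod in doc.modifications.values():
            t3_counts[mod.mod_type] += 1
            t3_counts["All"] += 1
    for combo in PAIR_COMBOS:
        exp.task2[combo] = {c: Counts(n, n, n, n) for c, n in t2_counts.items()}
        exp.task3[combo] = {c: Counts(n, n, n, n) for c, n in t3_counts.items()}

    n_links = sum(len(d.coref_relations) for d in corpus.docs.values())
    exp.coref_surface = Counts(n_links, n_links, n_links, n_links)
    n_plinks = 0
    by_label: dict[str, int] = {}
    for chain in corpus.coref_constructs:
        k = len(chain.protein_ids)
        n_plinks += k * len(chain.anaphor_ids)
        for lab in chain.labels:
            by_label[lab] = by_label.get(lab, 0) + k
    exp.coref_protein = Counts(n_plinks, n_plinks, n_plinks, n_plinks)
    exp.coref_protein_by_label = {
        lab: Counts(n, n, n, n) for lab, n in sorted(by_label.items())
    }
    return exp


def _take(rng: random.Random, pool: list, n: int, what: str) -> list:
    if n > len(pool):
        raise FixtureError(
            f"budget requests {n} x {what} but only {len(pool)} available"
        )
    picked = rng.sample(pool, n)
    for item in picked:
        pool.remove(item)
    return picked


def _shift_trigger(doc: Document, con: EventConstruct, new_beg_span: Span) -> None:
    tb = doc.text_bounds[con.trigger_id]
    new_span = Span(new_beg_span.beg, tb.span.end)
    doc.text_bounds[con.trigger_id] = replace(
        tb, span=new_span, text=doc.text[new_span.beg : new_span.end]
    )


def perturb(
    gold: FixtureCorpus, budget: ErrorBudget, seed: int = 0
) -> tuple[dict[str, Document], ExpectedScores]:
    """Apply a controlled error budget to a copy of the gold corpus.

    Returns the perturbed prediction documents and the expected count table
    for every task and mode combination, derived purely from the budget
    bookkeeping (never by running the scorers).
    """
    rng = random.Random(seed)
    pred = {doc_id: copy.deepcopy(doc) for doc_id, doc in gold.docs.items()}
    exp = _baseline_expected(gold)

    strict_span = [c for c in TASK1_COMBOS if c[0] == "strict"]
    strict_rec = [c for c in TASK1_COMBOS if c[1] == "strict"]
    decomp_on = [c for c in TASK1_COMBOS if c[2]]
    decomp_off = [c for c in TASK1_COMBOS if not c[2]]

    def bump1(combos, ev_type, **kw):
        for c in combos:
            exp.task1[c][ev_type].bump(**kw)

    clean_simple = [
        c for c in gold.event_constructs
        if c.kind in ("simple", "regulation") and c.clean
        and c.kind == "simple"
    ]
    clean_binding = [
        c for c in gold.event_constructs if c.kind == "binding" and c.clean
    ]
    nested = [c for c in gold.event_constructs if c.kind == "nested"]
    modded = [c for c in gold.event_constructs if c.mod_id is not None]
    with_secondary = [
        c for c in gold.event_constructs
        if c.has_secondary and c.mod_id is None
    ]
    spares = [c for c in gold.event_constructs if c.kind == "spare"]
    protein_chains = [c for c in gold.coref_constructs if c.protein_ids]

    # --- dropped events: the gold event goes missing from the predictions
    for con in _take(rng, clean_simple, budget.drop_events, "droppable simple event"):
        del pred[con.doc_id].events[con.event_id]
        bump1(TASK1_COMBOS, con.ev_type, d_answer=-1, d_rmatch=-1, d_pmatch=-1)

    # --- spurious events: predictions annotate a trigger the gold left bare
    for con in _take(rng, spares, budget.spurious_events, "spare construct"):
        doc = pred[con.doc_id]
        span = con.meta["trigger_span"]
        tid = f"T{1000 + len(doc.text_bounds)}"
        doc.text_bounds[tid] = TextBound(
            tid, "Gene_expression", span, doc.text[span.beg : span.end]
        )
        eid = f"E{1000 + len(doc.events)}"
        doc.events[eid] = EventFrame(
            eid, "Gene_expression", tid, (("Theme", con.meta["protein"]),)
        )
        bump1(TASK1_COMBOS, "Gene_expression", d_answer=1)

    # --- trigger span shifted by one word: hurts strict spans only
    for con in _take(
        rng, clean_simple, budget.span_shift_within_word, "shiftable simple event"
    ):
        _shift_trigger(pred[con.doc_id], con, con.meta["within"])
        bump1(strict_span, con.ev_type, d_rmatch=-1, d_pmatch=-1)

    # --- trigger span shifted beyond one word: hurts every span mode
    for con in _take(
        rng, clean_simple, budget.span_shift_beyond_word, "shiftable simple event"
    ):
        _shift_trigger(pred[con.doc_id], con, con.meta["beyond"])
        bump1(TASK1_COMBOS, con.ev_type, d_rmatch=-1, d_pmatch=-1)

    # --- event type swapped to a sibling simple type
    for con in _take(rng, clean_simple, budget.type_swaps, "swappable simple event"):
        doc = pred[con.doc_id]
        i = SIMPLE_TYPES.index(con.ev_type)
        new_type = SIMPLE_TYPES[(i + 1) % len(SIMPLE_TYPES)]
        doc.text_bounds[con.trigger_id] = replace(
            doc.text_bounds[con.trigger_id], ann_type=new_type
        )
        doc.events[con.event_id] = replace(
            doc.events[con.event_id], ev_type=new_type
        )
        bump1(TASK1_COMBOS, con.ev_type, d_answer=-1, d_rmatch=-1, d_pmatch=-1)
        bump1(TASK1_COMBOS, new_type, d_answer=1)

    # --- one Binding Theme dropped: full event fails, decomposition gives
    #     partial credit for the remaining single-argument units
    for con in _take(rng, clean_binding, budget.theme_drops, "multi-Theme Binding"):
        doc = pred[con.doc_id]
        ev = doc.events[con.event_id]
        doc.events[con.event_id] = replace(ev, args=ev.args[:-1])
        bump1(decomp_off, "Binding", d_rmatch=-1, d_pmatch=-1)
        bump1(decomp_on, "Binding", d_answer=-1, d_rmatch=-1, d_pmatch=-1)

    # --- nested event's Cause retargeted: the nesting regulation still
    #     matches under approximate recursive matching (Theme-only check of
    #     the referred event) but fails under strict recursive matching
    for con in _take(
        rng, nested, budget.nested_cause_perturbations, "nested regulation"
    ):
        doc = pred[con.doc_id]
        sub = doc.events[con.meta["sub_event"]]
        new_args = tuple(
            (r, con.meta["spare_protein"]) if r == "Cause" else (r, t)
            for r, t in sub.args
        )
        doc.events[sub.id] = replace(sub, args=new_args)
        bump1(TASK1_COMBOS, "Positive_regulation", d_rmatch=-1, d_pmatch=-1)
        bump1(strict_rec, con.ev_type, d_rmatch=-1, d_pmatch=-1)

    # --- modification dropped from the predictions
    for con in _take(rng, modded, budget.mod_drops, "modified event"):
        doc = pred[con.doc_id]
        mod_type = doc.modifications[con.mod_id].mod_type
        del doc.modifications[con.mod_id]
        for combo in PAIR_COMBOS:
            for cat in (mod_type, "All"):
                exp.task3[combo][cat].bump(d_answer=-1, d_rmatch=-1, d_pmatch=-1)

    # --- secondary argument retargeted to the wrong entity
    for con in _take(
        rng, with_secondary, budget.secondary_swaps, "event with secondary argument"
    ):
        doc = pred[con.doc_id]
        spare_entity = next(
            s.meta["entity"] for s in gold.event_constructs
            if s.kind == "spare" and s.doc_id == con.doc_id
        )
        ev = doc.events[con.event_id]
        swapped_role = None
        new_args = []
        for r, t in ev.args:
            if swapped_role is None and r in ("Site", "CSite", "AtLoc", "ToLoc"):
                swapped_role = r
                new_args.append((r, spare_entity))
            else:
                new_args.append((r, t))
        doc.events[con.event_id] = replace(ev, args=tuple(new_args))
        cats = ["All", "Sites" if swapped_role in ("Site", "CSite") else "Locations"]
        if swapped_role in ("Site", "CSite"):
            if con.ev_type == "Phosphorylation":
                cats.append("Sites:Phosphorylation")
            elif con.ev_type == "Binding":
                cats.append("Sites:Binding")
            elif con.ev_type in REGULATION_TYPES:
                cats.append("Sites:Regulation")
        for combo in PAIR_COMBOS:
            for cat in cats:
                exp.task2[combo][cat].bump(d_rmatch=-1, d_pmatch=-1)

    # --- coreference chain rewired to a protein-free decoy antecedent
    def chain_protein_deltas(chain: CorefConstruct):
        k = len(chain.protein_ids)
        total = k * len(chain.anaphor_ids)
        return k, total

    for chain in _take(
        rng, protein_chains, budget.wrong_antecedents, "protein coreference chain"
    ):
        doc = pred[chain.doc_id]
        rid = chain.relation_ids[0]
        rel = doc.coref_relations[rid]
        doc.coref_relations[rid] = CorefRelation(
            rel.id, rel.anaphora, chain.decoy_id, ()
        )
        exp.coref_surface.bump(d_rmatch=-1, d_pmatch=-1)
        k, total = chain_protein_deltas(chain)
        exp.coref_protein.bump(d_answer=-total, d_rmatch=-total, d_pmatch=-total)
        for lab in chain.labels:
            exp.coref_protein_by_label[lab].bump(
                d_answer=-k, d_rmatch=-k, d_pmatch=-k
            )

    # --- coreference link dropped entirely
    for chain in _take(
        rng, protein_chains, budget.dropped_links, "protein coreference chain"
    ):
        doc = pred[chain.doc_id]
        del doc.coref_relations[chain.relation_ids[0]]
        exp.coref_surface.bump(d_answer=-1, d_rmatch=-1, d_pmatch=-1)
        k, total = chain_protein_deltas(chain)
        exp.coref_protein.bump(d_answer=-total, d_rmatch=-total, d_pmatch=-total)
        for lab in chain.labels:
            exp.coref_protein_by_label[lab].bump(
                d_answer=-k, d_rmatch=-k, d_pmatch=-k
            )

    for doc in pred.values():
        doc.validate()
    return pred, exp
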