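"""Span extension, text-entity equality, argument/event matching, decomposition."""

import itertools
import random

import pytest

from bionlpeval import (
    MatchConfig,
    Span,
    arguments_match,
    decompose,
    event_match,
    extend_span,
    parse_document,
    span_match,
    text_bound_match,
)
from bionlpeval.matching import _target_match
from bionlpeval.standoff import TextBound

STRICT = MatchConfig(span_mode="strict", recursive_mode="strict")
APPROX = MatchConfig()  # approximate span + approximate recursive


class TestExtendSpan:
    def test_one_word_each_side(self):
        text = "the p65 subunit"
        ext = extend_span(Span(4, 7), text)
        assert (ext.ebeg, ext.eend) == (0, 15)

    def test_clamps_at_document_start(self):
        ext = extend_span(Span(0, 3), "p65 binds")
        assert ext.ebeg == 0
        assert ext.eend == 9

    @pytest.mark.parametrize("beg,end", [(0, 4), (4, 7), (8, 15), (4, 15)])
    def test_extension_always_contains_gold(self, beg, end):
        ext = extend_span(Span(beg, end), "the p65 subunit")
        assert ext.ebeg <= beg and ext.eend >= end

    def test_punctuation_does_not_count_as_word(self):
        # the parenthesis run between words is not a word, so the extension
        # jumps over it to the previous real word
        text = "protein ( p65 ) binds"
        ext = extend_span(Span(10, 13), text)
        assert (ext.ebeg, ext.eend) == (0, 21)


class TestSpanMatch:
    def test_strict_requires_exact_offsets(self):
        text = "the p65 subunit"
        assert span_match(Span(4, 7), Span(4, 7), "strict", text)
        assert not span_match(Span(0, 7), Span(4, 7), "strict", text)

    def test_approximate_accepts_one_flanking_word(self):
        text = "the p65 subunit"
        assert span_match(Span(0, 7), Span(4, 7), "approximate", text)
        assert span_match(Span(4, 15), Span(4, 7), "approximate", text)

    def test_approximate_rejects_two_words_away(self):
        text = "in all the p65 subunit"
        # predicted span reaches back two words before the gold span
        assert not span_match(Span(3, 14), Span(11, 14), "approximate", text)

    def test_strict_implies_approximate(self):
        text = "the p65 subunit of NF-kappa B"
        rng = random.Random(0)
        words = [Span(m, m + 3) for m in range(0, 20, 4)]
        for pred, gold in itertools.product(words, repeat=2):
            if span_match(pred, gold, "strict", text):
                assert span_match(pred, gold, "approximate", text)


class TestTextBoundMatch:
    def test_identical_annotations_match(self):
        a = TextBound("T1", "Protein", Span(4, 7), "p65")
        assert text_bound_match(a, a, "strict", "the p65 subunit")

    def test_type_mismatch_fails_even_on_same_span(self):
        a = TextBound("T1", "Protein", Span(4, 7), "p65")
        b = TextBound("T2", "Entity", Span(4, 7), "p65")
        assert not text_bound_match(a, b, "approximate", "the p65 subunit")

    def test_one_word_wider_span_matches_approximately(self):
        gold = TextBound("T1", "Protein", Span(4, 7), "p65")
        pred = TextBound("T2", "Protein", Span(0, 7), "the p65")
        assert not text_bound_match(pred, gold, "strict", "the p65 subunit")
        assert text_bound_match(pred, gold, "approximate", "the p65 subunit")


def _two_sided_doc():
    """A document with interchangeable proteins and a Binding/Regulation pair."""
    text = "p65 p50 Ak1 Bk2 bind regu other p65"
    lines = [
        "T1 Protein 0 3 p65",
        "T2 Protein 4 7 p50",
        "T3 Protein 8 11 Ak1",
        "T4 Protein 12 15 Bk2",
        "T5 Binding 16 20 bind",
        "T6 Regulation 21 25 regu",
        "T7 Protein 32 35 p65",
    ]
    return parse_document(text, lines)


class TestArgumentsMatch:
    def test_binding_themes_are_order_free(self):
        doc = _two_sided_doc()
        assert arguments_match(
            [("Theme", "T1"), ("Theme", "T2")],
            [("Theme", "T2"), ("Theme", "T1")],
            STRICT,
            doc,
            doc,
        )

    def test_cardinality_mismatch_fails(self):
        doc = _two_sided_doc()
        assert not arguments_match(
            [("Theme", "T1")],
            [("Theme", "T1"), ("Theme", "T2")],
            STRICT,
            doc,
            doc,
        )

    def test_role_crossed_assignment_fails(self):
        doc = _two_sided_doc()
        assert not arguments_match(
            [("Theme", "T2"), ("Cause", "T1")],
            [("Theme", "T1"), ("Cause", "T2")],
            STRICT,
            doc,
            doc,
        )

    @pytest.mark.parametrize("size", [1, 2, 3, 4, 5, 6])
    def test_agrees_with_exhaustive_permutation_search(self, size):
        """Bipartite matching equals brute-force search for sets of size <= 6."""
        doc = _two_sided_doc()
        targets = ["T1", "T2", "T3", "T4", "T7"]
        roles = ["Theme", "Cause", "Site"]
        rng = random.Random(size)
        for _ in range(60):
            pred = [(rng.choice(roles), rng.choice(targets)) for _ in range(size)]
            gold = [(rng.choice(roles), rng.choice(targets)) for _ in range(size)]
            brute = any(
                all(
                    p[0] == g[0] and _target_match(p[1], g[1], STRICT, doc, doc)
                    for p, g in zip(perm, gold)
                )
                for perm in itertools.permutations(pred)
            )
            assert arguments_match(pred, gold, STRICT, doc, doc) is brute


def _nested_pair(site_on_pred: str):
    """Gold and predicted docs: Regulation(Theme -> Gene_expression) where the
    predicted inner event differs only in a Site argument."""
    # the two entities sit more than one word apart, so not even approximate
    # span matching can conflate them
    text = "regu expr p65 Ser32 xx yy Tyr70"
    gold_lines = [
        "T1 Regulation 0 4 regu",
        "T2 Gene_expression 5 9 expr",
        "T3 Protein 10 13 p65",
        "T4 Entity 14 19 Ser32",
        "T5 Entity 26 31 Tyr70",
        "E1 Gene_expression:T2 Theme:T3 Site:T4",
        "E2 Regulation:T1 Theme:E1",
    ]
    pred_lines = [ln for ln in gold_lines]
    pred_lines[5] = f"E1 Gene_expression:T2 Theme:T3 Site:{site_on_pred}"
    return parse_document(text, gold_lines), parse_document(text, pred_lines)


class TestEventMatch:
    def test_secondary_argument_ignored_in_task1_but_not_task2(self, event_doc):
        pred = parse_document(
            event_doc.text,
            [
                "T1 Protein 15 18 p65",
                "T2 Localization 19 32 translocation",
                "E1 Localization:T2 Theme:T1",
            ],
        )
        g, p = event_doc.events["E1"], pred.events["E1"]
        task1 = MatchConfig(task_level="task1")
        task2 = MatchConfig(task_level="task2")
        assert event_match(p, g, task1, pred, event_doc)
        assert not event_match(p, g, task2, pred, event_doc)

    def test_nested_site_difference_needs_approximate_recursive(self):
        gold, pred = _nested_pair("T5")
        strict_rec = MatchConfig(recursive_mode="strict", task_level="task2")
        approx_rec = MatchConfig(recursive_mode="approximate", task_level="task2")
        g, p = gold.events["E2"], pred.events["E2"]
        assert not event_match(p, g, strict_rec, pred, gold)
        assert event_match(p, g, approx_rec, pred, gold)

    def test_top_level_arguments_are_never_relaxed(self):
        # the relaxation applies only to events in argument position: the
        # inner event itself still fails against its gold counterpart
        gold, pred = _nested_pair("T5")
        approx = MatchConfig(recursive_mode="approximate", task_level="task2")
        assert not event_match(
            pred.events["E1"], gold.events["E1"], approx, pred, gold
        )

    @pytest.mark.parametrize(
        "config",
        [
            STRICT,
            APPROX,
            MatchConfig(span_mode="approximate", recursive_mode="strict"),
            MatchConfig(task_level="task2"),
        ],
        ids=["strict", "approx", "approx-span-only", "task2"],
    )
    def test_reflexive_in_every_mode(self, event_doc, config):
        ev = event_doc.events["E1"]
        assert event_match(ev, ev, config, event_doc, event_doc)


class TestDecompose:
    def test_binding_splits_into_single_theme_units(self):
        doc = _two_sided_doc()
        ev = parse_document(
            doc.text,
            [
                "T1 Protein 0 3 p65",
                "T2 Protein 4 7 p50",
                "T5 Binding 16 20 bind",
                "E1 Binding:T5 Theme:T1 Theme:T2",
            ],
        ).events["E1"]
        units = decompose([ev])
        assert len(units) == 2
        assert {u.args for u in units} == {(("Theme", "T1"),), (("Theme", "T2"),)}
        assert all(u.trigger == "T5" and u.ev_type == "Binding" for u in units)

    def test_single_argument_event_is_identity(self, event_doc):
        ev = event_doc.events["E1"]
        single = decompose([ev.__class__(ev.id, ev.ev_type, ev.trigger, ev.args[:1])])
        assert single[0].args == ev.args[:1]

    def test_idempotent_and_counts_sum_of_arities(self):
        from bionlpeval.standoff import EventFrame

        rng = random.Random(1)
        events = [
            EventFrame(f"E{i}", "Binding", "T5",
                       tuple(("Theme", rng.choice(["T1", "T2"]))
                             for _ in range(rng.randint(0, 3))))
            for i in range(20)
        ]
        units = decompose(events)
        assert len(units) == sum(max(1, len(e.args)) for e in events)
        assert decompose(units) == units
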