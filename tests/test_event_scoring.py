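"""Task 1/2/3 scoring: F-score arithmetic, derived counts, error handling."""

import pytest

from bionlpeval import (
    MatchConfig,
    compute_fscore,
    parse_document,
    score_task1,
    score_task2,
    score_task3,
)
from bionlpeval.event_scoring import DocumentSetMismatch
from bionlpeval.fixtures import ErrorBudget, generate_gold, perturb
from bionlpeval.metrics import ScoreRow, round_half_away

from conftest import oracle_params


class TestFscore:
    @pytest.mark.parametrize(
        "recall, precision, expected, decimals",
        [
            (22.2, 73.3, 34.1, 1),
            (48.62, 58.96, 53.29, 2),
            (0, 0, 0.0, 2),
            (100.0, 100.0, 100.0, 2),
        ],
    )
    def test_harmonic_mean_matches_reported_triples(
        self, recall, precision, expected, decimals
    ):
        assert round_half_away(compute_fscore(recall, precision), decimals) == expected

    def test_row_derives_percentages_from_counts(self):
        row = ScoreRow("x", gold_count=10, answer_count=9,
                       recall_matched=8, precision_matched=8)
        assert row.recall == 80.0
        assert round_half_away(row.precision, 2) == 88.89

    def test_zero_answer_precision_is_zero(self):
        row = ScoreRow("x", gold_count=1, answer_count=0)
        assert row.precision == 0.0
        assert row.fscore == 0.0


def _drop_and_add_corpus():
    """10 gold events; predictions drop 2 and add 1 spurious one."""
    corpus = generate_gold(
        oracle_params(seed=11, n_docs=2, events_per_doc=(5, 5),
                      nesting_prob=0.0, secondary_arg_prob=0.0,
                      negation_prob=0.0, speculation_prob=0.0)
    )
    pred, _ = perturb(
        corpus, ErrorBudget(drop_events=2, spurious_events=1), seed=1
    )
    return corpus.docs, pred


class TestTask1:
    def test_self_scoring_is_perfect(self):
        corpus = generate_gold(oracle_params(seed=3, n_docs=3))
        report = score_task1(corpus.docs, corpus.docs)
        row = report["[All]"]
        assert (row.recall, row.precision, row.fscore) == (100.0, 100.0, 100.0)

    def test_recall_and_precision_reflect_injected_errors(self):
        gold, pred = _drop_and_add_corpus()
        row = score_task1(gold, pred)["[All]"]
        assert (row.gold_count, row.answer_count) == (10, 9)
        assert row.recall == 80.0
        assert round_half_away(row.precision, 1) == 88.9

    def test_group_rows_sum_member_types(self):
        corpus = generate_gold(oracle_params(seed=9, n_docs=3))
        report = score_task1(corpus.docs, corpus.docs)
        from bionlpeval.event_scoring import GROUPS

        for group, members in GROUPS.items():
            assert report[group].gold_count == sum(
                report[t].gold_count for t in members
            )

    def test_document_set_mismatch_lists_missing(self):
        corpus = generate_gold(oracle_params(seed=2, n_docs=2))
        partial = dict(list(corpus.docs.items())[:1])
        with pytest.raises(DocumentSetMismatch) as err:
            score_task1(corpus.docs, partial)
        assert err.value.missing_in_pred

    def test_relaxed_modes_never_score_lower(self):
        corpus = generate_gold(oracle_params(seed=13))
        pred, _ = perturb(
            corpus,
            ErrorBudget(span_shift_within_word=3, nested_cause_perturbations=2),
            seed=5,
        )
        strict = score_task1(
            corpus.docs, pred, MatchConfig(span_mode="strict", recursive_mode="strict")
        )["[All]"]
        relaxed = score_task1(corpus.docs, pred, MatchConfig())["[All]"]
        assert relaxed.recall >= strict.recall
        assert relaxed.precision >= strict.precision


class TestTask2:
    def test_self_scoring_is_perfect(self):
        corpus = generate_gold(oracle_params(seed=4))
        report = score_task2(corpus.docs, corpus.docs)
        assert report["All"].gold_count > 0
        assert report["All"].triple() == "100.00/100.00/100.00"

    def test_location_argument_recovered_from_matching_host(self, event_doc):
        gold = {"D1": event_doc}
        pred = {"D1": parse_document(event_doc.text, [
            "T1 Protein 15 18 p65",
            "T2 Localization 19 32 translocation",
            "T3 Entity 40 46 nuclei",
            "E1 Localization:T2 Theme:T1 ToLoc:T3",
        ], doc_id="D1")}
        row = score_task2(gold, pred)["Locations"]
        assert (row.gold_count, row.recall_matched) == (1, 1)

    def test_wrong_entity_counts_against_both_sides(self):
        """4 gold Site arguments; 2 predicted correctly, 1 on a wrong entity."""
        text = "pho1 p65 Ser32 pho2 p50 Tyr70 pho3 Ak1 Thr18 pho4 Bk2 Lys48 Xtra9"
        def tb(i, typ, beg, end):
            return f"T{i} {typ} {beg} {end} {text[beg:end]}"
        gold_lines, pred_lines = [], []
        offsets = [(0, 4, 5, 8, 9, 14), (15, 19, 20, 23, 24, 29),
                   (30, 34, 35, 38, 39, 44), (45, 49, 50, 53, 54, 59)]
        for k, (tb_, te_, pb, pe, sb, se) in enumerate(offsets):
            i = 3 * k
            gold_lines += [
                tb(i + 1, "Phosphorylation", tb_, te_),
                tb(i + 2, "Protein", pb, pe),
                tb(i + 3, "Entity", sb, se),
                f"E{k + 1} Phosphorylation:T{i + 1} Theme:T{i + 2} Site:T{i + 3}",
            ]
        pred_lines = list(gold_lines)
        # third site retargeted to a far-away entity; fourth dropped entirely
        pred_lines.append(tb(90, "Entity", 60, 65))
        pred_lines[11] = "E3 Phosphorylation:T7 Theme:T8 Site:T90"
        pred_lines[15] = "E4 Phosphorylation:T10 Theme:T11"
        gold = {"D": parse_document(text, gold_lines, doc_id="D")}
        pred = {"D": parse_document(text, pred_lines, doc_id="D")}
        row = score_task2(gold, pred)["Sites"]
        assert (row.gold_count, row.answer_count) == (4, 3)
        assert row.recall == 50.0
        assert round_half_away(row.precision, 1) == 66.7


class TestTask3:
    def test_self_scoring_is_perfect(self):
        corpus = generate_gold(oracle_params(seed=6, negation_prob=0.5,
                                             speculation_prob=0.5))
        report = score_task3(corpus.docs, corpus.docs)
        assert report["All"].gold_count > 0
        assert report["All"].triple() == "100.00/100.00/100.00"

    def test_missing_modification_on_matching_event(self, event_doc):
        pred = {"D1": parse_document(event_doc.text, [
            "T1 Protein 15 18 p65",
            "T2 Localization 19 32 translocation",
            "E1 Localization:T2 Theme:T1",
        ], doc_id="D1")}
        row = score_task3({"D1": event_doc}, pred)["Negation"]
        assert (row.gold_count, row.recall_matched, row.answer_count) == (1, 0, 0)
        assert row.precision == 0.0

    def test_counts_reflect_injected_errors(self):
        """5 gold negations; 3 predicted correctly, 1 on an unmatched event."""
        text = " ".join(f"neg{k} p6{k}" for k in range(5)) + " negX p6X"
        gold_lines, pred_lines = [], []
        for k in range(5):
            b = k * 9
            gold_lines += [
                f"T{2*k+1} Gene_expression {b} {b+4} neg{k}",
                f"T{2*k+2} Protein {b+5} {b+8} p6{k}",
                f"E{k+1} Gene_expression:T{2*k+1} Theme:T{2*k+2}",
                f"M{k+1} Negation E{k+1}",
            ]
        # predictions: events 1-4 kept, event 5 dropped; negations on 1-3 kept,
        # a 4th negation attached to a spurious event on unannotated text
        pred_lines = [ln for ln in gold_lines
                      if not ln.startswith(("M4", "M5", "E5"))]
        pred_lines += [
            "T90 Gene_expression 45 49 negX",
            "T91 Protein 50 53 p6X",
            "E90 Gene_expression:T90 Theme:T91",
            "M90 Negation E90",
        ]
        gold = {"D": parse_document(text, gold_lines, doc_id="D")}
        pred = {"D": parse_document(text, pred_lines, doc_id="D")}
        row = score_task3(gold, pred)["Negation"]
        assert (row.gold_count, row.answer_count) == (5, 4)
        assert row.recall == 60.0
        assert row.precision == 75.0
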