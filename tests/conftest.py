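"""Shared fixtures: worked-example documents and oracle-friendly generator params."""

import pytest

from bionlpeval import parse_document
from bionlpeval.fixtures import FixtureParams

# a localization event with a ToLoc secondary argument, negated, laid out so
# that the annotation offsets index real substrings
FIG_EVENT_TEXT = "the failure of p65 translocation to the nuclei is shown"
FIG_EVENT_LINES = [
    "T1 Protein 15 18 p65",
    "T2 Localization 19 32 translocation",
    "T3 Entity 40 46 nuclei",
    "E1 Localization:T2 Theme:T1 ToLoc:T3",
    "M1 Negation E1",
]

# the coreference worked example: four surface links, two of which lead
# (directly or through an intermediate antecedent) to protein names
CO_EXAMPLE_LINES = [
    "T4 Protein 275 278 p65",
    "T5 Protein 294 297 p50",
    "T10 Protein 879 882 p65",
    "T27 Exp 179 222 the NF-kappa B transcription factor complex 215 222 complex",
    "T28 Exp 264 297 NF-kappa B p65 and p50",
    "T29 Exp 307 312 which",
    "T30 Exp 459 471 this complex 464 471 complex",
    "T31 Exp 868 882 NF-kappa B p65",
    "T32 Exp 1022 1047 this transcription factor 1027 1047 transcription factor",
    "T33 Exp 1100 1102 it",
    "R1 Coref Ana:T29 Ant:T28 [T5, T4]",
    "R2 Coref Ana:T30 Ant:T27",
    "R3 Coref Ana:T32 Ant:T31 [T10]",
    "R4 Coref Ana:T33 Ant:T32",
]


@pytest.fixture
def event_doc():
    return parse_document(FIG_EVENT_TEXT, FIG_EVENT_LINES, doc_id="D1")


@pytest.fixture
def coref_doc():
    return parse_document(None, CO_EXAMPLE_LINES, doc_id="CO")


def oracle_params(seed: int = 7, **overrides) -> FixtureParams:
    """Generator parameters guaranteeing well-stocked perturbation pools:
    simple-type-heavy mix, frequent nesting, mods and secondary arguments."""
    kwargs = dict(
        seed=seed,
        n_docs=10,
        events_per_doc=(8, 8),
        type_mix={
            "Gene_expression": 0.30,
            "Transcription": 0.10,
            "Protein_catabolism": 0.05,
            "Phosphorylation": 0.10,
            "Localization": 0.10,
            "Binding": 0.15,
            "Regulation": 0.05,
            "Positive_regulation": 0.10,
            "Negative_regulation": 0.05,
        },
        nesting_prob=0.8,
        secondary_arg_prob=0.35,
        negation_prob=0.15,
        speculation_prob=0.15,
        coref_links_per_doc=(2, 3),
        protein_antecedent_prob=0.8,
        chain_length=(1, 3),
    )
    kwargs.update(overrides)
    return FixtureParams(**kwargs)
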