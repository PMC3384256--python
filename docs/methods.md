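# Methods

This note documents the evaluation model the package implements, the
numerical and design choices that were genuinely open, and what the
synthetic-fixture tests do and do not establish.

## Annotation model

A document is plain text plus standoff records referencing it by 0-based,
end-exclusive character offsets:

* `T` — text-bounds: `Protein`, generic `Entity`, event triggers (typed like
  the event they anchor), and coreference markables (`Exp`) which may carry a
  second offset pair giving the minimal (head) span;
* `E` — events: one of nine types. Five *simple* types (Gene_expression,
  Transcription, Protein_catabolism, Phosphorylation, Localization) take a
  single protein Theme; Binding takes one or more Themes; the Regulation
  family (Regulation, Positive_regulation, Negative_regulation) takes a
  Theme and optionally a Cause, either of which may be a protein or another
  event — making event structure recursive. Secondary roles (Site, CSite,
  AtLoc, ToLoc) further specify an event with an `Entity` text-bound;
* `M` — Negation/Speculation markers on events;
* `R` — coreference relations `anaphora → antecedent`, optionally listing
  the protein mentions embedded in the antecedent.

Validation enforces referential integrity, unique identifiers, span/text
agreement (when the document text is available), containment of minimal
spans, and acyclicity of event-to-event references. Duplicate identifiers
are a hard error rather than last-wins. Event *schema* constraints (e.g.
"simple events take exactly one Theme") are guaranteed by the fixture
generator but deliberately not enforced by the parser: real system output is
often schema-sloppy and the scorers must still be able to count it.

### Dialect decisions

* Offsets are 0-based with exclusive ends ("begins at the 275th character
  and ends before the 278th").
* Markable lines are accepted in both a tab-delimited form and a
  space-delimited form whose trailing `beg end [head]` group inside the full
  span marks the minimal boundary. The minimal span defaults to the full
  span when absent; a stated minimal span equal to the full span is
  canonicalized to "absent" so serialization round-trips structurally. The
  permissive space-delimited dialect can in principle misread a surface
  string that itself ends in two integers inside the span; the tab form is
  unambiguous and is what the writer emits.
* The text field of `T` lines is optional and is filled from the document
  text when available.
* Numbered roles (`Theme2`, `Site2`, …) are normalized to their base role;
  argument collections are multisets with no order semantics.
* Unknown line kinds are retained on the document and re-emitted on
  serialization, never silently dropped.
* Section labels (TIAB, Intro, R/D/C, Methods, Caption) attach to whole
  documents: a corpus is profiled or scored per section by treating each
  section as its own sub-corpus, which is how section-wise result rows are
  produced. No section inference from raw text is attempted.

## Matching calculus

Exact event equality: same type, triggers equal as text entities (same type,
same span), and a perfect one-to-one mapping between argument multisets with
equal roles and equal targets, recursively for event-valued targets.

* **Approximate span matching** relaxes text-entity span equality: a
  predicted span is accepted when entirely contained in the gold span
  extended by one word to the left and right. A *word* is a maximal run of
  non-whitespace, non-punctuation characters; at document edges the
  extension clamps to the gold boundary. Whether the original evaluation
  extended by one linguistic token or one whitespace word is not
  recoverable; the whitespace/punctuation rule is this package's documented
  choice. The relaxation applies to all text entities — triggers,
  argument proteins and secondary-argument entities alike.
* **Approximate recursive matching** relaxes equality for events *in
  argument position* only: a referred event matches when its type, trigger
  and Theme arguments match (applied recursively to Theme targets that are
  themselves events); its non-Theme arguments are ignored. The top-level
  argument sets must still fully match. A referred event's trigger follows
  the configured span mode.
* **Task levels**: Task 1 strips secondary roles from both gold and
  predicted events (at every nesting depth) before matching; Task 2 retains
  them.
* **Event decomposition** splits each event with k ≥ 1 arguments into k
  single-argument units sharing trigger and type; zero-argument events pass
  through, nested targets stay intact (they reference the original,
  undecomposed events), and the operation is idempotent. Under Task 1,
  secondary roles are stripped *before* decomposition so they never form
  units. Decomposition composes with the span/recursive switches.

Argument matching is a maximum bipartite matching (Hopcroft–Karp, via
networkx) over the precomputed role/target compatibility graph; an
exhaustive permutation search is kept in the test suite as an independent
oracle for multisets of size ≤ 6.

## Scoring conventions

Matched counting is existence-based and computed independently for recall
(over gold units) and precision (over answer units), rather than via a
global one-to-one alignment; duplicate identical predictions therefore
inflate the answer count without inflating recall. A category with zero
answers reports precision 0 (display convention), F is 0 when R + P = 0,
and group rows (Simple Event / Binding / Regulation / All — keyed in
brackets to stay distinct from the per-type "Regulation" row) micro-average
the member-type counts. Empty categories are zero-filled rather than
omitted. Printed triples are rounded half-away-from-zero, two decimals for
event tables and one for coreference tables.

Task 2 scores one unit per gold secondary argument: it is recovered when a
predicted event matching the host under Task-1 criteria carries a secondary
argument with the same role and an entity equal under the configured span
mode. Sites (Site/CSite) are additionally broken down by host event type
(Phosphorylation / Binding / Regulation family). Task 3 scores
modifications: a gold modification is recovered by a predicted modification
of the same type attached to an event matching the gold one under Task-1
criteria at the configured span/recursive modes (the original mode for
Task-3 host matching is unstated; tying it to the configuration mirrors
Task 2).

## Coreference evaluation

A response markable matches a gold markable when it covers the gold minimal
boundary and is included in the gold maximal boundary. Surface mode scores
the annotated links directly (both endpoints must match). Protein mode —
the primary mode — first generates (anaphor, protein) links by tracing each
chain of surface links depth-first with a visited set until an antecedent
embedding a protein is found, then stops (proteins beyond the first
protein-embedding antecedent are not accumulated); intermediate antecedents
and protein-free chains contribute nothing, and cycles terminate the trace
with a warning. An antecedent "embeds" a protein per the relation's
bracketed list when stated, otherwise by span containment against the
protein set. A response protein link is correct when the anaphors match as
markables and the protein identifiers are identical (proteins are the given
gold set on both sides).

For the per-anaphora-type breakdown, labels (relative pronoun / pronoun /
definite NP / …) are consumed from an external sidecar table and never
inferred from the text. When several gold anaphors match one response
anaphor, the response is attributed to the gold anaphor with the largest
span overlap (tie: earliest offset) — a documented choice, as the original
disambiguation is unspecified; response links matching no gold anaphor
count only toward All-precision. Cluster-based metrics (MUC, B³, CEAF) are
out of scope.

## Corpus statistics

Words are whitespace-delimited tokens of the raw text; published reference
densities are reproduced from their stated counts via `ratio_percent` (the
original tokenizer being unknown, the ratio operations accept externally
supplied counts). Densities P/W, E/W, E/P are percentages rounded
half-away-from-zero to two decimals; the coordination ratio E/T divides
events by distinct triggers referenced by at least one event, and events
with no triggers at all is an integrity error.

## Synthetic fixtures

The generator emulates the *structure* of an event-annotated corpus — the
event typology with its argument schemas, nesting of regulations, secondary
arguments, negation/speculation rates, and coreference chains with protein
or protein-free antecedents — using one construct per sentence over a small
vocabulary of gene-symbol-like tokens and trigger nominalizations. Default
proportions follow the make-up of an abstract-collection training corpus
(regulations ≈ 56 % of events, expression ≈ 20 %, binding ≈ 10 %,
catabolism rare); defaults for what such corpora do not pin down (6
documents, 4–8 events and 1–3 coreference chains per document, nesting
probability 0.4, secondary-argument rate 0.15, negation 0.06 / speculation
0.05, protein-antecedent rate 0.6, chain length 1–2) were chosen once as
plausible magnitudes and are documented here rather than tuned. Construct
locality is engineered so expected scores are exact: every event has its own
trigger span, constructs sit in separate sentences, and perturbation sites
keep at least one word of clearance so the one-word span extension never
bridges two constructs.

`perturb` applies an error budget — dropped/spurious events, trigger-span
shifts within/beyond one word, type swaps, Binding-Theme drops, nested-Cause
retargeting, modification drops, secondary-entity swaps, rewired or dropped
coreference links — and records each operation's effect on the per-mode
count tables by bookkeeping, not re-derivation. The shift-within-one-word
operation hurts only strict span modes; nested-Cause retargeting hurts the
nesting event only under strict recursive matching (the nested event itself
fails everywhere, since top-level argument sets are never relaxed); a
Binding-Theme drop fails the whole event but keeps partial credit under
decomposition. The nested perturbation targets a *Cause* rather than a
secondary Site because Task-1 stripping would make a nested-Site change
invisible in every Task-1 mode; Cause is the non-Theme primary argument
that survives stripping and exercises the same strict-vs-approximate
recursive contrast.

What passing these tests shows: the scorers implement the declared equality
calculus exactly, at every mode combination, on schema-valid inputs. What
they do not show: behaviour on real corpus phenomena absent from the
generator — coordinated events sharing one trigger in scoring (shared
triggers appear only in statistics tests), discontinuous spans, markable
dialect quirks beyond those described, or schema-violating system output
beyond what the parser tolerates.

## Problem sizes and determinism

The test suite and the acceptance script run on corpora of 2–10 documents
with 5–8 events per document (roughly 40–100 events and 30–60 protein links
per run), which exercises every code path while keeping the full suite in
the low seconds. All randomness flows through explicit integer seeds
(`random.Random`); identical parameters and seed reproduce byte-identical
corpora, predictions and reports.

## Known limitations

* No cluster-based coreference metrics and no coreference *resolution* —
  evaluation only.
* No conversion to other annotation schemes, no sentence splitting, POS
  tagging or section segmentation of raw full text.
* Existence-based counting is a convention choice; a global one-to-one
  alignment could give different precision in the presence of duplicate
  predictions.
* The space-delimited markable dialect is permissive by design and cannot
  be fully confirmed against the original file layout.
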