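# bionlpeval

Evaluation toolkit for standoff-annotated **biomolecular event extraction**
and **protein coreference resolution**.

Community shared tasks on fine-grained biomedical information extraction ask
systems to read literature text and produce *events* — typed relations such
as `Phosphorylation(Theme: p65, Site: Ser32)` or a `Regulation` whose Theme
is itself another event — together with negation/speculation markers and
coreference links from anaphoric expressions ("this transcription factor")
back to protein mentions. Comparing such structured predictions against gold
annotation fairly is its own problem: exact span equality is unnecessarily
harsh, and nested events propagate errors upward. This package implements
the evaluation side of that problem for tool builders and task organizers:

* **standoff I/O** — parser/writer for the `.txt` / `.a1` / `.a2` standoff
  dialect (`T` text-bounds with optional minimal spans, `E` events, `M`
  modifications, `R` coreference relations), with referential-integrity,
  span/text and acyclicity validation;
* **matching calculus** — strict matching, *approximate span matching*
  (a predicted span counts as equal when contained in the gold span extended
  by one word each side), *approximate recursive matching* (events in
  argument position compared on type, trigger and Theme arguments only), and
  *event decomposition* (multi-argument events split into single-argument
  units for partial credit);
* **event scorers** — Task 1 (core events + primary arguments), Task 2
  (secondary Site/Location arguments), Task 3 (negation/speculation), with
  per-type rows, Simple/Binding/Regulation/All group rows and optional
  per-section reporting;
* **coreference scorers** — surface-link mode with min/max-boundary markable
  matching, and the primary protein-link mode that traces chains of surface
  links to direct or indirect protein-embedding antecedents;
* **corpus statistics** — annotation counts, densities (P/W, E/W, E/P) and
  the event-coordination ratio E/T;
* **fixture generator** — seeded synthetic corpora plus error-injected
  predictions whose expected scores are known in closed form, used as the
  oracle for the whole scorer stack.

## Scores

Every scorer reports, per category,

```
recall    R = 100 · |gold matched|   / |gold|
precision P = 100 · |answer matched| / |answer|
F-score   F = 2RP / (R + P)
```

where "matched" is existence-based under the selected equality mode: event
equality requires equal types, triggers equal as text entities, and a
perfect one-to-one mapping between argument multisets (recursively for
event-valued arguments), relaxed per the mode switches above.

## Worked example

Generate a six-document synthetic corpus with a small error budget (one
dropped event, one spurious event) and score the predictions in the default
mode (approximate span + approximate recursive matching):

```
$ bionlpeval gen-fixtures --out-dir demo --seed 1
6 documents written to demo
$ bionlpeval evaluate-events --gold-dir demo/gold --pred-dir demo/pred
# mode: task1[span=approximate,recursive=approximate,decomposition=off,task1]
category	gold	answer	recall_matched	precision_matched	R/P/F
Gene_expression	5	6	5	5	100.00/83.33/90.91
...
[Simple Event]	7	7	6	6	85.71/85.71/85.71
[Binding]	4	4	4	4	100.00/100.00/100.00
[Regulation]	28	28	28	28	100.00/100.00/100.00
[All]	39	39	38	38	97.44/97.44/97.44
```

Of 39 gold events, the dropped one is the missing recall match
(38/39 = 97.44 % recall) and the spurious `Gene_expression` is the
unmatched answer (5/6 = 83.33 % precision for that type). The same
directories feed `evaluate-coref` (surface or protein mode, optionally with
an anaphora-type label sidecar) and `stats`.

As a library:

```python
from bionlpeval import parse_document, build_protein_links

doc = parse_document(None, [
    "T4 Protein 275 278 p65",
    "T5 Protein 294 297 p50",
    "T28 Exp 264 297 NF-kappa B p65 and p50",
    "T29 Exp 307 312 which",
    "R1 Coref Ana:T29 Ant:T28 [T5, T4]",
])
print(sorted((l.anaphora.id, l.protein) for l in build_protein_links(doc)))
# [('T29', 'T4'), ('T29', 'T5')]
```

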