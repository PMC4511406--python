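# grnpipe

Semi-supervised relation extraction for building gene-regulation networks
from biomedical text, with a full Slot Error Rate evaluation suite.

The package is aimed at text-mining practitioners working on shared-task
style relation extraction: sentences with gold entity annotations (BioNLP
standoff format, `.txt`/`.a1`/`.a2`), six directed relation types
(`Inhibition`, `Activation`, `Requirement`, `Binding`, `Transcription`,
`Regulation`) arranged in a small hierarchy, and a large unannotated corpus
that can be exploited to gain recall.

## What it does

1. **Candidate generation** — every ordered pair of distinct entities in a
   sentence is a classification data point (n·(n−1) pairs per sentence),
   with per-type one-vs-rest labels.
2. **Featurization** — each pair is encoded as
   `f = f_base ⊙ f_context`: one-hot local blocks (stem, part-of-speech,
   biomolecule category) for the agent and target entities, concatenated
   with distance-decayed context blocks

   `f_context = (1/Z) Σᵢ α^d(w,wᵢ) f_base(wᵢ)`,  `Z = Σᵢ α^d(w,wᵢ)`,

   a convex combination over the sentence's non-entity words with flat
   token distance `d` and decay `α = 0.9`.
3. **Distant supervision** — unlabelled sentences containing an entity pair
   that is related in the labelled data are selected and their matching
   ordered pairs labelled positive; this introduces new lexical patterns
   (and label noise).
4. **Rule mining** — zero-co-occurrence rules (`P(fᵢ ∈ Vᵢ | positive) = 0`
   with negative support above a threshold, arity ≤ 2) are extracted
   automatically from the labelled data and used to (a) filter noisy
   distant positives and (b) harvest likely distant negatives.
5. **Classification** — one soft-margin RBF SVM per relation type with
   class-asymmetric penalties C⁺/C⁻
   (`min ½‖w‖² + C⁺Σ_{x∈χ⁺}ξ_x + C⁻Σ_{x∈χ⁻}ξ_x`).
6. **Network scoring** — predictions are aggregated into a typed, directed
   arc set, duplicates collapsed, redundant (less specific) arcs removed,
   and scored with S/I/D/C/N/M counts, precision, recall, F1, Fβ and

   `SER = (S + I + D)/N = 1 − recall + I/N`.

   The gradient fields of SER and Fβ over recall–precision space are
   available (`ser_gradient`, `f_beta_gradient`); the SER recall-gradient
   `1/P − 2` changes sign at 50 % precision, which is why optimising SER
   below that line actively sacrifices recall.

A deterministic synthetic-corpus generator (`grnpipe.synthetic`) emulates
the statistical structure the pipeline assumes — trigger-word patterns
correlated with relation types, entity pairs shared between the labelled
and unlabelled portions, a configurable noise rate — so every stage is
testable without any download.

## Worked example

```bash
$ grnpipe run-all --seed 1 --regime preselect --negatives-mode rules
S=1 D=46 I=3 C=2 M=6 N=49  Recall=  4.1  Prec.= 33.3  F1=  7.3  SER=1.020
```

This simulates a small corpus (134 labelled + 400 unlabelled sentences),
mines negativity rules per relation type, filters the distant positives,
harvests rule-selected negatives, trains the six per-type SVMs and scores
the aggregated network against the held-out reference: of N=49 reference
arcs, 2 were predicted correctly (C), 1 with the wrong type (S), 46 were
missed (D), and 3 predicted arcs had no reference counterpart (I), giving
recall C/N = 4.1 %, precision C/M = 33.3 % and SER = (1+3+46)/49 = 1.020.
A single run at this desk scale is deliberately small; the regime
*comparisons* are averaged over 20 seeds (see below).

Library use mirrors the CLI:

```python
from grnpipe import GenConfig, PipelineConfig, generate, run_pipeline

labelled, unlabelled, truth = generate(GenConfig(seed=1))
test, _, _ = generate(GenConfig(seed=10_001, n_labelled=60, n_unlabelled=0,
                                core_triggers_only=False))
result = run_pipeline(labelled, unlabelled, test,
                      config=PipelineConfig(regime="preselect",
                                            negatives_mode="rules"))
print(result.scores.summary())
print(result.report.to_tsv())
```

## Layout

| Module | Role |
| --- | --- |
| `grnpipe.corpus_io` | standoff `.txt`/`.a1`/`.a2` reader/writer, relation-type hierarchy |
| `grnpipe.candidates` | ordered entity-pair enumeration and labelling |
| `grnpipe.featurization` | vocabulary, local + decayed-context feature blocks |
| `grnpipe.rule_mining` | zero-co-occurrence negativity rules (arity ≤ 2) |
| `grnpipe.distant` | sentence retention, distant positives/negatives, filtering |
| `grnpipe.classifier` | asymmetric-C RBF SVM, cross-validated grid search |
| `grnpipe.network_eval` | network aggregation, SER/Fβ suite, gradient fields |
| `grnpipe.synthetic` | deterministic corpus generator with planted structure |
| `grnpipe.pipeline` / `grnpipe.cli` | regime orchestration, `grnpipe` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
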