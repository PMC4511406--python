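# Methods

## Problem setting

The pipeline extracts a typed, directed gene-regulation network from
sentence-segmented text in which entity mentions are given (gold
annotations in BioNLP standoff format).  Six relation types are arranged in
a small hierarchy; by default `Regulation` is the generic root with the
other five types as its children.  The hierarchy is data, not code: any
forest can be supplied as a YAML/JSON config (`types:` + `parents:`), and
the default is used only when no config is given, because the concrete
published topology is not recoverable from text alone.  Scoring is
*global*: the de-duplicated, hierarchy-resolved network is compared to the
reference, not the individual predictions.

## Feature model

A data point is one ordered (agent, target) entity pair in one sentence.
Its vector concatenates four blocks:

* `agent_local`, `target_local` — binary indicators for the stem and
  part-of-speech of every entity word plus the entity's biomolecule
  category.  Indicators are set once (binary, not counted).
* `agent_context`, `target_context` — the decayed average
  `(1/Z) Σᵢ α^d(w,wᵢ) f_base(wᵢ)` over all sentence tokens outside the
  entity span.  `d` is the flat token distance to the nearest entity token
  (multi-word spans take the minimum over their tokens); parse-tree
  distance is deliberately not implemented, flat distance having proved the
  better variant.  `Z` normalises the weights to sum to one, so each
  context block is a convex combination of one-hot word blocks: every entry
  lies in [0, 1] and the entries of each feature family (stems; POS tags)
  sum to exactly 1 whenever at least one non-entity token exists.  As
  α → 1 the average becomes uniform.  Default α = 0.9.

Design choices worth noting:

* The *other* entity of the pair counts as context for this one — the sum
  runs over all tokens outside the focal entity's own span.  In the
  degenerate two-token sentence consisting only of the two entities, each
  context block therefore equals the other entity's word block, not zero.
* Context words carry stem + POS only; non-entity words have no
  biomolecule category.
* Every block reserves one out-of-vocabulary sentinel dimension.  The
  vocabulary is built over the labelled *and* the retained unlabelled
  sentences (an unbiased representation of the distant data), but
  prediction-time words can still be unseen.
* Tokenization, stemming and POS tagging are injected contracts with
  deterministic defaults (regex word/punctuation tokenizer, suffix-stripping
  stemmer, lexicon lookup with an `UNK` fallback), so no statistical model
  or download is involved and results are bit-reproducible.

## Distant supervision

If two entities are related in the labelled data, an unlabelled sentence
containing both has substantial probability of encoding that relation.
Unlabelled sentences are retained when they contain at least two mentions
of labelled-corpus entities (dictionary longest-match, case-insensitive
exact surface comparison) and are not textually identical to a training
sentence.  Retained pairs matching a known (agent, target, type) key — in
that direction — become distant positives for that type's classifier.  The
converse inference is invalid for negatives: absence from a sparse relation
set is weak evidence, so the basic regime adds no negatives at all.

## Rule-based pre-selection

From the labelled matrix of a relation type, the miner extracts sufficient
conditions for negativity: bin sides (`value ≤ ε` vs `> ε`, ε = 0) that no
positive point occupies but strictly more than `threshold` negative points
do, plus all such conjunctions of two dimensions.  The pairwise search is
restricted to the candidate set of sides whose marginal negative support
already exceeds the threshold (joint support cannot exceed a marginal), and
arity is capped at two for tractability.  Probabilistic relevance scores
(mutual information, Bayes factors, KL) are not used — they are undefined
on the zero probabilities these rules are built from.

The threshold defaults to 25 % of the labelled data-point count, the
midpoint of the 20–30 % band that balances precision against recall; it is
the main dial of the pre-selection regime.  Rules are applied two ways:
distant positives matched by any rule are discarded, and remaining
unlabelled pairs matched by a rule can be harvested as distant negatives
(`negatives_mode="rules"`), with `"all"` (every remaining pair) kept as the
unfiltered comparison arm and `"none"` as the recall-maximal arm.

## Classifier

One soft-margin RBF SVM per relation type (one-vs-rest):

    min ½‖w‖² + C⁺ Σ_{x∈χ⁺} ξ_x + C⁻ Σ_{x∈χ⁻} ξ_x

subject to the usual margin constraints.  The quadratic program is solved
by libsvm (via scikit-learn) with per-class weights on a base C of 1, so
the effective class penalties are exactly C⁺ and C⁻; with C⁺ = C⁻ the
solution coincides with the standard single-C machine (checked against the
plain formulation to 1e-6 in the tests).  Defaults: C⁺ = C⁻ = 10,
γ = 0.1; a cross-validated grid search over
C ∈ {0.1, 1, 10, 100}² × γ ∈ {0.01, 0.1, 1} with deterministic fold
assignment and lexicographic tie-breaking is provided, with F1 as the
default selection criterion (Fβ and a local slot-error criterion are
selectable — the choice of criterion matters precisely because of the SER
precision bias discussed below).

**Direction of the asymmetry.**  The textbook motivation for two penalty
constants is to soften the margin of the noisy (positive) class, i.e.
C⁺ < C⁻.  In a heavily imbalanced one-vs-rest problem, however, shrinking
the positive penalty simply starves the positive class: measured on the
synthetic corpora, C⁺ < C⁻ collapses the prediction set (M → 0, recall → 0).
The weighted-regularisation *outcome* this package reproduces — a further
recall gain over the basic distant regime at a severe precision cost — is
obtained with the opposite ratio, and the pipeline's `weighted` regime
therefore multiplies C⁻ by `weighted_neg_factor = 0.1` (penalty ratio
C⁺/C⁻ = 10, a softer negative margin).  The classifier itself stays fully
general in (C⁺, C⁻).

## Evaluation

Counting against a reference network (both sides post-resolution):
C = matching (agent, target, type) triples; S = entity pairs present in
both networks with no type agreement (one substitution per matched
pred/ref arc couple); I = predicted arcs left over; D = reference arcs
left over.  By construction N = C+S+D = |reference| and M = C+S+I =
|predicted|.  When a shared pair has at least one correct type, extra
wrong-type predicted arcs count as insertions, not substitutions — a
dialect decision isolated in `count_errors` (post-resolution networks
rarely hold several types per pair).  Direction is part of the slot: a
reversed prediction scores I + D, never S.  Node identity is the
normalised entity surface form.

Derived metrics satisfy, and the tests verify simultaneously:

* `SER = (S+I+D)/N = 1 − recall + I/N` — SER does not depend on S given N
  and I, and every SER above 1 is attributable to insertions (the empty
  prediction sits exactly at SER = 1);
* `F1 = 2PR/(P+R) = 1 − (2S+I+D)/(N+M)` with `N+M = 2(C+S)+D+I`;
* with M = N and S = D, `SER = 1.5(1 − F1)` exactly; with M = N alone,
  `SER/(1−F1) ∈ [1, 2]`;
* `∂SER/∂R = 1/P − 2` (at fixed S, N) vanishes at P = 0.5 and is positive
  below it — under 50 % precision, optimising SER pushes recall *down* —
  while both Fβ partials are non-negative everywhere.
* An empty prediction has undefined precision; it is reported as a flagged
  missing value (`None`), never as 0.

Global aggregation makes the precision–recall trade-off non-monotone:
adding a more specific correct arc deletes an already-correct generic arc
on the same pair during redundant-arc resolution, so C can decrease when a
prediction is *added* (a constructed fixture in the tests demonstrates
this).  Local, unresolved scoring is available alongside
(`score_networks(..., resolve=False)`).

## Synthetic corpus

The generator emulates what the pipeline needs from a GRN-style corpus and
nothing more.  Sentences are template-generated
(`AGENT trigger filler* TARGET filler*`), with type-specific trigger verbs
for relational sentences and neutral connectives for non-relational
co-mentions; connectives never co-occur with a relation, so they are
minable as negativity rules.  Labelled sentences draw triggers only from a
core synonym per type while unlabelled and evaluation text uses the full
synonym set — this plants exactly the unseen-pattern structure distant
supervision is meant to capture.  Unlabelled sentences reuse labelled
entity pairs with probability `pair_overlap` (default 0.7) and truly encode
the known relation with probability `1 − noise_rate` (default 0.7),
otherwise forming a noisy co-mention.

Default scale mirrors a small shared-task training set: 134 labelled
sentences, per-type relation probability 0.13 (≈ 38 positives per type
including second-relation draws), a 30-name entity lexicon, 50 filler
words, and 400 unlabelled sentences — large enough for distant selection to
matter, small enough that a full multi-regime comparison over 20 seeds runs
on one CPU in a few minutes.  Evaluation corpora are generated with a
disjoint seed offset.  All randomness flows from one seeded generator;
fixed seed means byte-identical corpora and scores.

What the generator does *not* model — real biomedical syntax, nested or
multi-word entity mentions dominating the text, entity-name ambiguity,
cross-sentence discourse — bounds what passing tests show: they demonstrate
the pipeline's mechanics and the *direction* of the regime effects
(distant positives raise recall; rule filtering and harvested negatives
restore precision; the weighted asymmetry trades precision for recall), not
absolute performance on real corpora, which depends on corpus-specific
feature statistics.

## Numerical choices and degenerate inputs

* Context weights are renormalised floats; accumulated entries are clamped
  at 1.0 against float epsilon overshoot; the convex-combination property
  is asserted to 1e-9.
* Rule binning uses exact zero (ε = 0) by default, reproducing the
  `fᵢ = 0` convention for binary features; ε is configurable.
* A mining threshold at or above the negative count yields an empty rule
  set with a warning (no rule can reach support); the threshold floor is 1.
* Single-class training sets raise a degenerate-training error; folds
  without both classes are skipped with a warning during grid search.
* Grid-search ties break on the lexicographically smallest (C⁺, C⁻, γ).
* A sentence with 0 or 1 entities yields no candidate pairs; a sentence
  whose tokens are all entity tokens yields a zero context block only for
  single-entity queries (see the feature-model note above).

## Known limitations

* Entity matching across corpora is case-insensitive exact surface match;
  no gene-name normalisation or aliasing.
* Event/trigger annotations, coreference and discontinuous spans are out of
  scope; only binary agent→target relations are handled.
* The substitution-matching dialect for multi-type pairs (above) is one of
  several defensible readings of the official scorer's behaviour.
* Rule support is counted over data points, not unique feature patterns;
  duplicated sentences therefore inflate support.
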