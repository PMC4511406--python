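"""End-to-end orchestration of the semi-supervised extraction regimes.

Regimes (mirroring the comparison systems of the study design):

* ``supervised``  — labelled data only;
* ``basic``       — + distant positives by shared entity pairs, no negatives;
* ``weighted``    — basic, trained with a softer positive margin (C+ < C-);
* ``preselect``   — distant positives filtered by mined negativity rules,
                    optionally with distant negatives (``negatives_mode`` in
                    {"none", "rules", "all"}).

Stage order is fixed: read -> candidates -> vocabulary (labelled plus
retained unlabelled) -> features -> [mine rules] -> distant selection ->
per-type training -> prediction -> network aggregation -> redundant-arc
resolution -> scoring.  Every stage logs its input/output counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from . import distant
from .candidates import CandidatePair, Label, generate_candidates
from .classifier import DegenerateTrainingError, TrainConfig, train
from .corpus_io import RelationHierarchy, Sentence, default_hierarchy
from .distant import SelectionReport, normalize_surface
from .featurization import ContextConfig, Vocabulary, build_vocabulary, features_matrix
from .network_eval import Arc, ScoreBreakdown, build_network, resolve_redundant, score_networks
from .rule_mining import RuleSet, default_threshold, mine_rules
from .synthetic import GenConfig, generate

logger = logging.getLogger("grnpipe")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "reference_network", "compare_regimes", "REGIMES"]

REGIMES = ("supervised", "basic", "weighted", "preselect")


@dataclass(frozen=True)
class PipelineConfig:
    regime: str = "basic"
    negatives_mode: str = "none"  # only meaningful for regime "preselect"
    context: ContextConfig = field(default_factory=ContextConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    #: C- multiplier (< 1) applied in the "weighted" regime: the asymmetry
    #: that reproduces the recall-up / precision-down behaviour of weighted
    #: regularisation under distant-supervision noise softens the negative
    #: margin relative to the positive one
    weighted_neg_factor: float = 0.1
    threshold_fraction: float = 0.25
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.negatives_mode not in ("none", "rules", "all"):
            raise ValueError(f"unknown negatives mode {self.negatives_mode!r}")
        if self.regime != "preselect" and self.negatives_mode != "none":
            raise ValueError("negatives require the preselect regime (rules must be mined)")


@dataclass
class PipelineResult:
    network: set[Arc]
    scores: ScoreBreakdown | None
    local_scores: ScoreBreakdown | None
    report: SelectionReport
    rules: dict[str, RuleSet] = field(default_factory=dict)
    vocabulary: Vocabulary | None = None


def reference_network(sentences: Iterable[Sentence]) -> set[Arc]:
    """Gold network over normalised entity surfaces."""
    arcs = set()
    for s in sentences:
        for r in s.relations:
            arcs.add(
                Arc(
                    normalize_surface(s.entity(r.agent).text),
                    normalize_surface(s.entity(r.target).text),
                    r.rtype,
                )
            )
    return arcs


def _train_config_for(config: PipelineConfig) -> TrainConfig:
    if config.regime == "weighted":
        tc = config.train
        return replace(tc, c_neg=tc.c_neg * config.weighted_neg_factor, seed=config.seed)
    return replace(config.train, seed=config.seed)


def run_pipeline(
    labelled: Sequence[Sentence],
    unlabelled: Sequence[Sentence],
    test: Sequence[Sentence],
    hierarchy: RelationHierarchy | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run one regime end to end and score against the test corpus gold.

    ``test`` sentences must carry gold entities (their relations are the
    reference); predictions are made on all ordered candidate pairs of the
    test sentences.
    """
    hierarchy = hierarchy or default_hierarchy()
    config = config or PipelineConfig()
    types = sorted(hierarchy.types)
    report = SelectionReport()

    lab_pairs: list[CandidatePair] = []
    for s in labelled:
        lab_pairs.extend(generate_candidates(s, types))
    logger.info("stage candidates: %d labelled pairs from %d sentences", len(lab_pairs), len(labelled))

    use_distant = config.regime != "supervised"
    retained: list[Sentence] = []
    unl_pairs: list[CandidatePair] = []
    if use_distant:
        lexicon = distant.entity_lexicon(labelled)
        lab_texts = [" ".join(s.surfaces) for s in labelled]
        retained = distant.retain_sentences(unlabelled, lexicon, lab_texts)
        for s in retained:
            unl_pairs.extend(generate_candidates(s, types))
        logger.info(
            "stage retain: %d/%d unlabelled sentences kept, %d candidate pairs",
            len(retained), len(unlabelled), len(unl_pairs),
        )

    vocab = build_vocabulary(list(labelled) + retained)
    logger.info("stage vocabulary: %d dimensions", vocab.size)

    X_lab = features_matrix(lab_pairs, vocab, config.context)
    X_unl = features_matrix(unl_pairs, vocab, config.context) if unl_pairs else None

    test_pairs: list[CandidatePair] = []
    for s in test:
        test_pairs.extend(generate_candidates(s, types))
    X_test = features_matrix(test_pairs, vocab, config.context)
    logger.info("stage features: %d test pairs", len(test_pairs))

    known = distant.known_pair_keys(labelled) if use_distant else set()
    # distant positives are selected per relation type on the shared pairs
    predictions: list[tuple[str, str, str]] = []
    rules_by_type: dict[str, RuleSet] = {}
    train_cfg = _train_config_for(config)

    for rtype in types:
        y_lab = np.array(
            [1 if p.label_for(rtype) is Label.POSITIVE else 0 for p in lab_pairs]
        )
        report.candidates[rtype] = len(unl_pairs)
        pos_rows: list[int] = []
        neg_rows: list[int] = []
        if use_distant:
            keys_r = {k for k in known if k.rtype == rtype}
            by_pair = {(k.agent, k.target) for k in keys_r}
            matched = [
                i
                for i, p in enumerate(unl_pairs)
                if (normalize_surface(p.agent.text), normalize_surface(p.target.text)) in by_pair
            ]
            if config.regime == "preselect":
                threshold = default_threshold(len(lab_pairs), config.threshold_fraction)
                ruleset = mine_rules(X_lab, y_lab, threshold)
                rules_by_type[rtype] = ruleset
                if matched:
                    from .rule_mining import apply_rules

                    hit = apply_rules(ruleset, X_unl[matched])
                    pos_rows = [i for i, h in zip(matched, hit) if not h]
                    report.filtered_out_positive[rtype] = int(hit.sum())
                else:
                    report.filtered_out_positive[rtype] = 0
                rest = sorted(set(range(len(unl_pairs))) - set(matched))
                if config.negatives_mode == "all":
                    neg_rows = rest
                elif config.negatives_mode == "rules" and rest:
                    from .rule_mining import apply_rules

                    hit = apply_rules(ruleset, X_unl[rest])
                    neg_rows = [i for i, h in zip(rest, hit) if h]
            else:
                pos_rows = matched
                report.filtered_out_positive[rtype] = 0
        report.selected_positive[rtype] = len(pos_rows)
        report.selected_negative[rtype] = len(neg_rows)
        logger.info(
            "stage select[%s]: +%d distant positives, +%d distant negatives",
            rtype, len(pos_rows), len(neg_rows),
        )

        parts = [X_lab]
        ys = [y_lab]
        if pos_rows:
            parts.append(X_unl[pos_rows])
            ys.append(np.ones(len(pos_rows), dtype=int))
        if neg_rows:
            parts.append(X_unl[neg_rows])
            ys.append(np.zeros(len(neg_rows), dtype=int))
        X = sparse.vstack(parts).tocsr() if len(parts) > 1 else X_lab
        y = np.concatenate(ys)
        try:
            model = train(X, y, train_cfg)
        except DegenerateTrainingError:
            logger.warning("stage train[%s]: single-class training set, skipping type", rtype)
            continue
        y_hat = model.predict(X_test)
        for p, lab in zip(test_pairs, y_hat):
            if lab == 1:
                predictions.append(
                    (normalize_surface(p.agent.text), normalize_surface(p.target.text), rtype)
                )
        logger.info("stage predict[%s]: %d positive pairs", rtype, int(y_hat.sum()))

    network = resolve_redundant(build_network(predictions), hierarchy)
    reference = reference_network(test)
    scores = local = None
    if reference:
        scores = score_networks(network, reference, hierarchy, beta=config.beta)
        local = score_networks(predictions, reference, beta=config.beta, resolve=False)
        logger.info("stage score: %s", scores.summary())
    return PipelineResult(
        network=network,
        scores=scores,
        local_scores=local,
        report=report,
        rules=rules_by_type,
        vocabulary=vocab,
    )


# ---------------------------------------------------------------------------
# Regime comparison experiments on synthetic corpora
# ---------------------------------------------------------------------------

def compare_regimes(
    seeds: Iterable[int],
    gen_cfg: GenConfig | None = None,
    configs: Mapping[str, PipelineConfig] | None = None,
    n_test: int = 60,
) -> dict[str, list[ScoreBreakdown]]:
    """Run several regimes over per-seed synthetic corpora.

    For each seed a training corpus (labelled + unlabelled) and a disjoint
    test corpus are generated; every configured regime is trained on the
    same data and scored globally against the same reference network.
    """
    base = gen_cfg or GenConfig()
    if configs is None:
        configs = {
            "supervised": PipelineConfig(regime="supervised"),
            "basic": PipelineConfig(regime="basic"),
            "preselect_rules": PipelineConfig(regime="preselect", negatives_mode="rules"),
        }
    out: dict[str, list[ScoreBreakdown]] = {name: [] for name in configs}
    for seed in seeds:
        train_cfg = replace(base, seed=int(seed))
        labelled, unlabelled, _ = generate(train_cfg)
        test_gen = replace(
            base,
            seed=int(seed) + 10_000,
            n_labelled=n_test,
            n_unlabelled=0,
            core_triggers_only=False,
        )
        test, _, _ = generate(test_gen)
        for name, cfg in configs.items():
            res = run_pipeline(
                labelled, unlabelled, test, config=replace(cfg, seed=int(seed))
            )
            if res.scores is not None:
                out[name].append(res.scores)
    return out
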