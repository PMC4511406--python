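"""Distant-supervision selection of unlabelled data points.

Positives: any candidate pair from the unannotated corpus whose (agent,
target) surface forms and direction match an entity pair related in the
labelled data is taken as a positive for that relation type.  This projects
known relations onto new sentences and is inherently noisy — a sentence
mentioning both entities need not encode the relation.

Negatives: the converse inference is invalid (absence from a sparse set of
known relations says little), so no naive negatives are harvested.  Three
regimes are supported: ``none`` (no negatives), ``rules`` (only pairs
matched by a mined negativity rule), and ``all`` (every remaining pair, the
unfiltered comparison arm).

Entity matching across corpora is case-insensitive exact surface match;
unlabelled sentences are tagged by dictionary longest-match against the
labelled-corpus entity lexicon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .candidates import CandidatePair, Label, Provenance
from .corpus_io import Entity, Sentence
from .rule_mining import RuleSet, apply_rules

__all__ = [
    "normalize_surface",
    "EntityPairKey",
    "SelectionReport",
    "entity_lexicon",
    "tag_entities",
    "retain_sentences",
    "known_pair_keys",
    "select_positives",
    "filter_positives",
    "select_negatives",
]


def normalize_surface(s: str) -> str:
    """Deterministic surface normalisation: lowercase, collapse whitespace."""
    return " ".join(s.lower().split())


@dataclass(frozen=True)
class EntityPairKey:
    """Directed (agent, target, type) key over normalised surface forms."""

    agent: str
    target: str
    rtype: str

    @classmethod
    def of(cls, agent_text: str, target_text: str, rtype: str) -> "EntityPairKey":
        return cls(normalize_surface(agent_text), normalize_surface(target_text), rtype)


@dataclass
class SelectionReport:
    """Per-relation-type bookkeeping of the selection stage."""

    candidates: dict[str, int] = field(default_factory=dict)
    selected_positive: dict[str, int] = field(default_factory=dict)
    filtered_out_positive: dict[str, int] = field(default_factory=dict)
    selected_negative: dict[str, int] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["type\tcandidates\tpositives\tfiltered_out\tnegatives"]
        for t in sorted(self.candidates):
            lines.append(
                f"{t}\t{self.candidates.get(t, 0)}\t{self.selected_positive.get(t, 0)}"
                f"\t{self.filtered_out_positive.get(t, 0)}\t{self.selected_negative.get(t, 0)}"
            )
        return "\n".join(lines) + "\n"


def entity_lexicon(sentences: Iterable[Sentence]) -> dict[str, str]:
    """Map normalised entity surface form -> category, from gold entities."""
    lex: dict[str, str] = {}
    for s in sentences:
        for e in s.entities:
            lex.setdefault(normalize_surface(e.text), e.etype)
    return lex


def tag_entities(sentence: Sentence, lexicon: Mapping[str, str]) -> Sentence:
    """Dictionary-match lexicon entries against the token sequence.

    Greedy left-to-right, longest match wins; matched spans do not overlap.
    Adds Entity objects in place and returns the sentence.
    """
    if sentence.entities:
        return sentence
    max_len = max((len(k.split()) for k in lexicon), default=1)
    toks = sentence.tokens
    i = 0
    n_found = 0
    while i < len(toks):
        matched = False
        for span_len in range(min(max_len, len(toks) - i), 0, -1):
            surface = " ".join(t.surface for t in toks[i : i + span_len])
            key = normalize_surface(surface)
            if key in lexicon:
                n_found += 1
                sentence.entities.append(
                    Entity(
                        id=f"{sentence.id}.E{n_found}",
                        etype=lexicon[key],
                        span=(i, i + span_len),
                        text=surface,
                    )
                )
                i += span_len
                matched = True
                break
        if not matched:
            i += 1
    return sentence


def retain_sentences(
    unlabelled: Iterable[Sentence],
    lexicon: Mapping[str, str],
    labelled_texts: Iterable[str] = (),
) -> list[Sentence]:
    """Keep unlabelled sentences with >= 2 lexicon entity mentions, dropping
    any sentence textually identical to a labelled training sentence."""
    seen = {normalize_surface(t) for t in labelled_texts}
    kept: list[Sentence] = []
    for s in unlabelled:
        tag_entities(s, lexicon)
        if len(s.entities) < 2:
            continue
        if normalize_surface(" ".join(s.surfaces)) in seen:
            continue
        kept.append(s)
    return kept


def known_pair_keys(labelled: Iterable[Sentence]) -> set[EntityPairKey]:
    """All (agent surface, target surface, type) triples related in the
    labelled data."""
    keys: set[EntityPairKey] = set()
    for s in labelled:
        for r in s.relations:
            keys.add(
                EntityPairKey.of(s.entity(r.agent).text, s.entity(r.target).text, r.rtype)
            )
    return keys


def select_positives(
    pairs: Sequence[CandidatePair], known: Iterable[EntityPairKey]
) -> list[CandidatePair]:
    """Distant positives: unlabelled pairs matching a known key (direction
    respected).  A pair matching keys of several types becomes a positive
    for each such type independently."""
    by_pair: dict[tuple[str, str], set[str]] = {}
    for k in known:
        by_pair.setdefault((k.agent, k.target), set()).add(k.rtype)
    out: list[CandidatePair] = []
    for p in pairs:
        key = (normalize_surface(p.agent.text), normalize_surface(p.target.text))
        rtypes = by_pair.get(key)
        if not rtypes:
            continue
        p.provenance = Provenance.DISTANT_POSITIVE
        for r in rtypes:
            p.labels[r] = Label.POSITIVE
        out.append(p)
    return out


def filter_positives(
    selected: Sequence[CandidatePair],
    rules: RuleSet,
    features,
) -> tuple[list[CandidatePair], list[CandidatePair]]:
    """Drop selected positives matched by any negativity rule.

    ``features`` is the feature matrix whose rows align with ``selected``.
    Returns (kept, removed).
    """
    if not len(selected):
        return [], []
    mask = apply_rules(rules, features)
    kept = [p for p, hit in zip(selected, mask) if not hit]
    removed = [p for p, hit in zip(selected, mask) if hit]
    return kept, removed


def select_negatives(
    pairs: Sequence[CandidatePair],
    rules: RuleSet,
    features,
    mode: str = "none",
    rtype: str | None = None,
) -> list[CandidatePair]:
    """Harvest distant negatives among pairs not selected as positives.

    mode "none": no negatives (the basic distant regime); "rules": only
    pairs matched by a mined rule; "all": every remaining pair (unfiltered
    comparison arm).
    """
    if mode not in ("none", "rules", "all"):
        raise ValueError(f"unknown negatives mode {mode!r}")
    if mode == "none":
        return []
    if mode == "all":
        chosen = list(pairs)
    else:
        if not len(rules):
            warnings.warn("rule-selected negatives requested with an empty rule set", stacklevel=2)
            return []
        mask = apply_rules(rules, features)
        chosen = [p for p, hit in zip(pairs, mask) if hit]
    for p in chosen:
        p.provenance = Provenance.DISTANT_NEGATIVE
        if rtype is not None:
            p.labels[rtype] = Label.NEGATIVE
    return chosen
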