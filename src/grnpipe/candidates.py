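"""Enumerate ordered agent/target entity couples as classification points.

Every ordered pair of distinct entities in a sentence is one candidate data
point, so a sentence with ``n`` entities yields ``n*(n-1)`` candidates.
Labelling is per relation type (one-vs-rest): for a labelled sentence a pair
is positive for type ``r`` iff a relation of type ``r`` with exactly that
direction exists; pairs from unlabelled sentences carry ``UNKNOWN`` labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_io import Entity, RelationInstance, Sentence

__all__ = ["Label", "Provenance", "CandidatePair", "generate_candidates", "label_from_relations"]


class Label(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


class Provenance(enum.Enum):
    ANNOTATED = "annotated"
    DISTANT_POSITIVE = "distant_positive"
    DISTANT_NEGATIVE = "distant_negative"


@dataclass
class CandidatePair:
    sentence: Sentence
    agent: Entity
    target: Entity
    labels: dict[str, Label] = field(default_factory=dict)
    provenance: Provenance = Provenance.ANNOTATED

    @property
    def key(self) -> tuple[str, str, str]:
        """(agent text, target text, sentence id); direction-sensitive."""
        return (self.agent.text, self.target.text, self.sentence.id)

    def label_for(self, rtype: str) -> Label:
        return self.labels.get(rtype, Label.UNKNOWN)


def generate_candidates(
    sentence: Sentence, types: Iterable[str] | None = None
) -> list[CandidatePair]:
    """All ordered pairs of distinct entities in ``sentence``.

    ``types`` is the universe of relation types to label against; when None
    it defaults to the types occurring in the sentence's own relations.
    Unlabelled sentences yield pairs with all labels UNKNOWN.
    """
    if types is None:
        types = {r.rtype for r in sentence.relations}
    types = list(types)
    pairs: list[CandidatePair] = []
    for a in sentence.entities:
        for t in sentence.entities:
            if a.id == t.id:
                continue
            pairs.append(CandidatePair(sentence=sentence, agent=a, target=t))
    if sentence.origin == "labelled":
        label_from_relations(pairs, sentence.relations, types)
        for p in pairs:
            p.provenance = Provenance.ANNOTATED
    else:
        for p in pairs:
            p.labels = {r: Label.UNKNOWN for r in types}
    return pairs


def label_from_relations(
    pairs: Sequence[CandidatePair],
    relations: Sequence[RelationInstance],
    types: Iterable[str] | None = None,
) -> Sequence[CandidatePair]:
    """Assign per-type positive/negative labels from gold relations.

    Idempotent; a relation whose entities are absent from the pair list is a
    consistency error.
    """
    if types is None:
        types = {r.rtype for r in relations}
    types = set(types) | {r.rtype for r in relations}
    by_ids = {(p.agent.id, p.target.id): p for p in pairs}
    for p in pairs:
        p.labels = {r: Label.NEGATIVE for r in types}
    for rel in relations:
        pair = by_ids.get((rel.agent, rel.target))
        if pair is None:
            raise ValueError(
                f"relation {rel.rtype} ({rel.agent}->{rel.target}) has no "
                "matching candidate pair"
            )
        pair.labels[rel.rtype] = Label.POSITIVE
    return pairs
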