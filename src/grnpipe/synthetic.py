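"""Deterministic generator of labelled + unlabelled fixture corpora.

The generator emulates the statistical structure a gene-regulation-network
corpus presents to this pipeline, at desk scale and without any download:

* labelled sentences with >= 2 genic entities and gold directed relations of
  six types in a small hierarchy, realised through type-specific trigger
  verbs placed between agent and target;
* an unannotated corpus whose sentences reuse labelled entity pairs with
  probability ``pair_overlap``; such a sentence truly encodes the known
  relation with probability ``1 - noise_rate`` (using the *full* trigger
  synonym set, so it contains patterns absent from the labelled data —
  exactly what distant supervision is meant to pick up) and is otherwise a
  non-relational co-mention built around a neutral connective;
* neutral connectives never occur in sentences carrying a relation, so they
  are minable as zero-co-occurrence negativity rules.

Default scale mirrors a small shared-task corpus: 134 labelled sentences
with roughly 38 positive examples per relation type.  All randomness flows
from one seeded generator; fixed seed implies identical corpora.

Sentences are template-generated ("AGENT trigger filler* TARGET filler*");
the featurizer needs realistic distance structure, not linguistic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus_io import Document, Entity, RelationInstance, Sentence, Token, default_stemmer
from .network_eval import Arc
from .distant import normalize_surface

__all__ = ["GenConfig", "GroundTruth", "generate", "planted_rule_corpus", "DEFAULT_TRIGGERS"]

DEFAULT_TRIGGERS: dict[str, list[str]] = {
    "Inhibition": ["inhibits", "represses", "antagonizes"],
    "Activation": ["activates", "stimulates", "induces"],
    "Requirement": ["requires", "necessitates", "presupposes"],
    "Binding": ["binds", "contacts", "docks"],
    "Transcription": ["transcribes", "copies", "reads"],
    "Regulation": ["regulates", "controls", "modulates"],
}

#: neutral connectives for non-relational co-mentions; never co-occur with a
#: relation, hence minable as negativity rules
CONNECTIVES = ["meanwhile", "whereas", "alongside", "near", "cotranscribed"]

_POS_BY_ROLE = {"entity": "NNP", "trigger": "VBZ", "filler": "NN", "connective": "RB", "conj": "CC"}


@dataclass
class GenConfig:
    seed: int = 0
    n_labelled: int = 134
    n_unlabelled: int = 400
    entity_lexicon_size: int = 30
    vocab_size: int = 50
    relation_probs: Mapping[str, float] | None = None  # default: 0.13 each
    trigger_map: Mapping[str, Sequence[str]] | None = None
    noise_rate: float = 0.3
    pair_overlap: float = 0.7
    #: labelled sentences draw triggers only from the first ``n_core``
    #: synonyms of each type; unlabelled/test text uses the full list
    core_triggers_only: bool = True
    n_core_triggers: int = 1

    def resolved_probs(self) -> dict[str, float]:
        probs = dict(self.relation_probs or {t: 0.13 for t in DEFAULT_TRIGGERS})
        total = sum(probs.values())
        if total > 1.0 + 1e-9 or any(not (0 <= p <= 1) for p in probs.values()):
            raise ValueError("relation_probs must be probabilities with sum <= 1")
        return probs

    def resolved_triggers(self) -> dict[str, list[str]]:
        return {t: list(v) for t, v in (self.trigger_map or DEFAULT_TRIGGERS).items()}

    def validate(self) -> None:
        if self.entity_lexicon_size < 2:
            raise ValueError("entity lexicon needs at least 2 names")
        if not (0 <= self.noise_rate <= 1 and 0 <= self.pair_overlap <= 1):
            raise ValueError("noise_rate and pair_overlap must lie in [0, 1]")
        self.resolved_probs()


@dataclass
class GroundTruth:
    """Relation status of every generated sentence, for evaluation.

    ``arcs`` is the corpus-level network over normalised entity surfaces;
    ``by_sentence`` maps sentence id -> realised (agent, target, type)
    triples (empty list = non-relational co-mention)."""

    arcs: set[Arc] = field(default_factory=set)
    by_sentence: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)


def _entity_names(n: int) -> list[str]:
    # gene-locus style names: sigA0, spoB1, ...
    stems = ["sig", "spo", "ger", "cot", "yqx", "kin"]
    return [f"{stems[i % len(stems)]}{chr(ord('A') + i % 26)}{i}" for i in range(n)]


def _fillers(n: int) -> list[str]:
    return [f"filler{i:02d}" for i in range(n)]


class _SentenceBuilder:
    def __init__(self, sid: str, origin: str):
        self.sid = sid
        self.origin = origin
        self.words: list[tuple[str, str]] = []  # (surface, role)
        self.entities: list[tuple[int, str, str]] = []  # (token idx, name, etype)
        self.relations: list[tuple[int, int, str]] = []  # entity-list indices

    def add(self, surface: str, role: str) -> int:
        self.words.append((surface, role))
        return len(self.words) - 1

    def add_entity(self, name: str, etype: str) -> int:
        idx = self.add(name, "entity")
        self.entities.append((idx, name, etype))
        return len(self.entities) - 1

    def build(self, attach_gold: bool, ent_counter: list[int]) -> Sentence:
        tokens = [
            Token(index=i, surface=w, stem=default_stemmer(w), pos=_POS_BY_ROLE[role])
            for i, (w, role) in enumerate(self.words)
        ]
        entities = []
        ids = []
        for tok_idx, name, etype in self.entities:
            ent_counter[0] += 1
            eid = f"T{ent_counter[0]}"
            ids.append(eid)
            entities.append(Entity(id=eid, etype=etype, span=(tok_idx, tok_idx + 1), text=name))
        relations = [
            RelationInstance(rtype=rt, agent=ids[a], target=ids[t])
            for a, t, rt in self.relations
        ]
        return Sentence(
            id=self.sid,
            tokens=tokens,
            entities=entities if attach_gold else [],
            relations=relations if attach_gold else [],
            origin=self.origin,
        )


def generate(cfg: GenConfig) -> tuple[list[Sentence], list[Sentence], GroundTruth]:
    """Generate (labelled sentences, unlabelled sentences, ground truth).

    Deterministic for a fixed seed.  Unlabelled sentences carry no entity or
    relation annotations (origin "unlabelled"); their true relation status
    lives in the returned :class:`GroundTruth`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = _entity_names(cfg.entity_lexicon_size)
    fillers = _fillers(cfg.vocab_size)
    probs = cfg.resolved_probs()
    triggers = cfg.resolved_triggers()
    types = list(probs)
    p_vec = np.array([probs[t] for t in types])
    p_none = max(0.0, 1.0 - p_vec.sum())
    etypes = {n: ("Gene" if i % 3 else "Protein") for i, n in enumerate(names)}

    def pick_trigger(rt: str, core: bool) -> str:
        opts = triggers[rt]
        if core:
            opts = opts[: max(1, cfg.n_core_triggers)]
        return str(rng.choice(opts))

    def pick_type() -> str | None:
        r = rng.random()
        acc = 0.0
        for t, p in zip(types, p_vec):
            acc += p
            if r < acc:
                return t
        return None

    truth = GroundTruth()
    ent_counter = [0]
    labelled: list[Sentence] = []
    gold_triples: list[tuple[str, str, str]] = []

    def relational_sentence(
        sid: str, origin: str, agent: str, target: str, rt: str, core: bool
    ) -> _SentenceBuilder:
        b = _SentenceBuilder(sid, origin)
        ia = b.add_entity(agent, etypes[agent])
        b.add(pick_trigger(rt, core), "trigger")
        for _ in range(int(rng.integers(1, 4))):
            b.add(str(rng.choice(fillers)), "filler")
        it = b.add_entity(target, etypes[target])
        for _ in range(int(rng.integers(0, 3))):
            b.add(str(rng.choice(fillers)), "filler")
        b.relations.append((ia, it, rt))
        return b

    def neutral_sentence(sid: str, origin: str, agent: str, target: str) -> _SentenceBuilder:
        b = _SentenceBuilder(sid, origin)
        b.add_entity(agent, etypes[agent])
        b.add(str(rng.choice(CONNECTIVES)), "connective")
        for _ in range(int(rng.integers(1, 4))):
            b.add(str(rng.choice(fillers)), "filler")
        b.add_entity(target, etypes[target])
        for _ in range(int(rng.integers(0, 3))):
            b.add(str(rng.choice(fillers)), "filler")
        return b

    core = cfg.core_triggers_only
    for k in range(cfg.n_labelled):
        sid = f"L{k + 1}"
        a, t = (str(x) for x in rng.choice(names, size=2, replace=False))
        rt = pick_type()
        if rt is None:
            b = neutral_sentence(sid, "labelled", a, t)
            realised: list[tuple[str, str, str]] = []
        else:
            b = relational_sentence(sid, "labelled", a, t, rt, core)
            realised = [(a, t, rt)]
            # occasionally a second relation to a third entity
            if rng.random() < 0.3:
                rt2 = pick_type()
                if rt2 is not None:
                    b.add("and", "conj")
                    b.add(pick_trigger(rt2, core), "trigger")
                    third = str(rng.choice([n for n in names if n not in (a, t)]))
                    i3 = b.add_entity(third, etypes[third])
                    b.relations.append((0, i3, rt2))
                    realised.append((a, third, rt2))
        sent = b.build(attach_gold=True, ent_counter=ent_counter)
        labelled.append(sent)
        gold_triples.extend(realised)
        truth.by_sentence[sid] = realised
        for ag, tg, rt_ in realised:
            truth.arcs.add(Arc(normalize_surface(ag), normalize_surface(tg), rt_))

    unlabelled: list[Sentence] = []
    for k in range(cfg.n_unlabelled):
        sid = f"U{k + 1}"
        if gold_triples and rng.random() < cfg.pair_overlap:
            a, t, rt = gold_triples[int(rng.integers(len(gold_triples)))]
            if rng.random() < cfg.noise_rate:
                b = neutral_sentence(sid, "unlabelled", a, t)
                realised = []
            else:
                b = relational_sentence(sid, "unlabelled", a, t, rt, core=False)
                realised = [(a, t, rt)]
        else:
            a, t = (str(x) for x in rng.choice(names, size=2, replace=False))
            rt = pick_type()
            if rt is None:
                b = neutral_sentence(sid, "unlabelled", a, t)
                realised = []
            else:
                b = relational_sentence(sid, "unlabelled", a, t, rt, core=False)
                realised = [(a, t, rt)]
        sent = b.build(attach_gold=False, ent_counter=ent_counter)
        unlabelled.append(sent)
        truth.by_sentence[sid] = realised
        for ag, tg, rt_ in realised:
            truth.arcs.add(Arc(normalize_surface(ag), normalize_surface(tg), rt_))

    return labelled, unlabelled, truth


def planted_rule_corpus(
    cfg: GenConfig,
    planted_rules: Sequence[tuple[str, str]],
    n_sentences_per_rule: int = 20,
) -> tuple[list[Sentence], list[Sentence], GroundTruth]:
    """Corpus with planted zero-co-occurrence structure.

    For each (relation type, forbidden trigger), appends labelled
    non-relational sentences (negative for every type) built around the
    forbidden trigger word, which never occurs in any relational sentence.
    Each such sentence contributes two negative candidate pairs whose
    context features carry the forbidden word, so the rule miner can
    recover the pattern once its support clears the threshold.
    """
    labelled, unlabelled, truth = generate(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    names = _entity_names(cfg.entity_lexicon_size)
    fillers = _fillers(cfg.vocab_size)
    etypes = {n: ("Gene" if i % 3 else "Protein") for i, n in enumerate(names)}
    ent_counter = [10**6]  # disjoint id range from generate()
    k = 0
    for rtype, forbidden in planted_rules:
        for _ in range(n_sentences_per_rule):
            k += 1
            b = _SentenceBuilder(f"P{k}", "labelled")
            a, t = (str(x) for x in rng.choice(names, size=2, replace=False))
            b.add_entity(a, etypes[a])
            b.add(forbidden, "connective")
            for _ in range(int(rng.integers(1, 3))):
                b.add(str(rng.choice(fillers)), "filler")
            b.add_entity(t, etypes[t])
            sent = b.build(attach_gold=True, ent_counter=ent_counter)
            labelled.append(sent)
            truth.by_sentence[sent.id] = []
    return labelled, unlabelled, truth


def as_document(sentences: Iterable[Sentence]) -> Document:
    return Document(sentences=list(sentences))
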