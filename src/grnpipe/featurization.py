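"""Sparse feature construction for candidate pairs.

A pair's vector is the concatenation of four blocks: local (one-hot) features
of the agent and target entities, and distance-decayed context features of
each entity.  Local features indicate the stem and part-of-speech of each
entity word plus the entity's biomolecule category.  The context block for an
entity is a weighted average of the one-hot blocks of all non-entity words in
the sentence,

    f_context = (1/Z) * sum_i alpha^d(w, w_i) * f_base(w_i),

where d is the flat token distance from word w_i to the nearest entity token,
alpha in (0, 1] controls the decay, and Z = sum_i alpha^d normalises the
weights to sum to one.  Context entries therefore lie in [0, 1] and, within
each feature family (stems; POS tags), sum to exactly 1 whenever the sentence
has at least one non-entity token.  As alpha -> 1 the average becomes uniform
over the non-entity words.

Each block reserves one out-of-vocabulary sentinel dimension, since test-time
words may be unseen even though the vocabulary is built over both the
labelled and the selected unlabelled sentences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .candidates import CandidatePair
from .corpus_io import Entity, Sentence

__all__ = [
    "BLOCKS",
    "LOCAL_BLOCKS",
    "CONTEXT_BLOCKS",
    "OOV",
    "ContextConfig",
    "Vocabulary",
    "FeatureVector",
    "build_vocabulary",
    "local_features",
    "context_features",
    "assemble",
    "features_matrix",
]

LOCAL_BLOCKS = ("agent_local", "target_local")
CONTEXT_BLOCKS = ("agent_context", "target_context")
BLOCKS = LOCAL_BLOCKS + CONTEXT_BLOCKS

#: reserved out-of-vocabulary key present once in every block
OOV = ("oov", "")


def token_distance(entity: Entity, token_index: int) -> int:
    """Flat sentence distance: minimum |i - j| over the entity's tokens."""
    lo, hi = entity.span
    return min(abs(token_index - j) for j in range(lo, hi))


@dataclass
class ContextConfig:
    """Decay configuration for context features (``alpha`` in (0, 1])."""

    alpha: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")


class Vocabulary:
    """Injective mapping (block, feature key) -> global dimension index.

    Keys are ``("stem", s)``, ``("pos", p)`` and, for local blocks only,
    ``("cat", c)``, plus the OOV sentinel.  Ordering is deterministic
    (lexicographic within each block), so the mapping is stable under
    re-serialization.
    """

    def __init__(self, block_keys: dict[str, list[tuple[str, str]]]):
        self._index: dict[str, dict[tuple[str, str], int]] = {}
        self._offsets: dict[str, int] = {}
        off = 0
        for block in BLOCKS:
            keys = block_keys.get(block, [])
            self._offsets[block] = off
            self._index[block] = {tuple(k): off + i for i, k in enumerate(keys)}
            off += len(keys)
        self.size = off

    def block_range(self, block: str) -> tuple[int, int]:
        start = self._offsets[block]
        return start, start + len(self._index[block])

    def index(self, block: str, key: tuple[str, str]) -> int:
        """Dimension of ``key`` in ``block``; unknown keys map to the OOV
        sentinel of that block."""
        blk = self._index[block]
        return blk.get(tuple(key), blk[OOV])

    def key_of(self, dim: int) -> tuple[str, str, str]:
        """Inverse lookup (block, kind, value) — used for stable rule dumps."""
        for block, mapping in self._index.items():
            for key, d in mapping.items():
                if d == dim:
                    return (block, key[0], key[1])
        raise KeyError(dim)

    def keys(self, block: str) -> list[tuple[str, str]]:
        return sorted(self._index[block], key=lambda k: self._index[block][k])

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "version": 1,
            "blocks": {b: [list(k) for k in self.keys(b)] for b in BLOCKS},
        }
        return json.dumps(payload, indent=0, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        payload = json.loads(text)
        return cls({b: [tuple(k) for k in ks] for b, ks in payload["blocks"].items()})

    def __eq__(self, other) -> bool:
        return isinstance(other, Vocabulary) and self._index == other._index


def build_vocabulary(sentences: Iterable[Sentence]) -> Vocabulary:
    """Collect every stem, POS tag and entity category into a Vocabulary.

    Local blocks receive stem + POS + category keys; context blocks receive
    stem + POS keys only (non-entity words carry no biomolecule category).
    """
    stems: set[str] = set()
    poss: set[str] = set()
    cats: set[str] = set()
    for s in sentences:
        for t in s.tokens:
            stems.add(t.stem)
            poss.add(t.pos)
        for e in s.entities:
            cats.add(e.etype)
    word_keys = [("stem", s) for s in sorted(stems)] + [("pos", p) for p in sorted(poss)]
    local = word_keys + [("cat", c) for c in sorted(cats)] + [OOV]
    context = word_keys + [OOV]
    return Vocabulary(
        {
            "agent_local": local,
            "target_local": list(local),
            "agent_context": context,
            "target_context": list(context),
        }
    )


@dataclass
class FeatureVector:
    """Sparse vector: map global dimension -> value in [0, 1]."""

    data: dict[int, float]
    vocab: Vocabulary

    def toarray(self) -> np.ndarray:
        v = np.zeros(self.vocab.size)
        for d, x in self.data.items():
            v[d] = x
        return v


def local_features(entity: Entity, sentence: Sentence, vocab: Vocabulary, block: str) -> dict[int, float]:
    """Binary indicators for each entity word's stem and POS plus the
    entity category.  Indicators are set once (binary, not counted)."""
    if block not in LOCAL_BLOCKS:
        raise ValueError(f"{block!r} is not a local block")
    out: dict[int, float] = {}
    lo, hi = entity.span
    for t in sentence.tokens[lo:hi]:
        out[vocab.index(block, ("stem", t.stem))] = 1.0
        out[vocab.index(block, ("pos", t.pos))] = 1.0
    out[vocab.index(block, ("cat", entity.etype))] = 1.0
    return out


def context_features(
    entity: Entity,
    sentence: Sentence,
    vocab: Vocabulary,
    cfg: ContextConfig,
    block: str,
) -> dict[int, float]:
    """Distance-decayed average of the one-hot word blocks of all tokens
    outside the entity span (tokens of the pair's other entity included).

    Returns the zero block when the sentence has no non-entity token.
    """
    if block not in CONTEXT_BLOCKS:
        raise ValueError(f"{block!r} is not a context block")
    lo, hi = entity.span
    outside = [t for t in sentence.tokens if not (lo <= t.index < hi)]
    if not outside:
        return {}
    weights = np.array(
        [cfg.alpha ** token_distance(entity, t.index) for t in outside]
    )
    weights /= weights.sum()
    out: dict[int, float] = {}
    for t, w in zip(outside, weights):
        for key in (("stem", t.stem), ("pos", t.pos)):
            d = vocab.index(block, key)
            out[d] = out.get(d, 0.0) + float(w)
    # accumulated weights can overshoot 1.0 by float epsilon
    return {d: min(v, 1.0) for d, v in out.items()}


def assemble(pair: CandidatePair, vocab: Vocabulary, cfg: ContextConfig | None = None) -> FeatureVector:
    """Concatenate the four blocks for one candidate pair."""
    cfg = cfg or ContextConfig()
    data: dict[int, float] = {}
    data.update(local_features(pair.agent, pair.sentence, vocab, "agent_local"))
    data.update(local_features(pair.target, pair.sentence, vocab, "target_local"))
    data.update(context_features(pair.agent, pair.sentence, vocab, cfg, "agent_context"))
    data.update(context_features(pair.target, pair.sentence, vocab, cfg, "target_context"))
    return FeatureVector(data=data, vocab=vocab)


def features_matrix(
    pairs: Sequence[CandidatePair],
    vocab: Vocabulary,
    cfg: ContextConfig | None = None,
) -> sparse.csr_matrix:
    """Stack assembled vectors into a CSR matrix (rows follow ``pairs``)."""
    cfg = cfg or ContextConfig()
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i, pair in enumerate(pairs):
        for d, x in assemble(pair, vocab, cfg).data.items():
            rows.append(i)
            cols.append(d)
            vals.append(x)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(pairs), vocab.size)
    )


def dump_coo(matrix: sparse.spmatrix) -> str:
    """Sparse coordinate text export: one ``row col value`` line per entry."""
    coo = matrix.tocoo()
    lines = [
        f"{r} {c} {v:.12g}" for r, c, v in zip(coo.row, coo.col, coo.data)
    ]
    return "\n".join(lines) + ("\n" if lines else "")
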