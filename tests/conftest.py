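import numpy as np
import pytest

from grnpipe.corpus_io import (
    Entity,
    RelationInstance,
    Sentence,
    Token,
    default_hierarchy,
    default_stemmer,
)


def make_sentence(sid, words, entities=(), relations=(), origin="labelled", pos=None):
    """Handmade sentence: ``entities`` = (id, etype, lo, hi) tuples over token
    indices, ``relations`` = (rtype, agent_id, target_id)."""
    tokens = [
        Token(index=i, surface=w, stem=default_stemmer(w), pos=(pos[i] if pos else "NN"))
        for i, w in enumerate(words)
    ]
    ents = [
        Entity(id=eid, etype=etype, span=(lo, hi), text=" ".join(words[lo:hi]))
        for eid, etype, lo, hi in entities
    ]
    rels = [RelationInstance(rtype=r, agent=a, target=t) for r, a, t in relations]
    return Sentence(id=sid, tokens=tokens, entities=ents, relations=rels, origin=origin)


@pytest.fixture
def hierarchy():
    return default_hierarchy()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def figure_sentence():
    """Two genic entities with one Requirement-flavoured relation."""
    return make_sentence(
        "S1",
        ["GerE", "is", "required", "for", "sspG", "expression"],
        entities=[("T1", "Protein", 0, 1), ("T2", "Gene", 4, 5)],
        relations=[("Interaction:Requirement", "T1", "T2")],
    )


def random_sentences(rng, n, max_tokens=12, vocab=30, origin="labelled"):
    """Random sentences with two single-token entities at random positions."""
    out = []
    for k in range(n):
        n_tok = int(rng.integers(4, max_tokens + 1))
        words = [f"w{int(rng.integers(vocab))}" for _ in range(n_tok)]
        i, j = sorted(rng.choice(n_tok, size=2, replace=False))
        words[i] = f"entA{k}"
        words[j] = f"entB{k}"
        sent = make_sentence(
            f"R{k}",
            words,
            entities=[("T1", "Gene", int(i), int(i) + 1), ("T2", "Protein", int(j), int(j) + 1)],
            origin=origin,
        )
        out.append(sent)
    return out
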