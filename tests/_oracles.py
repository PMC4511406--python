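"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive results by naive enumeration (set algebra,
double loops) and share no code path with the implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Rule mining: exhaustive enumeration of zero-co-occurrence rules
# ---------------------------------------------------------------------------

def brute_force_rules(matrix, labels, threshold, eps=0.0):
    """All arity-1 and arity-2 (dimension, side) negativity rules.

    side 0: value <= eps; side 1: value > eps.  Returns a set of frozensets
    of (dim, side) conditions, and a dict condition-set -> negative support.
    """
    x = np.asarray(matrix.toarray() if hasattr(matrix, "toarray") else matrix)
    y = np.asarray(labels)
    n, d = x.shape
    pos_rows = [k for k in range(n) if y[k] == 1]
    neg_rows = [k for k in range(n) if y[k] == 0]

    def member(k, dim, side):
        v = x[k, dim]
        return v > eps if side == 1 else v <= eps

    rules = {}
    sides = [(dim, side) for dim in range(d) for side in (0, 1)]
    for dim, side in sides:
        npos = sum(member(k, dim, side) for k in pos_rows)
        nneg = sum(member(k, dim, side) for k in neg_rows)
        if npos == 0 and nneg > threshold:
            rules[frozenset([(dim, side)])] = nneg
    for (d1, s1), (d2, s2) in itertools.combinations(sides, 2):
        if d1 == d2:
            continue
        npos = sum(member(k, d1, s1) and member(k, d2, s2) for k in pos_rows)
        nneg = sum(member(k, d1, s1) and member(k, d2, s2) for k in neg_rows)
        if npos == 0 and nneg > threshold:
            rules[frozenset([(d1, s1), (d2, s2)])] = nneg
    return rules


def brute_force_apply(rule_condition_sets, matrix, eps=0.0):
    """Per-point rule evaluation by direct looping."""
    x = np.asarray(matrix.toarray() if hasattr(matrix, "toarray") else matrix)
    out = np.zeros(x.shape[0], dtype=bool)
    for k in range(x.shape[0]):
        for conds in rule_condition_sets:
            ok = True
            for dim, side in conds:
                v = x[k, dim]
                if not (v > eps if side == 1 else v <= eps):
                    ok = False
                    break
            if ok:
                out[k] = True
                break
    return out


# ---------------------------------------------------------------------------
# Context features: naive double-loop evaluation of the decay sum
# ---------------------------------------------------------------------------

def naive_context_block(entity, sentence, vocab, alpha, block):
    """Direct evaluation of (1/Z) sum_i alpha^d(w, w_i) f_base(w_i)."""
    lo, hi = entity.span
    ent_idx = list(range(lo, hi))
    weights = {}
    for t in sentence.tokens:
        if t.index in ent_idx:
            continue
        d = min(abs(t.index - j) for j in ent_idx)
        weights[t.index] = alpha**d
    z = sum(weights.values())
    out = {}
    for t in sentence.tokens:
        if t.index not in weights:
            continue
        w = weights[t.index] / z
        for key in (("stem", t.stem), ("pos", t.pos)):
            dim = vocab.index(block, key)
            out[dim] = out.get(dim, 0.0) + w
    return out


# ---------------------------------------------------------------------------
# Network error counting: per-arc exhaustive classification
# ---------------------------------------------------------------------------

def naive_error_counts(predicted, reference):
    """Classify every arc of both networks one by one.

    A reference arc is Correct if present in the prediction; a predicted arc
    is Correct if present in the reference.  A non-correct reference arc is
    a Substitution if the prediction holds some arc on the same pair (up to
    the number of such non-correct predicted arcs), else a Deletion;
    symmetrically non-correct predicted arcs are Substitutions or
    Insertions.  Returns (S, I, D, C).
    """
    pred = set(predicted)
    ref = set(reference)
    c = len(pred & ref)
    s = i = d = 0
    pairs = {(a[0], a[1]) for a in pred | ref}
    for pair in pairs:
        p_wrong = [a for a in pred - ref if (a[0], a[1]) == pair]
        r_wrong = [a for a in ref - pred if (a[0], a[1]) == pair]
        has_common = any((a[0], a[1]) == pair for a in pred & ref)
        if has_common:
            i += len(p_wrong)
            d += len(r_wrong)
        else:
            k = min(len(p_wrong), len(r_wrong))
            s += k
            i += len(p_wrong) - k
            d += len(r_wrong) - k
    return s, i, d, c
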