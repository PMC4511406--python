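"""Automatic mining of sufficient conditions for negativity.

Given a feature matrix with values in [0, 1] and binary labels, each feature
dimension is split into two bins: the "zero" bin (value <= eps, eps = 0 by
default) and its complement.  A bin side that is never occupied by a positive
training point but is occupied by strictly more than ``threshold`` negative
points is taken as a sufficient condition for a negative label (a
zero-co-occurrence rule).  Conjunctions of two such conditions are mined as
well; the pairwise search is restricted to the candidate set T of
dimension-sides whose negative support already exceeds the threshold, since
the joint support can never exceed either marginal support.  Arity is capped
at two to keep the search tractable.

The threshold is the knob trading precision against recall downstream: with
a high threshold few rules survive, so fewer distant positives get filtered
and fewer negatives are harvested.  The default is 25% of the labelled data
size (the midpoint of the 20-30% band that balances the two).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "BinAssignment",
    "Rule",
    "RuleSet",
    "bin_features",
    "mine_rules",
    "apply_rules",
    "default_threshold",
]

ZERO_SIDE = 0  # value <= eps  (the V_i bin; f_i = 0 for binary features)
NONZERO_SIDE = 1  # value > eps


@dataclass(frozen=True)
class BinAssignment:
    """Two-bin split per dimension: ``value <= eps`` vs ``value > eps``."""

    eps: float = 0.0

    def membership(self, matrix, side: int) -> np.ndarray:
        """Dense boolean matrix of bin membership for one side."""
        x = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
        if x.size and (x.min() < 0.0 or x.max() > 1.0):
            raise ValueError("feature values must lie in [0, 1]")
        nz = x > self.eps
        return nz if side == NONZERO_SIDE else ~nz


@dataclass(frozen=True)
class Rule:
    """Conjunction of (dimension, bin side) conditions implying negativity.

    ``support`` counts negative training points satisfying all conditions;
    no positive training point satisfies them (zero co-occurrence).
    """

    conditions: tuple[tuple[int, int], ...]
    support: int

    @property
    def arity(self) -> int:
        return len(self.conditions)


@dataclass
class RuleSet:
    rules: list[Rule] = field(default_factory=list)
    threshold: int = 1
    bins: BinAssignment = field(default_factory=BinAssignment)

    def __len__(self) -> int:
        return len(self.rules)

    def to_json_obj(self, vocab=None) -> dict:
        def dim_repr(d: int):
            return list(vocab.key_of(d)) if vocab is not None else d

        return {
            "threshold": self.threshold,
            "eps": self.bins.eps,
            "rules": [
                {
                    "conditions": [[dim_repr(d), s] for d, s in r.conditions],
                    "support": r.support,
                }
                for r in self.rules
            ],
        }


def bin_features(matrix, eps: float = 0.0) -> BinAssignment:
    """Validate the value range and fix the two-bin split."""
    x = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
    if x.size and (x.min() < 0.0 or x.max() > 1.0):
        raise ValueError("feature values must lie in [0, 1]")
    return BinAssignment(eps=eps)


def default_threshold(n_labelled: int, fraction: float = 0.25) -> int:
    """Support threshold as a fraction of the labelled data size (>= 1)."""
    if n_labelled <= 0:
        raise ValueError("n_labelled must be positive")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    return max(1, round(fraction * n_labelled))


def mine_rules(
    matrix,
    labels: Sequence[int],
    threshold: int,
    eps: float = 0.0,
    subsume: bool = False,
) -> RuleSet:
    """Mine all arity-1 and arity-2 zero-co-occurrence negativity rules.

    A condition set is a rule iff no positive point satisfies it and strictly
    more than ``threshold`` negative points do.  Both bin sides of every
    dimension are examined.  With ``subsume=True``, pair rules implied by a
    kept single rule on either dimension are dropped (off by default).
    """
    y = np.asarray(labels)
    if y.ndim != 1 or not set(np.unique(y)).issubset({0, 1}):
        raise ValueError("labels must be a flat 0/1 array")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bins = bin_features(matrix, eps=eps)
    n_neg = int((y == 0).sum())
    if threshold >= n_neg:
        warnings.warn(
            f"threshold {threshold} >= number of negatives {n_neg}; "
            "no rule can reach the required support",
            stacklevel=2,
        )
        return RuleSet(rules=[], threshold=threshold, bins=bins)

    pos = y == 1
    neg = ~pos
    # membership columns for both sides, tracked as (dim, side) entries
    sides = []
    cols = []
    for side in (ZERO_SIDE, NONZERO_SIDE):
        m = bins.membership(matrix, side)
        for d in range(m.shape[1]):
            sides.append((d, side))
            cols.append(m[:, d])
    M = np.column_stack(cols) if cols else np.zeros((len(y), 0), dtype=bool)
    neg_counts = M[neg].sum(axis=0)
    pos_counts = M[pos].sum(axis=0)

    rules: list[Rule] = []
    singles: set[tuple[int, int]] = set()
    in_T: list[int] = []
    for k, (d, side) in enumerate(sides):
        if neg_counts[k] > threshold:
            in_T.append(k)
            if pos_counts[k] == 0:
                rules.append(
                    Rule(conditions=((d, side),), support=int(neg_counts[k]))
                )
                singles.add((d, side))

    if in_T:
        Mt = M[:, in_T]
        pos_co = Mt[pos].astype(np.int64).T @ Mt[pos].astype(np.int64)
        neg_co = Mt[neg].astype(np.int64).T @ Mt[neg].astype(np.int64)
        for a in range(len(in_T)):
            da, sa = sides[in_T[a]]
            for b in range(a + 1, len(in_T)):
                db, sb = sides[in_T[b]]
                if da == db:
                    continue  # two sides of one dimension are no conjunction
                if pos_co[a, b] == 0 and neg_co[a, b] > threshold:
                    if subsume and ((da, sa) in singles or (db, sb) in singles):
                        continue
                    conds = tuple(sorted(((da, sa), (db, sb))))
                    rules.append(Rule(conditions=conds, support=int(neg_co[a, b])))

    return RuleSet(rules=rules, threshold=threshold, bins=bins)


def apply_rules(rules: RuleSet, matrix) -> np.ndarray:
    """Boolean mask: True where a point satisfies every condition of at
    least one rule (i.e. is predicted negative)."""
    x = matrix.toarray() if sparse.issparse(matrix) else np.asarray(matrix)
    n, d = x.shape
    for r in rules.rules:
        for dim, _ in r.conditions:
            if not (0 <= dim < d):
                raise ValueError(f"rule dimension {dim} out of range for d={d}")
    mask = np.zeros(n, dtype=bool)
    if not rules.rules:
        return mask
    memb = {
        side: rules.bins.membership(x, side) for side in (ZERO_SIDE, NONZERO_SIDE)
    }
    for r in rules.rules:
        hit = np.ones(n, dtype=bool)
        for dim, side in r.conditions:
            hit &= memb[side][:, dim]
        mask |= hit
    return mask
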