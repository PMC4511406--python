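"""Network aggregation and the Slot Error Rate metric suite.

Predictions are aggregated into a network whose nodes are (normalised)
entity surface forms and whose arcs are directed, typed relations.  Scoring
is *global*: duplicate predictions of one relation collapse into a single
arc, and an arc whose type is a strict ancestor (less specific) of another
arc's type on the same entity pair is removed before counting ("resolution
of redundant arcs").  This makes the precision/recall trade-off
non-monotone: adding a more specific correct arc can delete an existing
correct, more generic one.

Counting against a reference network yields
  C  correct arcs (matching agent, target and type),
  S  substitutions (pair present in both networks, no type agreement),
  I  insertions (predicted arcs on pairs absent from the reference),
  D  deletions (reference arcs on pairs absent from the prediction),
  N = C + S + D  reference arcs,   M = C + S + I  predicted arcs.

Derived metrics:
  precision = C/M,  recall = C/N,
  SER = (S + I + D)/N = 1 - recall + I/N     (independent of S given N, I),
  F_beta = (1 + b^2) P R / (b^2 P + R),  F1 = 1 - (2S + I + D)/(N + M).

Because SER = 1 + R/P - 2R - S/N when rewritten over recall and precision
(at fixed S and N), its recall-gradient 1/P - 2 changes sign at P = 1/2:
below 50% precision, raising recall *raises* the error rate, which is the
precision bias this metric carries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .corpus_io import RelationHierarchy

__all__ = [
    "Arc",
    "Counts",
    "ScoreBreakdown",
    "build_network",
    "resolve_redundant",
    "count_errors",
    "compute_metrics",
    "score_networks",
    "ser_gradient",
    "f_beta_gradient",
]


class Arc(NamedTuple):
    """Directed, typed arc between two entity nodes."""

    agent: str
    target: str
    rtype: str


class Counts(NamedTuple):
    s: int
    i: int
    d: int
    c: int

    @property
    def n(self) -> int:
        return self.c + self.s + self.d

    @property
    def m(self) -> int:
        return self.c + self.s + self.i


@dataclass(frozen=True)
class ScoreBreakdown:
    """Error counts plus the derived metric suite (beta-parameterised).

    ``precision`` and ``f_beta`` are None when the prediction is empty
    (M = 0): an undefined ratio is flagged missing rather than scored 0.
    """

    s: int
    i: int
    d: int
    c: int
    n: int
    m: int
    recall: float
    precision: float | None
    f1: float
    f_beta: float | None
    ser: float
    beta: float = 1.0

    def to_dict(self) -> dict:
        return {
            "S": self.s, "D": self.d, "I": self.i, "C": self.c,
            "N": self.n, "M": self.m,
            "recall": self.recall, "precision": self.precision,
            "F1": self.f1, "F_beta": self.f_beta, "SER": self.ser,
            "beta": self.beta,
        }

    def summary(self) -> str:
        p = "  n/a" if self.precision is None else f"{100 * self.precision:5.1f}"
        return (
            f"S={self.s} D={self.d} I={self.i} C={self.c} M={self.m} N={self.n}  "
            f"Recall={100 * self.recall:5.1f}  Prec.={p}  "
            f"F1={100 * self.f1:5.1f}  SER={self.ser:.3f}"
        )


def build_network(predictions: Iterable[tuple[str, str, str] | Arc]) -> set[Arc]:
    """Collapse predicted (agent, target, type) triples into an arc set."""
    return {Arc(*p) for p in predictions}


def resolve_redundant(network: Iterable[Arc], hierarchy: RelationHierarchy) -> set[Arc]:
    """Drop every arc whose type is a strict ancestor of another arc's type
    on the same (agent, target) pair.  Idempotent."""
    net = set(network)
    for a in net:
        if a.rtype not in hierarchy.types:
            raise ValueError(f"arc type {a.rtype!r} not in hierarchy")
    out = set()
    for a in net:
        shadowed = any(
            b != a
            and (b.agent, b.target) == (a.agent, a.target)
            and hierarchy.is_ancestor(a.rtype, b.rtype)
            for b in net
        )
        if not shadowed:
            out.add(a)
    return out


def count_errors(predicted: Iterable[Arc], reference: Iterable[Arc]) -> Counts:
    """Classify every arc of both (post-resolution) networks.

    Per (agent, target) pair: type matches count as C.  A pair present in
    both networks with no type agreement contributes substitutions (one per
    matched pred/ref arc couple); leftover predicted types on any shared
    pair are insertions and leftover reference types deletions.  Pairs
    present in only one network contribute pure insertions or deletions.
    The identities N = C + S + D = |reference| and M = C + S + I =
    |predicted| hold by construction.
    """
    pred = set(predicted)
    ref = set(reference)
    pairs = {(a.agent, a.target) for a in pred} | {(a.agent, a.target) for a in ref}
    s = i = d = c = 0
    for pair in pairs:
        pt = {a.rtype for a in pred if (a.agent, a.target) == pair}
        rt = {a.rtype for a in ref if (a.agent, a.target) == pair}
        common = pt & rt
        c += len(common)
        if common:
            i += len(pt - common)
            d += len(rt - common)
        elif pt and rt:
            subs = min(len(pt), len(rt))
            s += subs
            i += len(pt) - subs
            d += len(rt) - subs
        elif pt:
            i += len(pt)
        else:
            d += len(rt)
    return Counts(s=s, i=i, d=d, c=c)


def compute_metrics(counts: Counts, beta: float = 1.0) -> ScoreBreakdown:
    """Derive precision, recall, F1, F_beta and SER from error counts."""
    s, i, d, c = counts
    if min(s, i, d, c) < 0:
        raise ValueError("counts must be non-negative")
    n, m = counts.n, counts.m
    if n <= 0:
        raise ValueError("reference network must be non-empty (N > 0)")
    recall = c / n
    precision = c / m if m > 0 else None
    ser = (s + i + d) / n
    f1 = 1.0 - (2 * s + i + d) / (n + m)
    if precision is None or precision + recall == 0:
        f_beta = None if precision is None else 0.0
    else:
        b2 = beta * beta
        denom = b2 * precision + recall
        f_beta = (1 + b2) * precision * recall / denom if denom else 0.0
    return ScoreBreakdown(
        s=s, i=i, d=d, c=c, n=n, m=m,
        recall=recall, precision=precision, f1=f1, f_beta=f_beta, ser=ser,
        beta=beta,
    )


def score_networks(
    predicted: Iterable[Arc],
    reference: Iterable[Arc],
    hierarchy: RelationHierarchy | None = None,
    beta: float = 1.0,
    resolve: bool = True,
) -> ScoreBreakdown:
    """End-to-end global scoring: aggregate, resolve redundancy, count,
    derive metrics.  With ``resolve=False`` the networks are scored as-is
    (local, unprocessed figures)."""
    pred = build_network(predicted)
    ref = build_network(reference)
    if resolve:
        if hierarchy is None:
            raise ValueError("hierarchy required for global (resolved) scoring")
        pred = resolve_redundant(pred, hierarchy)
        ref = resolve_redundant(ref, hierarchy)
    return compute_metrics(count_errors(pred, ref), beta=beta)


# ---------------------------------------------------------------------------
# Gradient fields in recall-precision space
# ---------------------------------------------------------------------------

def ser_gradient(recall: float, precision: float) -> tuple[float, float]:
    """Partial derivatives of SER(R, P) = 1 + R/P - 2R - S/N at fixed S, N.

    Returns (dSER/dR, dSER/dP) = (1/P - 2, -R/P^2).  The recall-derivative
    vanishes at P = 0.5 and is positive below it: in that half-plane,
    improving SER pushes recall *down*.
    """
    if precision <= 0:
        raise ValueError("precision must be > 0")
    return (1.0 / precision - 2.0, -recall / precision**2)


def f_beta_gradient(
    recall: float, precision: float, beta: float = 1.0
) -> tuple[float, float]:
    """Analytic gradient of F_beta over (R, P); both components >= 0."""
    if precision + recall <= 0:
        raise ValueError("P + R must be > 0")
    b2 = beta * beta
    denom = (b2 * precision + recall) ** 2
    d_dr = (1 + b2) * b2 * precision**2 / denom
    d_dp = (1 + b2) * recall**2 / denom
    return (d_dr, d_dp)
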