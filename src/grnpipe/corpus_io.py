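"""Read/write corpora in BioNLP shared-task standoff format.

A corpus document is a plain-text file (one sentence per line) accompanied by
two annotation files: ``.a1`` holds entity (term) annotations with character
offsets into the text, ``.a2`` holds directed, typed relations between a1
entities.  Offsets are 0-based, half-open ``[start, end)``.

Tokenization, stemming and part-of-speech tagging are injected contracts with
deterministic defaults, so no statistical models need to be downloaded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import yaml

__all__ = [
    "Token",
    "Entity",
    "RelationInstance",
    "Sentence",
    "Document",
    "RelationHierarchy",
    "StandoffError",
    "MalformedAnnotationError",
    "DanglingReferenceError",
    "InvalidHierarchyError",
    "default_tokenizer",
    "default_stemmer",
    "default_pos_tagger",
    "read_standoff",
    "write_standoff",
    "load_hierarchy",
    "default_hierarchy",
]


class StandoffError(ValueError):
    """Base error for malformed standoff input."""


class MalformedAnnotationError(StandoffError):
    """An annotation record is syntactically broken or its offsets do not
    match the document text; the message names the offending annotation id."""


class DanglingReferenceError(StandoffError):
    """A relation references an entity id that does not exist."""


class InvalidHierarchyError(ValueError):
    """The relation-type hierarchy config is cyclic or references an
    undeclared type."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Token:
    """One token of a sentence.

    ``index`` is the 0-based position within the sentence; ``start``/``end``
    are character offsets into the whole document text (-1 when unknown).
    """

    index: int
    surface: str
    stem: str
    pos: str
    start: int = -1
    end: int = -1


@dataclass
class Entity:
    """A typed, contiguous entity mention.

    ``span`` is a half-open token-index range ``(lo, hi)`` within the
    sentence; ``etype`` is the biomolecule category (Gene, Protein, ...).
    """

    id: str
    etype: str
    span: tuple[int, int]
    text: str


@dataclass
class RelationInstance:
    """A directed, typed relation: the agent entity acts on the target."""

    rtype: str
    agent: str  # entity id
    target: str  # entity id


@dataclass
class Sentence:
    id: str
    tokens: list[Token]
    entities: list[Entity] = field(default_factory=list)
    relations: list[RelationInstance] = field(default_factory=list)
    origin: str = "labelled"  # "labelled" | "unlabelled"
    text: str | None = None

    def entity(self, eid: str) -> Entity:
        for e in self.entities:
            if e.id == eid:
                return e
        raise KeyError(eid)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def validate(self) -> None:
        n = len(self.tokens)
        for i, t in enumerate(self.tokens):
            if t.index != i:
                raise ValueError(f"token index {t.index} != position {i}")
        ids = [e.id for e in self.entities]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate entity ids in sentence {self.id}")
        for e in self.entities:
            lo, hi = e.span
            if not (0 <= lo < hi <= n):
                raise ValueError(
                    f"entity {e.id} span {e.span} outside sentence {self.id}"
                )
            joined = " ".join(t.surface for t in self.tokens[lo:hi])
            if _squash(e.text) != _squash(joined):
                raise ValueError(
                    f"entity {e.id} text {e.text!r} != spanned tokens {joined!r}"
                )
        for r in self.relations:
            if r.agent == r.target:
                raise ValueError(f"self-relation on entity {r.agent}")
            self.entity(r.agent)
            self.entity(r.target)


@dataclass
class Document:
    sentences: list[Sentence]
    text: str | None = None

    def validate(self) -> None:
        for s in self.sentences:
            s.validate()
        ids = [e.id for s in self.sentences for e in s.entities]
        if len(set(ids)) != len(ids):
            raise ValueError("entity ids must be unique within a document")


def _squash(s: str) -> str:
    return " ".join(s.split())


# ---------------------------------------------------------------------------
# Default linguistic contracts
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")

# crude inflectional suffix stripping; deterministic, no language model
_SUFFIXES = ("ing", "edly", "ed", "ly", "ies", "es", "s")


def default_stemmer(word: str) -> str:
    w = word.lower()
    for suf in _SUFFIXES:
        if w.endswith(suf) and len(w) - len(suf) >= 3:
            return w[: -len(suf)]
    return w


def default_pos_tagger(word: str, lexicon: Mapping[str, str] | None = None) -> str:
    if lexicon is not None:
        tag = lexicon.get(word.lower())
        if tag is not None:
            return tag
    return "UNK"


def default_tokenizer(
    text: str,
    offset: int = 0,
    stemmer: Callable[[str], str] = default_stemmer,
    pos_lexicon: Mapping[str, str] | None = None,
) -> list[Token]:
    """Split on whitespace/punctuation boundaries, keeping char offsets."""
    toks: list[Token] = []
    for i, m in enumerate(_TOKEN_RE.finditer(text)):
        w = m.group(0)
        toks.append(
            Token(
                index=i,
                surface=w,
                stem=stemmer(w),
                pos=default_pos_tagger(w, pos_lexicon),
                start=offset + m.start(),
                end=offset + m.end(),
            )
        )
    return toks


# ---------------------------------------------------------------------------
# Standoff reading / writing
# ---------------------------------------------------------------------------

def _as_text(stream) -> str:
    if isinstance(stream, str):
        return stream
    if isinstance(stream, Path):
        return stream.read_text()
    return stream.read()


_A1_RE = re.compile(r"^(T\w+)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_standoff(
    text_doc,
    a1,
    a2,
    tokenizer: Callable[..., list[Token]] | None = None,
    agent_role: str = "Agent",
    target_role: str = "Target",
    origin: str = "labelled",
) -> Document:
    """Parse a ``.txt`` + ``.a1`` + ``.a2`` triple into a :class:`Document`.

    Each line of the text is one sentence.  ``agent_role``/``target_role``
    name the a2 argument roles (some task dialects use different names).
    """
    tokenizer = tokenizer or default_tokenizer
    text = _as_text(text_doc)
    a1_text = _as_text(a1)
    a2_text = _as_text(a2)

    sentences: list[Sentence] = []
    bounds: list[tuple[int, int]] = []
    pos = 0
    for li, line in enumerate(text.split("\n")):
        start, end = pos, pos + len(line)
        pos = end + 1
        if not line.strip():
            continue
        toks = tokenizer(line, offset=start)
        sentences.append(Sentence(id=f"S{len(sentences) + 1}", tokens=toks, origin=origin))
        bounds.append((start, end))

    ent_sentence: dict[str, int] = {}
    for raw in a1_text.splitlines():
        if not raw.strip():
            continue
        m = _A1_RE.match(raw)
        if not m:
            raise MalformedAnnotationError(f"unparseable a1 line: {raw!r}")
        eid, etype, s_s, s_e, etext = m.groups()
        cs, ce = int(s_s), int(s_e)
        if not (0 <= cs < ce <= len(text)):
            raise MalformedAnnotationError(
                f"annotation {eid}: offsets [{cs},{ce}) outside document"
            )
        if text[cs:ce] != etext:
            raise MalformedAnnotationError(
                f"annotation {eid}: text {etext!r} != document slice {text[cs:ce]!r}"
            )
        si = next(
            (k for k, (bs, be) in enumerate(bounds) if bs <= cs and ce <= be),
            None,
        )
        if si is None:
            raise MalformedAnnotationError(
                f"annotation {eid}: span [{cs},{ce}) crosses a sentence boundary"
            )
        sent = sentences[si]
        covered = [t.index for t in sent.tokens if t.start < ce and t.end > cs]
        if not covered:
            raise MalformedAnnotationError(f"annotation {eid}: no tokens in span")
        span = (min(covered), max(covered) + 1)
        if span[1] - span[0] != len(covered):
            raise MalformedAnnotationError(f"annotation {eid}: discontiguous span")
        sent.entities.append(Entity(id=eid, etype=etype, span=span, text=etext))
        ent_sentence[eid] = si

    for raw in a2_text.splitlines():
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise MalformedAnnotationError(f"unparseable a2 line: {raw!r}")
        rid, body = parts[0], parts[1]
        fields = body.split()
        rtype = fields[0]
        roles: dict[str, str] = {}
        for f in fields[1:]:
            role, _, ref = f.rpartition(":")
            roles[role.lower()] = ref
        try:
            agent_id = roles[agent_role.lower()]
            target_id = roles[target_role.lower()]
        except KeyError as exc:
            raise MalformedAnnotationError(
                f"relation {rid}: missing role {exc} (roles seen: {sorted(roles)})"
            ) from None
        for ref in (agent_id, target_id):
            if ref not in ent_sentence:
                raise DanglingReferenceError(
                    f"relation {rid} references unknown entity {ref}"
                )
        if ent_sentence[agent_id] != ent_sentence[target_id]:
            raise MalformedAnnotationError(
                f"relation {rid}: entities in different sentences"
            )
        sentences[ent_sentence[agent_id]].relations.append(
            RelationInstance(rtype=rtype, agent=agent_id, target=target_id)
        )

    doc = Document(sentences=sentences, text=text)
    doc.validate()
    return doc


def write_standoff(
    doc: Document,
    agent_role: str = "Agent",
    target_role: str = "Target",
) -> tuple[str, str, str]:
    """Serialise a :class:`Document` back to ``(txt, a1, a2)`` strings.

    Byte-stable for a fixed Document: sentence text is reconstructed from
    token offsets when available, otherwise tokens are joined with single
    spaces and offsets assigned accordingly.
    """
    doc.validate()
    lines: list[str] = []
    line_starts: list[int] = []
    pos = 0
    tok_offsets: list[list[tuple[int, int]]] = []
    for sent in doc.sentences:
        if sent.text is not None and all(t.start >= 0 for t in sent.tokens):
            base = min(t.start for t in sent.tokens) if sent.tokens else 0
            line = sent.text
            offs = [(t.start - base + pos, t.end - base + pos) for t in sent.tokens]
        else:
            line = " ".join(sent.surfaces)
            offs = []
            cur = pos
            for t in sent.tokens:
                offs.append((cur, cur + len(t.surface)))
                cur += len(t.surface) + 1
        line_starts.append(pos)
        lines.append(line)
        tok_offsets.append(offs)
        pos += len(line) + 1
    txt = "\n".join(lines) + ("\n" if lines else "")

    a1_lines: list[str] = []
    a2_lines: list[str] = []
    rid = 0
    for si, sent in enumerate(doc.sentences):
        for e in sent.entities:
            lo, hi = e.span
            cs = tok_offsets[si][lo][0]
            ce = tok_offsets[si][hi - 1][1]
            a1_lines.append(f"{e.id}\t{e.etype} {cs} {ce}\t{txt[cs:ce]}")
        for r in sent.relations:
            rid += 1
            a2_lines.append(
                f"R{rid}\t{r.rtype} {agent_role}:{r.agent} {target_role}:{r.target}"
            )
    a1 = "\n".join(a1_lines) + ("\n" if a1_lines else "")
    a2 = "\n".join(a2_lines) + ("\n" if a2_lines else "")
    return txt, a1, a2


# ---------------------------------------------------------------------------
# Relation-type hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelationHierarchy:
    """A forest over relation-type names; ``parent`` maps child -> parent.

    ``is_ancestor(a, b)`` is a strict partial order: a type is never its own
    ancestor.
    """

    types: frozenset[str]
    parent: Mapping[str, str]

    def __post_init__(self) -> None:
        for child, par in self.parent.items():
            if child not in self.types:
                raise InvalidHierarchyError(f"unknown child type {child!r}")
            if par not in self.types:
                raise InvalidHierarchyError(
                    f"parent {par!r} of {child!r} is not a declared type"
                )
        # cycle check by walking every chain
        for t in self.types:
            seen = {t}
            cur = t
            while cur in self.parent:
                cur = self.parent[cur]
                if cur in seen:
                    raise InvalidHierarchyError(f"cycle through type {cur!r}")
                seen.add(cur)

    def ancestors(self, t: str) -> list[str]:
        out = []
        cur = t
        while cur in self.parent:
            cur = self.parent[cur]
            out.append(cur)
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        """True iff ``a`` is a strict (less specific) ancestor of ``b``."""
        return a in self.ancestors(b)


DEFAULT_TYPES = (
    "Inhibition",
    "Activation",
    "Requirement",
    "Binding",
    "Transcription",
    "Regulation",
)


def default_hierarchy() -> RelationHierarchy:
    """Regulation as the generic root, the other five types as its children."""
    return RelationHierarchy(
        types=frozenset(DEFAULT_TYPES),
        parent={t: "Regulation" for t in DEFAULT_TYPES if t != "Regulation"},
    )


def load_hierarchy(config) -> RelationHierarchy:
    """Load a hierarchy from a mapping, YAML/JSON text, a path or a stream.

    Expected shape::

        types: [Regulation, Inhibition, ...]
        parents: {Inhibition: Regulation, ...}
    """
    if isinstance(config, Mapping):
        data = config
    else:
        raw = _as_text(config)
        data = yaml.safe_load(raw)
    if not isinstance(data, Mapping) or "types" not in data:
        raise InvalidHierarchyError("hierarchy config must map 'types' (+ 'parents')")
    types = frozenset(data["types"])
    parents = dict(data.get("parents") or {})
    return RelationHierarchy(types=types, parent=parents)
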