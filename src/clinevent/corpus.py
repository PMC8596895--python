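"""Core domain types for clinical event detection corpora.

A corpus is a list of :class:`LabeledSentence` objects: pre-tokenized
sentences with one BIOES tag per token over the six clinical event types
(problem, test, treatment, evidential, occurrence, clinical_department).
This module provides the tag schema, the span<->tag codec, the preprocessing
steps applied to clinical text (sentence splitting/rejoining on break
punctuation, digit normalization, possessive splicing) and CoNLL-style
two-column file I/O.

Span coordinates are 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

__all__ = [
    "EVENT_TYPES",
    "EventSpan",
    "LabeledSentence",
    "TagSchema",
    "SchemaError",
    "encode_spans",
    "decode_tags",
    "split_and_rejoin",
    "normalize_tokens",
    "read_conll",
    "write_conll",
]

#: The six clinical event types, in canonical order.
EVENT_TYPES: tuple[str, ...] = (
    "problem",
    "test",
    "treatment",
    "evidential",
    "occurrence",
    "clinical_department",
)

_PREFIXES = ("B", "I", "E", "S")


class SchemaError(ValueError):
    """Raised for tags, spans or files that violate the BIOES schema."""


@dataclass(frozen=True, order=True)
class EventSpan:
    """A typed token interval, 0-based half-open — the unit of evaluation."""

    start: int
    end: int
    type: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise SchemaError(f"invalid span interval [{self.start}, {self.end})")

    def overlap(self, other: "EventSpan") -> int:
        """Number of tokens shared with `other` (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TagSchema:
    """Event-type vocabulary and the derived BIOES label vocabulary.

    The label order is deterministic given the type order: "O" first, then
    B/I/E/S for each type.  ``d_f`` (the CRF label count) is 4*|types| + 1.
    """

    types: tuple[str, ...] = EVENT_TYPES
    labels: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        self.types = tuple(self.types)
        self.labels = ("O",) + tuple(
            f"{p}-{t}" for t in self.types for p in _PREFIXES
        )

    @property
    def d_f(self) -> int:
        return len(self.labels)

    def label_index(self, tag: str) -> int:
        try:
            return self.labels.index(tag)
        except ValueError:
            raise SchemaError(f"unknown label {tag!r}") from None

    def validate_tags(self, tags: Sequence[str]) -> None:
        """Check strict BIOES grammar: I/E only continue a same-type B/I."""
        prev_prefix, prev_type = "O", None
        for i, tag in enumerate(tags):
            prefix, type_ = _parse_tag(tag, self)
            if prefix in ("I", "E"):
                if prev_prefix not in ("B", "I") or prev_type != type_:
                    raise SchemaError(
                        f"tag {tag!r} at position {i} does not continue a "
                        f"same-type B/I tag"
                    )
            if prev_prefix in ("B", "I") and (
                prefix not in ("I", "E") or type_ != prev_type
            ):
                raise SchemaError(
                    f"span of type {prev_type!r} left open before position {i}"
                )
            prev_prefix, prev_type = prefix, type_
        if prev_prefix in ("B", "I"):
            raise SchemaError("span left open at end of sentence")


def _parse_tag(tag: str, schema: TagSchema) -> tuple[str, str | None]:
    if tag == "O":
        return "O", None
    if len(tag) > 2 and tag[1] == "-" and tag[0] in _PREFIXES:
        type_ = tag[2:]
        if type_ in schema.types:
            return tag[0], type_
    raise SchemaError(f"unknown label {tag!r}")


@dataclass
class LabeledSentence:
    """Tokens plus aligned BIOES tags."""

    tokens: list[str]
    tags: list[str]

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise SchemaError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    def spans(self, schema: TagSchema | None = None,
              mode: Literal["strict", "forgiving"] = "strict") -> list[EventSpan]:
        return decode_tags(self.tags, mode=mode, schema=schema)

    def text(self) -> str:
        return " ".join(self.tokens)


def encode_spans(length: int, spans: Iterable[EventSpan],
                 schema: TagSchema | None = None) -> list[str]:
    """Render non-overlapping spans as a BIOES tag sequence of `length` tags.

    Single-token spans become ``S-type``; multi-token spans become
    ``B-…(I-…)E-…``; every other position is ``O``.
    """
    schema = schema or TagSchema()
    tags = ["O"] * length
    occupied = [False] * length
    for span in sorted(spans):
        if span.type not in schema.types:
            raise SchemaError(f"unknown event type in span {span}")
        if span.end > length:
            raise SchemaError(f"span {span} exceeds sentence length {length}")
        if any(occupied[span.start:span.end]):
            raise SchemaError(f"span {span} overlaps a previous span")
        for i in range(span.start, span.end):
            occupied[i] = True
        if span.end - span.start == 1:
            tags[span.start] = f"S-{span.type}"
        else:
            tags[span.start] = f"B-{span.type}"
            for i in range(span.start + 1, span.end - 1):
                tags[i] = f"I-{span.type}"
            tags[span.end - 1] = f"E-{span.type}"
    return tags


def decode_tags(tags: Sequence[str],
                mode: Literal["strict", "forgiving"] = "strict",
                schema: TagSchema | None = None) -> list[EventSpan]:
    """Recover typed spans from a BIOES tag sequence.

    strict
        Only well-formed groups (``S`` or ``B (I)* E`` of one type) become
        spans; ill-formed fragments are dropped.
    forgiving
        Every maximal run of same-type non-O tags becomes one span,
        regardless of its B/I/E/S decoration.  Needed to score the raw
        output of an untrained or CRF-free model, which may be ill-formed.
    """
    schema = schema or TagSchema()
    parsed = [_parse_tag(t, schema) for t in tags]
    spans: list[EventSpan] = []
    if mode == "forgiving":
        i = 0
        while i < len(parsed):
            prefix, type_ = parsed[i]
            if type_ is None:
                i += 1
                continue
            j = i + 1
            while j < len(parsed) and parsed[j][1] == type_:
                j += 1
            spans.append(EventSpan(i, j, type_))
            i = j
        return spans
    if mode != "strict":
        raise ValueError(f"unknown decode mode {mode!r}")
    i = 0
    while i < len(parsed):
        prefix, type_ = parsed[i]
        if prefix == "S":
            spans.append(EventSpan(i, i + 1, type_))
            i += 1
        elif prefix == "B":
            j = i + 1
            while j < len(parsed) and parsed[j] == ("I", type_):
                j += 1
            if j < len(parsed) and parsed[j] == ("E", type_):
                spans.append(EventSpan(i, j + 1, type_))
                i = j + 1
            else:
                i += 1  # unterminated B-group: drop
        else:
            i += 1
    return spans


def split_and_rejoin(tokens: Sequence[str], max_len: int,
                     break_puncts: frozenset[str] | set[str] = frozenset({",", ";"}),
                     ) -> list[list[str]]:
    """Split an over-long sentence at break punctuation and greedily rejoin.

    Long clinical sentences are cut immediately after each break-punctuation
    token, then adjacent fragments are re-merged left-to-right while the
    merged length stays within ``max_len``.  A fragment with no internal
    break punctuation that still exceeds ``max_len`` is hard-split at
    ``max_len`` (truncation would silently drop gold events).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    tokens = list(tokens)
    if not tokens:
        return []
    fragments: list[list[str]] = [[]]
    for tok in tokens:
        fragments[-1].append(tok)
        if tok in break_puncts:
            fragments.append([])
    if not fragments[-1]:
        fragments.pop()
    merged: list[list[str]] = []
    for frag in fragments:
        if merged and len(merged[-1]) + len(frag) <= max_len:
            merged[-1].extend(frag)
        else:
            merged.append(list(frag))
    out: list[list[str]] = []
    for seg in merged:
        while len(seg) > max_len:
            out.append(seg[:max_len])
            seg = seg[max_len:]
        if seg:
            out.append(seg)
    return out


_POSSESSIVES = ("'s", "’s")


def normalize_tokens(tokens: Sequence[str], tags: Sequence[str] | None = None):
    """Apply the clinical-text normalization rules.

    Every decimal digit character becomes "0" (dates, doses and measurements
    share one surface shape), and a token that is exactly a possessive
    marker ("'s") is spliced onto the preceding token.  When aligned tags
    are given, the spliced token must be "O" — splicing an event token would
    corrupt span alignment — and the merged token keeps the surviving
    token's tag.  Returns the token list, or ``(tokens, tags)`` when tags
    were provided.  Idempotent.
    """
    out_tokens: list[str] = []
    out_tags: list[str] | None = [] if tags is not None else None
    for i, tok in enumerate(tokens):
        tok = re.sub(r"\d", "0", tok)
        if tok in _POSSESSIVES and out_tokens:
            if tags is not None and tags[i] != "O":
                raise SchemaError(
                    f"possessive token at position {i} carries tag "
                    f"{tags[i]!r}; splicing would corrupt span alignment"
                )
            out_tokens[-1] += tok
            continue
        out_tokens.append(tok)
        if out_tags is not None:
            out_tags.append(tags[i])
    if out_tags is not None:
        return out_tokens, out_tags
    return out_tokens


def read_conll(path, schema: TagSchema | None = None,
               validate: bool = True) -> list[LabeledSentence]:
    """Read a two-column (token, tag) file; blank lines separate sentences.

    Tags are validated against the schema; errors report 1-based line
    numbers.  With ``validate=False`` only label-vocabulary membership is
    checked, not the BIOES grammar — needed to read raw model output, which
    may be ill-formed.
    """
    schema = schema or TagSchema()
    sentences: list[LabeledSentence] = []
    tokens: list[str] = []
    tags: list[str] = []
    start_line = 1
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            if tokens:
                _finish_sentence(tokens, tags, schema, sentences, start_line,
                                 path, validate)
                tokens, tags = [], []
            start_line = lineno + 1
            continue
        cols = line.split()
        if len(cols) != 2:
            raise SchemaError(
                f"{path}:{lineno}: expected 2 columns, got {len(cols)}: {line!r}"
            )
        tokens.append(cols[0])
        tags.append(cols[1])
    if tokens:
        _finish_sentence(tokens, tags, schema, sentences, start_line, path,
                         validate)
    return sentences


def _finish_sentence(tokens, tags, schema, sentences, start_line, path,
                     validate=True):
    try:
        if validate:
            schema.validate_tags(tags)
        else:
            for t in tags:
                _parse_tag(t, schema)
    except SchemaError as exc:
        raise SchemaError(f"{path}: sentence starting at line {start_line}: {exc}") from None
    sentences.append(LabeledSentence(list(tokens), list(tags)))


def write_conll(sentences: Iterable[LabeledSentence], path) -> None:
    """Write sentences in the canonical two-column format (token TAB tag)."""
    lines: list[str] = []
    for sent in sentences:
        for tok, tag in zip(sent.tokens, sent.tags):
            lines.append(f"{tok}\t{tag}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
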