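"""Label-preserving corpus expansion by priority-ordered lexical replacement.

Sequence-labeling corpora are expensive to annotate; generic text
augmentation (random swap/insert/delete) breaks token/tag alignment.  The
scheme implemented here replaces only *non-event* words (tag "O"), one-for-one,
with candidates drawn from a lexicon of five lexical relations.  Because
every substitution is a single token at a fixed position, the generated
sentence inherits the source tag sequence unchanged.

Candidates are scanned in a fixed priority order
``synonyms -> antonyms -> hypernyms -> hyponyms -> related_words`` and only
the first element of the first non-empty list is used, which keeps the
generated corpus size bounded and deterministic.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .corpus import LabeledSentence

__all__ = [
    "RELATIONS",
    "Lexicon",
    "AugmentationMode",
    "find_replaceable",
    "select_replacement",
    "augment_sentence",
    "augment_corpus",
]

#: Replacement relations in priority order.
RELATIONS: tuple[str, ...] = (
    "synonyms",
    "antonyms",
    "hypernyms",
    "hyponyms",
    "related_words",
)

_PUNCT = set(string.punctuation)


@dataclass
class Lexicon:
    """Per-word candidate-replacement lists in five lexical relations.

    Keys are lowercased; lookup is case-insensitive and the replacement is
    re-capitalized to match the original token.  List order is significant:
    "the first relevant word" is the first element in stored order, so the
    lexicon file fixes determinism.
    """

    entries: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self):
        clean: dict[str, dict[str, list[str]]] = {}
        for word, rels in self.entries.items():
            entry = {}
            for rel in RELATIONS:
                seen: list[str] = []
                for cand in rels.get(rel, []):
                    if cand not in seen:
                        seen.append(cand)
                entry[rel] = seen
            clean[word.lower()] = entry
        self.entries = clean

    def __contains__(self, word: str) -> bool:
        return word.lower() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, word: str) -> dict[str, list[str]]:
        return self.entries.get(word.lower(), {rel: [] for rel in RELATIONS})

    def has_candidates(self, word: str, exclude_antonyms: bool = False) -> bool:
        entry = self.get(word)
        return any(
            entry[rel] for rel in RELATIONS
            if not (exclude_antonyms and rel == "antonyms")
        )

    @classmethod
    def from_json(cls, path) -> "Lexicon":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.entries, indent=1, sort_keys=True), encoding="utf-8"
        )


def worked_example_lexicon() -> Lexicon:
    """The packaged fixture lexicon for the worked augmentation example."""
    path = Path(__file__).parent / "data" / "worked_example_lexicon.json"
    return Lexicon.from_json(path)


class AugmentationMode(str, Enum):
    """The three augmentation regimes.

    ALL replaces every replaceable word in one generated sentence;
    ALL_NO_ANT does the same after discarding antonym candidates;
    ONE_NO_ANT discards antonyms and emits one generated sentence per
    replaceable position, changing only that position.
    """

    ALL = "all"
    ALL_NO_ANT = "all_no_ant"
    ONE_NO_ANT = "one_no_ant"

    @property
    def exclude_antonyms(self) -> bool:
        return self is not AugmentationMode.ALL


def _is_candidate_token(token: str) -> bool:
    # tokens containing digits (dates, doses) or pure punctuation are never
    # replaced; substituting them would corrupt temporal expressions
    if any(ch.isdigit() for ch in token):
        return False
    if all(ch in _PUNCT for ch in token):
        return False
    return True


def find_replaceable(sentence: LabeledSentence, lexicon: Lexicon) -> list[int]:
    """Indices of non-event ("O"-tagged) tokens with lexicon candidates."""
    return [
        i
        for i, (tok, tag) in enumerate(zip(sentence.tokens, sentence.tags))
        if tag == "O"
        and _is_candidate_token(tok)
        and lexicon.has_candidates(tok)
    ]


def _match_case(replacement: str, source: str) -> str:
    if source[:1].isupper():
        return replacement[:1].upper() + replacement[1:]
    return replacement


def select_replacement(word: str, lexicon: Lexicon,
                       exclude_antonyms: bool = False) -> str | None:
    """First candidate of the first non-empty relation list, or None.

    Relations are scanned in priority order; antonyms are skipped when
    excluded.  The returned word mirrors the source word's initial
    capitalization.
    """
    entry = lexicon.get(word)
    for rel in RELATIONS:
        if exclude_antonyms and rel == "antonyms":
            continue
        if entry.get(rel):
            return _match_case(entry[rel][0], word)
    return None


def augment_sentence(sentence: LabeledSentence, lexicon: Lexicon,
                     mode: AugmentationMode) -> list[LabeledSentence]:
    """Generate new sentences from one source sentence.

    Every output shares the source's tag sequence exactly.  Outputs that
    differ from the source in zero tokens are suppressed.
    """
    mode = AugmentationMode(mode)
    indices = find_replaceable(sentence, lexicon)
    out: list[LabeledSentence] = []
    if mode is AugmentationMode.ONE_NO_ANT:
        for i in indices:
            repl = select_replacement(sentence.tokens[i], lexicon,
                                      exclude_antonyms=True)
            if repl is None or repl == sentence.tokens[i]:
                continue
            tokens = list(sentence.tokens)
            tokens[i] = repl
            out.append(LabeledSentence(tokens, list(sentence.tags)))
        return out
    tokens = list(sentence.tokens)
    changed = False
    for i in indices:
        repl = select_replacement(tokens[i], lexicon,
                                  exclude_antonyms=mode.exclude_antonyms)
        if repl is not None and repl != tokens[i]:
            tokens[i] = repl
            changed = True
    if changed:
        out.append(LabeledSentence(tokens, list(sentence.tags)))
    return out


def augment_corpus(corpus: list[LabeledSentence], lexicon: Lexicon,
                   mode: AugmentationMode, sample_fraction: float = 1.0,
                   seed: int = 0) -> list[LabeledSentence]:
    """Original corpus plus generated sentences, optionally subsampled.

    When ``sample_fraction < 1`` the *generated* sentences (originals are
    always kept) are subsampled uniformly without replacement, reproducibly
    under ``seed``.  Output order is originals first, then generated
    sentences in source order.
    """
    if not (0.0 < sample_fraction <= 1.0):
        raise ValueError(f"sample_fraction must be in (0, 1], got {sample_fraction}")
    generated: list[LabeledSentence] = []
    for sent in corpus:
        generated.extend(augment_sentence(sent, lexicon, mode))
    if sample_fraction < 1.0 and generated:
        rng = np.random.default_rng(seed)
        k = int(round(sample_fraction * len(generated)))
        keep = sorted(rng.choice(len(generated), size=k, replace=False))
        generated = [generated[i] for i in keep]
    return list(corpus) + generated
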