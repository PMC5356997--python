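"""Word segmentation and stop-word filtration for diagnosis strings.

Chinese clinical text carries no delimiters between words, so diagnosis
strings must be segmented into a word sequence before any token-level
similarity can be computed.  This module ships a deterministic forward
maximum-matching (FMM) segmenter over a user-supplied lexicon: at each
position the longest lexicon entry wins, and spans covered by no entry fall
back to single atomic units.

An *atom* is the smallest indivisible unit of the input: a single CJK (or
other non-Latin) character, or a maximal run of Latin letters/digits.  The
bundled fixtures transcribe Chinese characters as whitespace-separated
pinyin syllables, so in that transcription one syllable is one atom and a
lexicon entry such as "BING DU XING GAN YAN" spans five atoms, exactly as
the corresponding five-character Chinese word would.

Stop-word filtration removes connective words ("BAN"/with) but never
negation words ("BU BAN"/without), because dropping a negation flips the
clinical meaning of the diagnosis.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "Token",
    "TokenSequence",
    "SegmenterConfig",
    "normalize",
    "segment",
    "filter_words",
]

_ATOM_RE = re.compile(r"[0-9a-z]+|\S")


@lru_cache(maxsize=65536)
def normalize(text: str) -> str:
    """Unicode-NFC normalize and case-fold ``text``."""
    return unicodedata.normalize("NFC", text).casefold()


def _atomize(text: str) -> list[str]:
    """Split normalized text into atoms.

    Whitespace is a hard atom boundary; within a whitespace-delimited chunk,
    runs of ASCII alphanumerics form one atom and every other character is
    its own atom.
    """
    atoms: list[str] = []
    for chunk in text.split():
        atoms.extend(_ATOM_RE.findall(chunk))
    return atoms


def _join_atoms(atoms: Sequence[str]) -> str:
    # Pinyin/Latin atoms are re-joined with single spaces so the surface is
    # readable; runs of bare CJK characters are joined without separator,
    # matching how the word appears in the source text.
    if all(len(a) == 1 and not a.isascii() for a in atoms):
        return "".join(atoms)
    return " ".join(atoms)


@dataclass(frozen=True)
class Token:
    """One word unit of a segmented diagnosis string."""

    surface: str
    is_negation: bool = False

    def __post_init__(self) -> None:
        if not self.surface or self.surface != self.surface.strip():
            raise ValueError(f"invalid token surface: {self.surface!r}")


@dataclass(frozen=True)
class TokenSequence:
    """Ordered, filtered tokens of one diagnosis string."""

    tokens: tuple[Token, ...]
    source: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    def __getitem__(self, i: int) -> Token:
        return self.tokens[i]

    @property
    def surfaces(self) -> tuple[str, ...]:
        return tuple(t.surface for t in self.tokens)


@dataclass(frozen=True)
class SegmenterConfig:
    """Lexicon, stop-word and mode settings for the segmenter.

    ``negation_words`` may overlap ``stop_words``; negation always wins and
    such tokens survive filtration.  ``mode`` selects token-level (lexicon
    FMM) or character-level (one atom per token) segmentation.
    """

    lexicon: frozenset[str] = frozenset()
    stop_words: frozenset[str] = frozenset()
    negation_words: frozenset[str] = frozenset()
    mode: str = "token"

    def __post_init__(self) -> None:
        if self.mode not in ("token", "char"):
            raise ValueError(f"mode must be 'token' or 'char', got {self.mode!r}")
        if any(not e for e in self.lexicon):
            raise ValueError("lexicon entries must be non-empty")

    def normalized(self) -> "SegmenterConfig":
        return replace(
            self,
            lexicon=frozenset(normalize(e) for e in self.lexicon),
            stop_words=frozenset(normalize(e) for e in self.stop_words),
            negation_words=frozenset(normalize(e) for e in self.negation_words),
        )

    @classmethod
    def from_files(
        cls,
        lexicon_path: str | Path | None = None,
        stopwords_path: str | Path | None = None,
        mode: str = "token",
    ) -> "SegmenterConfig":
        """Load from plain-text files: one entry per line, ``#`` comments.

        In the stop-word file a line suffixed with a tab and ``NEG`` marks a
        negation word (exempt from removal).
        """
        lexicon: set[str] = set()
        stop: set[str] = set()
        neg: set[str] = set()
        if lexicon_path is not None:
            for line in _read_lines(lexicon_path):
                lexicon.add(line)
        if stopwords_path is not None:
            for line in _read_lines(stopwords_path):
                if "\t" in line:
                    word, flag = line.split("\t", 1)
                    word = word.strip()
                    if flag.strip().upper() == "NEG":
                        neg.add(word)
                    stop.add(word)
                else:
                    stop.add(line)
        return cls(
            lexicon=frozenset(lexicon),
            stop_words=frozenset(stop),
            negation_words=frozenset(neg),
            mode=mode,
        )


def _read_lines(path: str | Path) -> Iterator[str]:
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                yield line


def segment(text: str, config: SegmenterConfig) -> TokenSequence:
    """Segment ``text`` into a token sequence by forward maximum matching.

    The longest lexicon entry starting at the current atom wins; atoms
    covered by no entry are emitted as single-atom tokens.  Empty input
    yields an empty sequence.  In ``char`` mode every atom is a token.
    """
    config = config.normalized()
    norm = normalize(text)
    atoms = _atomize(norm)
    tokens: list[Token] = []
    if config.mode == "char" or not config.lexicon:
        tokens = [Token(a) for a in atoms]
        return TokenSequence(tuple(tokens), source=text)

    entries = {tuple(_atomize(e)) for e in config.lexicon}
    max_len = max((len(e) for e in entries), default=1)
    i = 0
    n = len(atoms)
    while i < n:
        matched = False
        for k in range(min(max_len, n - i), 1, -1):
            cand = tuple(atoms[i : i + k])
            if cand in entries:
                tokens.append(Token(_join_atoms(cand)))
                i += k
                matched = True
                break
        if not matched:
            tokens.append(Token(atoms[i]))
            i += 1
    return TokenSequence(tuple(tokens), source=text)


def filter_words(seq: TokenSequence, config: SegmenterConfig) -> TokenSequence:
    """Remove stop-word tokens, retaining and flagging negation words.

    A token listed in both ``stop_words`` and ``negation_words`` survives:
    negation wins, since removing "without" would silently turn "hepatitis A
    without hepatic coma" into its opposite.
    """
    config = config.normalized()
    out: list[Token] = []
    for tok in seq:
        if tok.surface in config.negation_words:
            out.append(Token(tok.surface, is_negation=True))
        elif tok.surface in config.stop_words:
            continue
        else:
            out.append(tok)
    return TokenSequence(tuple(out), source=seq.source)


def segment_and_filter(text: str, config: SegmenterConfig) -> TokenSequence:
    """Convenience composition of :func:`segment` and :func:`filter_words`."""
    return filter_words(segment(text, config), config)
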