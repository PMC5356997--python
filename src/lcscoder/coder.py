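"""End-to-end ICD-10 code assignment against a standard diagnosis library.

A Standard Diagnosis Library (SDL) is the reference list of standardized
diagnosis names, each carrying a six-character ICD-10 code such as
``B15.000``.  A free-text query diagnosis is segmented and filtered, scored
against every SDL entry with the chosen similarity measure, and the ranked
candidates are returned.  The similarity of the top candidate doubles as
the *confidence value*: above the policy threshold the code is emitted
automatically, below it the record is routed to a human coder.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable

from .lcs import semantic_lcs
from .ontology import TermOntology, EMPTY_ONTOLOGY
from .similarity import (
    SimilarityScore,
    bigram_similarity,
    lcs_similarity,
    tlcs_similarity,
    wlcs_similarity,
    word_match_similarity,
)
from .tokenizer import SegmenterConfig, TokenSequence, segment_and_filter

__all__ = [
    "CODE_PATTERN",
    "MEASURES",
    "SDLEntry",
    "StandardDiagnosisLibrary",
    "Candidate",
    "CodingResult",
    "SDLFormatError",
    "EmptyQueryError",
    "load_sdl",
    "build_sdl",
    "assign_code",
    "apply_confidence_policy",
]

CODE_PATTERN = re.compile(r"^[A-Z][0-9]{2}\.[0-9]{3}$")

#: Canonical measure names accepted throughout the package.
MEASURES = ("lcs", "tlcs", "wlcs", "word-match", "bigram")

_ALIASES = {
    "lcs": "lcs",
    "t-lcs": "tlcs",
    "tlcs": "tlcs",
    "w-lcs": "wlcs",
    "wlcs": "wlcs",
    "word-match": "word-match",
    "word_match": "word-match",
    "wordmatch": "word-match",
    "bigram": "bigram",
    "bigrams": "bigram",
}


def canonical_measure(name: str) -> str:
    key = name.strip().lower()
    if key not in _ALIASES:
        raise ValueError(f"unknown measure {name!r}; choose from {MEASURES}")
    return _ALIASES[key]


class SDLFormatError(ValueError):
    """Raised for malformed SDL files (bad codes, duplicates)."""


class EmptyQueryError(ValueError):
    """Query segmented and filtered down to zero tokens."""


@dataclass(frozen=True)
class SDLEntry:
    """One standard diagnosis: name, ICD-10 code, cached token sequence."""

    name: str
    code: str
    tokens: TokenSequence

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("diagnosis name must be non-empty")
        if not CODE_PATTERN.match(self.code):
            raise ValueError(f"invalid ICD-10 code {self.code!r}")


@dataclass(frozen=True)
class StandardDiagnosisLibrary:
    """Pre-tokenized SDL entries plus a code index."""

    entries: tuple[SDLEntry, ...]
    config: SegmenterConfig

    def __post_init__(self) -> None:
        object.__setattr__(self, "index", {e.code: e for e in self.entries})

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Candidate:
    code: str
    name: str
    confidence: float
    lcsl: int = 0
    lb: int = 0


@dataclass(frozen=True)
class CodingResult:
    """Ranked candidates for one query and the auto/manual routing decision."""

    query: str
    candidates: tuple[Candidate, ...]
    decision: str  # "auto_output" | "manual_review"
    measure: str = "wlcs"
    threshold: float = 0.803


def build_sdl(
    rows: Iterable[tuple[str, str]], config: SegmenterConfig
) -> StandardDiagnosisLibrary:
    """Build a library from (name, code) pairs, tokenizing each name once."""
    entries: list[SDLEntry] = []
    seen: set[str] = set()
    for name, code in rows:
        if code in seen:
            raise SDLFormatError(f"duplicate code {code!r}")
        seen.add(code)
        entries.append(SDLEntry(name=name, code=code, tokens=segment_and_filter(name, config)))
    if not entries:
        warnings.warn("standard diagnosis library is empty", stacklevel=2)
    return StandardDiagnosisLibrary(entries=tuple(entries), config=config)


def load_sdl(path: str | Path, config: SegmenterConfig) -> StandardDiagnosisLibrary:
    """Load a UTF-8 TSV file of ``name<TAB>code`` rows."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SDLFormatError(
                    f"{path}:{lineno}: expected name<TAB>code, got {len(parts)} fields"
                )
            name, code = parts[0].strip(), parts[1].strip()
            if not CODE_PATTERN.match(code):
                raise SDLFormatError(f"{path}:{lineno}: invalid ICD-10 code {code!r}")
            rows.append((name, code))
    try:
        return build_sdl(rows, config)
    except SDLFormatError as exc:
        raise SDLFormatError(f"{path}: {exc}") from exc


def _score(
    measure: str,
    query: TokenSequence,
    entry: TokenSequence,
    onto: TermOntology,
    epsilon: float,
    inclusive: bool,
) -> SimilarityScore:
    if measure in ("lcs", "tlcs", "wlcs"):
        lcsl = semantic_lcs(query, entry, onto, epsilon=epsilon, inclusive=inclusive).length
        la, lb = len(query), len(entry)
        if measure == "lcs":
            return lcs_similarity(lcsl, la, lb)
        if measure == "tlcs":
            return tlcs_similarity(lcsl, la, lb)
        return wlcs_similarity(lcsl, la, lb)
    if measure == "word-match":
        return word_match_similarity(query, entry)
    return bigram_similarity(query, entry)


def assign_code(
    query: str,
    sdl: StandardDiagnosisLibrary,
    onto: TermOntology = EMPTY_ONTOLOGY,
    measure: str = "wlcs",
    epsilon: float = 0.8,
    top_k: int = 5,
    inclusive: bool = False,
    confidence_threshold: float = 0.803,
) -> CodingResult:
    """Rank every SDL entry against ``query`` and keep the top ``top_k``.

    Ties on confidence are broken by larger LCS length, then shorter
    standard name (fewer unmatched tokens), then lexicographic code, making
    the ranking total and deterministic.
    """
    measure = canonical_measure(measure)
    if not sdl.entries:
        raise ValueError("standard diagnosis library is empty")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    qtokens = segment_and_filter(query, sdl.config)
    if len(qtokens) == 0:
        raise EmptyQueryError(f"query {query!r} has no tokens after filtration")

    scored: list[Candidate] = []
    for entry in sdl.entries:
        s = _score(measure, qtokens, entry.tokens, onto, epsilon, inclusive)
        scored.append(
            Candidate(
                code=entry.code,
                name=entry.name,
                confidence=s.value,
                lcsl=s.lcsl,
                lb=len(entry.tokens),
            )
        )
    scored.sort(key=lambda c: (-c.confidence, -c.lcsl, c.lb, c.code))
    result = CodingResult(
        query=query,
        candidates=tuple(scored[:top_k]),
        decision="manual_review",
        measure=measure,
        threshold=confidence_threshold,
    )
    return apply_confidence_policy(result, confidence_threshold)


def apply_confidence_policy(result: CodingResult, threshold: float) -> CodingResult:
    """Route to automatic output iff the top confidence exceeds ``threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    auto = bool(result.candidates) and result.candidates[0].confidence > threshold
    return replace(
        result,
        decision="auto_output" if auto else "manual_review",
        threshold=threshold,
    )
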