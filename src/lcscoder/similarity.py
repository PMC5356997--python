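"""String-level similarity measures built on the LCS length.

Three measures over the LCS length ``LCSL`` and the token-sequence lengths
``L(A)``, ``L(B)``:

* LCS-ratio:  Sim = LCSL / max(L(A), L(B))
* T-LCS:      Sim = 2 * LCSL / (L(A) + L(B))          ("twofold" LCS)
* W-LCS:      Sim = (LCSL + 1) * LCSL / (L(A) * LCSL + L(B)),  L(A) <= L(B)

W-LCS up-weights long common subsequences: for any admissible triple it is
at least T-LCS, which is at least the plain ratio, so more candidate pairs
clear a given decision threshold.  Two baselines are included for
comparison: all-or-nothing word matching and a Dice coefficient over
boundary-padded token bigrams.

Display rounding follows round-half-up to two decimals; raw values are kept
at full precision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .tokenizer import TokenSequence

__all__ = [
    "SimilarityScore",
    "UndefinedSimilarityError",
    "lcs_similarity",
    "tlcs_similarity",
    "wlcs_similarity",
    "word_match_similarity",
    "bigram_similarity",
    "round2",
]

_BOUNDARY_START = "\x02"
_BOUNDARY_END = "\x03"


class UndefinedSimilarityError(ValueError):
    """Similarity is undefined, e.g. both sequences are empty."""


@dataclass(frozen=True)
class SimilarityScore:
    """A similarity value together with the quantities that produced it."""

    value: float
    measure: str
    lcsl: int
    la: int
    lb: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"similarity out of [0, 1]: {self.value}")

    @property
    def rounded(self) -> float:
        return round2(self.value)


def round2(value: float) -> float:
    """Round half-up to two decimals (table display convention)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _check_triple(lcsl: int, la: int, lb: int) -> None:
    if lcsl < 0 or la < 0 or lb < 0:
        raise ValueError("lengths must be non-negative")
    if lcsl > min(la, lb):
        raise ValueError(f"LCSL {lcsl} exceeds min(L(A), L(B)) = {min(la, lb)}")


def lcs_similarity(lcsl: int, la: int, lb: int) -> SimilarityScore:
    """LCS-ratio: LCSL over the longer sequence length."""
    _check_triple(lcsl, la, lb)
    if max(la, lb) == 0:
        raise UndefinedSimilarityError("both sequences are empty")
    return SimilarityScore(lcsl / max(la, lb), "LCS", lcsl, la, lb)


def tlcs_similarity(lcsl: int, la: int, lb: int) -> SimilarityScore:
    """Twofold LCS: 2 * LCSL over the sum of the sequence lengths."""
    _check_triple(lcsl, la, lb)
    if la + lb == 0:
        raise UndefinedSimilarityError("both sequences are empty")
    return SimilarityScore(2.0 * lcsl / (la + lb), "T-LCS", lcsl, la, lb)


def wlcs_similarity(lcsl: int, la: int, lb: int) -> SimilarityScore:
    """Weighted LCS: (LCSL + 1) * LCSL / (L(A) * LCSL + L(B)) with L(A) <= L(B).

    Operands are canonicalized so the shorter length plays L(A).  LCSL = 0 is
    defined as similarity 0, continuing the other measures.
    """
    _check_triple(lcsl, la, lb)
    la, lb = min(la, lb), max(la, lb)
    if lb == 0:
        raise UndefinedSimilarityError("both sequences are empty")
    if lcsl == 0:
        return SimilarityScore(0.0, "W-LCS", lcsl, la, lb)
    value = (lcsl + 1) * lcsl / (la * lcsl + lb)
    return SimilarityScore(value, "W-LCS", lcsl, la, lb)


def word_match_similarity(X: TokenSequence | Sequence[str], Y: TokenSequence | Sequence[str]) -> SimilarityScore:
    """All-or-nothing baseline: 1 iff the token sequences are identical."""
    xs = tuple(X.surfaces if isinstance(X, TokenSequence) else X)
    ys = tuple(Y.surfaces if isinstance(Y, TokenSequence) else Y)
    equal = xs == ys
    return SimilarityScore(
        1.0 if equal else 0.0,
        "word-match",
        len(xs) if equal else 0,
        len(xs),
        len(ys),
    )


def _padded_bigrams(surfaces: Sequence[str]) -> Counter:
    padded = [_BOUNDARY_START, *surfaces, _BOUNDARY_END]
    return Counter(zip(padded, padded[1:]))


def bigram_similarity(X: TokenSequence | Sequence[str], Y: TokenSequence | Sequence[str]) -> SimilarityScore:
    """Dice coefficient over boundary-padded adjacent token pairs."""
    xs = tuple(X.surfaces if isinstance(X, TokenSequence) else X)
    ys = tuple(Y.surfaces if isinstance(Y, TokenSequence) else Y)
    bx, by = _padded_bigrams(xs), _padded_bigrams(ys)
    common = sum((bx & by).values())
    value = 2.0 * common / (sum(bx.values()) + sum(by.values()))
    return SimilarityScore(value, "bigram", common, len(xs), len(ys))
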