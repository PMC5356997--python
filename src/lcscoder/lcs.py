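"""Classic and semantic longest-common-subsequence dynamic programs.

The classic DP fills an (m+1) x (n+1) matrix ``c`` where ``c[i][j]`` is the
LCS length of the first ``i`` tokens of X and the first ``j`` tokens of Y:

    c[i][j] = 0                                if i = 0 or j = 0
    c[i][j] = c[i-1][j-1] + 1                  if a_i matches b_j
    c[i][j] = max(c[i-1][j], c[i][j-1])        otherwise

The semantic variant replaces surface equality in the match test with a
threshold on the pairwise token similarity: tokens match when
``sim(a_i, b_j) > epsilon`` (strict by default; an inclusive ``>=`` mode is
available).  With an empty ontology and the character fallback off, the
similarity is the exact-match indicator and the semantic DP reduces to the
classic one for any epsilon < 1.

``brute_force_lcs`` enumerates subsequences directly and exists purely as a
test oracle; it refuses inputs longer than 12 tokens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .ontology import TermOntology, EMPTY_ONTOLOGY, token_similarity
from .tokenizer import Token, TokenSequence

__all__ = ["LCSResult", "classic_lcs", "semantic_lcs", "brute_force_lcs"]

BRUTE_FORCE_CAP = 12


@dataclass(frozen=True)
class LCSResult:
    """LCS length, the DP matrix, and one optimal alignment path."""

    length: int
    matrix: tuple[tuple[int, ...], ...]
    matched_pairs: tuple[tuple[int, int], ...]


def _surfaces(seq: Sequence) -> list[str]:
    out = []
    for item in seq:
        if isinstance(item, Token):
            out.append(item.surface)
        elif isinstance(item, str):
            out.append(item)
        else:
            raise TypeError(f"expected Token or str, got {type(item).__name__}")
    return out


def _lcs_dp(xs: list[str], ys: list[str], match: Callable[[str, str], bool]) -> LCSResult:
    m, n = len(xs), len(ys)
    c = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        row, prev = c[i], c[i - 1]
        for j in range(1, n + 1):
            if match(xs[i - 1], ys[j - 1]):
                row[j] = prev[j - 1] + 1
            else:
                row[j] = prev[j] if prev[j] >= row[j - 1] else row[j - 1]
    # Traceback, preferring diagonal, then up, then left: deterministic pairs.
    pairs: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 and j > 0:
        if match(xs[i - 1], ys[j - 1]) and c[i][j] == c[i - 1][j - 1] + 1:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif c[i - 1][j] >= c[i][j - 1]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return LCSResult(
        length=c[m][n],
        matrix=tuple(tuple(row) for row in c),
        matched_pairs=tuple(pairs),
    )


def classic_lcs(X: TokenSequence | Sequence, Y: TokenSequence | Sequence) -> LCSResult:
    """LCS under exact (normalized) surface equality."""
    return _lcs_dp(_surfaces(X), _surfaces(Y), lambda a, b: a == b)


def semantic_lcs(
    X: TokenSequence | Sequence,
    Y: TokenSequence | Sequence,
    onto: TermOntology = EMPTY_ONTOLOGY,
    epsilon: float = 0.8,
    inclusive: bool = False,
) -> LCSResult:
    """LCS where tokens match when their similarity exceeds ``epsilon``.

    ``inclusive=True`` switches the threshold test from strict ``>`` to
    ``>=``.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    if inclusive:
        match = lambda a, b: token_similarity(a, b, onto) >= epsilon
    else:
        match = lambda a, b: token_similarity(a, b, onto) > epsilon
    return _lcs_dp(_surfaces(X), _surfaces(Y), match)


def brute_force_lcs(
    X: TokenSequence | Sequence,
    Y: TokenSequence | Sequence,
    match: Callable[[str, str], bool] | None = None,
) -> int:
    """Test oracle: maximum common-subsequence length by enumeration.

    Enumerates every subsequence of X (by index subset, longest first) and
    greedily tests whether it can be matched inside Y under the pairwise
    predicate.  Greedy leftmost matching is exact here because the predicate
    depends only on the element pair, so any witness alignment can be shifted
    left position by position.
    """
    xs, ys = _surfaces(X), _surfaces(Y)
    if len(xs) > BRUTE_FORCE_CAP or len(ys) > BRUTE_FORCE_CAP:
        raise ValueError(
            f"brute_force_lcs is capped at {BRUTE_FORCE_CAP} tokens per sequence"
        )
    if match is None:
        match = lambda a, b: a == b
    m = len(xs)
    subsets = sorted(range(1 << m), key=lambda s: -bin(s).count("1"))
    for s in subsets:
        pattern = [xs[i] for i in range(m) if s >> i & 1]
        j = 0
        ok = True
        for p in pattern:
            while j < len(ys) and not match(p, ys[j]):
                j += 1
            if j == len(ys):
                ok = False
                break
            j += 1
        if ok:
            return len(pattern)
    return 0
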