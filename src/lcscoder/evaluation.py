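"""Precision / recall / F-score evaluation and threshold sweeps.

Evaluation follows the retrieval framing: a prediction matching the gold
code is a true positive, a differing prediction a false positive, and an
abstention (the confidence policy routing a record to manual review) a
false negative — the relevant record was not retrieved.  Evaluation is
top-1: exactly one code is scored per query.

    precision = tp / (tp + fp)
    recall    = tp / (tp + fn)
    F-score   = 2 * precision * recall / (precision + recall)

The threshold sweep re-applies the confidence policy at each threshold on
cached rankings, reporting the F-score and the *coverage* (fraction of
queries auto-coded).  Raising the threshold can only turn auto-coded
queries into abstentions, so coverage is non-increasing — the trade-off a
deployment tunes when choosing its operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .coder import StandardDiagnosisLibrary, assign_code
from .ontology import TermOntology, EMPTY_ONTOLOGY

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "score_predictions",
    "precision_recall_fscore",
    "threshold_sweep",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class EvaluationReport:
    counts: ConfusionCounts
    precision: float
    recall: float
    fscore: float
    threshold: float = 0.0
    coverage: float = 1.0
    measure: str = ""


def score_predictions(
    predictions: Iterable[tuple[str, str | None]],
    gold: Mapping[str, str],
) -> ConfusionCounts:
    """Count tp/fp/fn for top-1 predictions; ``None`` marks an abstention."""
    tp = fp = fn = 0
    for query, predicted in predictions:
        if query not in gold:
            raise KeyError(f"query not in gold standard: {query!r}")
        if predicted is None:
            fn += 1
        elif predicted == gold[query]:
            tp += 1
        else:
            fp += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def precision_recall_fscore(
    counts: ConfusionCounts, threshold: float = 0.0, coverage: float = 1.0, measure: str = ""
) -> EvaluationReport:
    """Compute the three metrics; degenerate zero denominators yield 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp + fn == 0:
        raise ValueError("all counts are zero: metrics undefined")
    if tp + fp == 0:
        warnings.warn("no predictions made: precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    fscore = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvaluationReport(
        counts=counts,
        precision=precision,
        recall=recall,
        fscore=fscore,
        threshold=threshold,
        coverage=coverage,
        measure=measure,
    )


def threshold_sweep(
    queries: Sequence[tuple[str, str]],
    sdl: StandardDiagnosisLibrary,
    onto: TermOntology = EMPTY_ONTOLOGY,
    measure: str = "wlcs",
    thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    epsilon: float = 0.8,
    inclusive: bool = False,
) -> list[EvaluationReport]:
    """One report per confidence threshold over (query, gold_code) pairs.

    Each query is ranked once; the policy is then re-applied per threshold.
    """
    if not queries:
        raise ValueError("empty query set")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    tops: list[tuple[str, str, float]] = []
    for query, gold_code in queries:
        result = assign_code(
            query, sdl, onto, measure=measure, epsilon=epsilon, top_k=1, inclusive=inclusive
        )
        top = result.candidates[0]
        tops.append((query, top.code, top.confidence))

    gold = {q: g for q, g in queries}
    reports: list[EvaluationReport] = []
    for thr in thresholds:
        preds: list[tuple[str, str | None]] = []
        auto = 0
        for query, code, conf in tops:
            if conf > thr:
                preds.append((query, code))
                auto += 1
            else:
                preds.append((query, None))
        counts = score_predictions(preds, gold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports.append(
                precision_recall_fscore(
                    counts, threshold=thr, coverage=auto / len(tops), measure=measure
                )
            )
    return reports
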