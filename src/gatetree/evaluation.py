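"""F-score evaluation of automated gating against manual gating.

Per-type precision, recall and F (harmonic mean), aggregated either weighted
by population size (``Σ (|c_i|/N)·F_i``) or unweighted (macro mean), with or
without the ungated label.  When ungated cells are excluded, cells whose
*truth* label is ungated are dropped from the evaluation entirely before any
counting, matching evaluation on manually gated cells only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sample import DEFAULT_UNGATED

__all__ = [
    "TypeScore",
    "EvaluationReport",
    "type_f_score",
    "aggregate_f",
    "evaluate",
]


def _as_labels(x) -> np.ndarray:
    labels = getattr(x, "labels", x)
    return np.asarray(labels, dtype=object)


def _f_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


@dataclass(frozen=True)
class TypeScore:
    cell_type: str
    precision: float
    recall: float
    f_score: float
    n_truth: int
    n_predicted: int
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class EvaluationReport:
    """Per-type and aggregate gating scores for one truth/prediction pair."""

    per_type: tuple[TypeScore, ...]
    weighted_f: float
    macro_f: float
    include_ungated: bool
    n_cells: int
    ungated_sentinel: str = DEFAULT_UNGATED

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cell_type": s.cell_type,
                "n_cells": s.n_truth,
                "precision": s.precision,
                "recall": s.recall,
                "f_score": s.f_score,
            }
            for s in self.per_type
        ]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            f"evaluation ({'with' if self.include_ungated else 'without'} ungated), "
            f"N = {self.n_cells}",
        ]
        for s in self.per_type:
            lines.append(
                f"  {s.cell_type}: precision {s.precision:.4f}, "
                f"recall {s.recall:.4f}, F {s.f_score:.4f} (n = {s.n_truth})"
            )
        lines.append(f"  weighted F: {self.weighted_f:.4f}")
        lines.append(f"  unweighted (macro) F: {self.macro_f:.4f}")
        return "\n".join(lines)


def type_f_score(truth, predicted, cell_type: str) -> tuple[float, float, float]:
    """Precision, recall and F for one cell type on raw label vectors.

    Precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R) with the
    0-when-degenerate convention.  A type absent from both truth and
    prediction has no defined score and raises.
    """
    t = _as_labels(truth)
    p = _as_labels(predicted)
    if t.shape != p.shape:
        raise ValueError("truth and prediction must have equal length")
    in_t = t == cell_type
    in_p = p == cell_type
    if not in_t.any() and not in_p.any():
        raise ValueError(
            f"score undefined: type {cell_type!r} absent from both truth and prediction"
        )
    tp = int((in_t & in_p).sum())
    fp = int((~in_t & in_p).sum())
    fn = int((in_t & ~in_p).sum())
    return _f_from_counts(tp, fp, fn)


def evaluate(
    truth,
    predicted,
    include_ungated: bool = True,
    ungated_sentinel: str = DEFAULT_UNGATED,
    known_types=None,
) -> EvaluationReport:
    """Score a prediction against manual-gating truth.

    The evaluated type set C is the set of labels present in the truth
    (including the sentinel only when ``include_ungated``); types absent from
    the truth carry no population weight and are excluded from aggregates.
    ``known_types``, when given, makes unknown predicted type names an error.
    """
    t = _as_labels(truth)
    p = _as_labels(predicted)
    if t.shape != p.shape:
        raise ValueError(
            f"label vectors differ in length: {t.shape[0]} vs {p.shape[0]}"
        )
    if known_types is not None:
        allowed = set(known_types) | {ungated_sentinel}
        unknown = sorted(set(p.astype(str)) - allowed)
        if unknown:
            raise ValueError(f"unknown cell types in prediction: {unknown}")
    if not include_ungated:
        keep = t != ungated_sentinel
        t, p = t[keep], p[keep]
    n = t.shape[0]
    types = sorted(set(t.astype(str)))
    if not types:
        raise ValueError("no cell types to evaluate (empty included type set)")
    scores = []
    for ct in types:
        in_t = t == ct
        in_p = p == ct
        tp = int((in_t & in_p).sum())
        fp = int((~in_t & in_p).sum())
        fn = int((in_t & ~in_p).sum())
        precision, recall, f = _f_from_counts(tp, fp, fn)
        scores.append(
            TypeScore(
                cell_type=ct,
                precision=precision,
                recall=recall,
                f_score=f,
                n_truth=int(in_t.sum()),
                n_predicted=int(in_p.sum()),
                tp=tp,
                fp=fp,
                fn=fn,
            )
        )
    weighted = float(sum(s.n_truth * s.f_score for s in scores) / n)
    macro = float(np.mean([s.f_score for s in scores]))
    return EvaluationReport(
        per_type=tuple(scores),
        weighted_f=weighted,
        macro_f=macro,
        include_ungated=include_ungated,
        n_cells=n,
        ungated_sentinel=ungated_sentinel,
    )


def aggregate_f(
    truth,
    predicted,
    include_ungated: bool = True,
    weighted: bool = True,
    ungated_sentinel: str = DEFAULT_UNGATED,
) -> float:
    """Population-weighted or macro F over the included cell types."""
    report = evaluate(
        truth, predicted, include_ungated=include_ungated,
        ungated_sentinel=ungated_sentinel,
    )
    return report.weighted_f if weighted else report.macro_f
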