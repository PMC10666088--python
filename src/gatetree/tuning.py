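"""Decision-boundary fine-tuning, reclassification and drift iteration.

Marker identities in a gating rule are assumed universal across biologically
relevant samples; only the thresholds shift with batch effects.  Each rule's
thresholds are therefore re-derived on the new sample: starting from the
tentative cell-type centroid (assumed inside the boundaries), the admitted
region is expanded stepwise along each condition's marker, and the expansion
halts once a step introduces more cells of other tentative labels than of
the rule's own type, or once the introduced population falls below a small
fraction (default 1%) of the densest point within the current boundaries.

After all rules are tuned, every cell is reclassified against every tuned
rule; cells matching no rule stay ungated, and cells matching several rules
go to the rule with the lowest impurity in terms of tentative labels.  If
the majority of reassigned-cell centroids deviate from the reference
centroids, batch effects are assumed and the whole procedure repeats with
the new centroids and tuned rules in place of the reference ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .labeling import (
    PROV_RECLASSIFIED,
    PROV_UNGATED,
    LabelVector,
    assign_tentative,
    tree_only_label,
)
from .params import HyperParams
from .sample import CentroidSet, ExpressionSample, SampleError
from .trees import GREATER, GatingRule, MarkerCondition

logger = logging.getLogger(__name__)

__all__ = [
    "TunedRule",
    "tune_rule",
    "reclassify",
    "centroid_drift",
    "GatingOutcome",
    "run_gating",
    "gate_sample",
]


@dataclass(frozen=True)
class TunedRule:
    """A gating rule with per-condition thresholds re-derived on a new sample."""

    base: GatingRule
    thresholds: tuple[float, ...]
    impurity: float  # fraction of cells in the tuned region with another tentative label

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.base.conditions):
            raise ValueError("one tuned threshold per condition required")

    @property
    def cell_type(self) -> str:
        return self.base.cell_type

    @property
    def conditions(self) -> tuple[MarkerCondition, ...]:
        return tuple(
            replace(c, threshold=t)
            for c, t in zip(self.base.conditions, self.thresholds)
        )

    def mask(self, sample: ExpressionSample) -> np.ndarray:
        out = np.ones(sample.n_cells, dtype=bool)
        for cond in self.conditions:
            out &= cond.admits(sample.marker_column(cond.marker))
        return out

    def as_rule(self) -> GatingRule:
        return replace(self.base, conditions=self.conditions)


def _region_mask(
    sample: ExpressionSample,
    conditions: Sequence[MarkerCondition],
    thresholds: Sequence[float],
    skip: int | None = None,
) -> np.ndarray:
    out = np.ones(sample.n_cells, dtype=bool)
    for j, cond in enumerate(conditions):
        if j == skip:
            continue
        col = sample.marker_column(cond.marker)
        out &= col > thresholds[j] if cond.direction == GREATER else col <= thresholds[j]
    return out


def _sweep_threshold(
    x: np.ndarray,
    is_positive: np.ndarray,
    start: float,
    direction: str,
    lo: float,
    hi: float,
    params: HyperParams,
) -> float:
    """Expand one condition's threshold from the tentative centroid outward.

    ``x`` holds the tuned marker's values for cells satisfying the rule's
    other conditions.  Steps are ``(hi - lo) / sweep_bins`` wide; a step is
    accepted while the newly admitted cells contain at least as many
    positives (tentative label = rule type) as negatives and are not a
    negligible fraction of the densest point inside the current boundaries.
    The first step is always taken so the tuned region strictly contains the
    tentative centroid.
    """
    step = (hi - lo) / params.sweep_bins
    if step <= 0 or x.size == 0:
        return start
    sign = -1.0 if direction == GREATER else 1.0
    # distance from the start, in steps, along the expansion direction
    r = (start - x) / step if direction == GREATER else (x - start) / step
    if direction == GREATER:
        initially_admitted = r < 0  # x > start
        n_steps = max(1, int(math.ceil((start - lo) / step)) + 1)
    else:
        initially_admitted = r <= 0  # x <= start
        n_steps = max(1, int(math.ceil((hi - start) / step)) + 1)
    # step k (k >= 1) admits cells with r in [k-1, k) for GREATER
    # and r in (k-1, k] for AT_MOST
    out = ~initially_admitted
    if direction == GREATER:
        kbin = np.floor(r[out]).astype(int) + 1
    else:
        kbin = np.ceil(r[out]).astype(int)
    kbin = np.clip(kbin, 1, n_steps)
    pos_counts = np.bincount(kbin[is_positive[out]], minlength=n_steps + 1)
    all_counts = np.bincount(kbin, minlength=n_steps + 1)

    # densest point within the current boundaries, on the same step grid
    densest = 0.0
    if initially_admitted.any():
        inner = np.floor(np.abs(r[initially_admitted])).astype(int)
        densest = float(np.bincount(inner).max())

    # Expansion ends at the furthest step that still introduces a
    # positive-dominated, non-negligible population; interior sparse lulls do
    # not pin the boundary, but no step beyond the last acceptable one is
    # taken (so opposing masses and empty space bound the region).  The first
    # step is always acceptable (centroid containment).
    accepted = 1
    densest = max(densest, float(all_counts[1]))
    for k in range(2, n_steps + 1):
        tot = int(all_counts[k])
        pos = int(pos_counts[k])
        neg = tot - pos
        if pos >= neg and tot >= max(1.0, params.density_stop_fraction * densest):
            accepted = k
        densest = max(densest, float(tot))
    return start + sign * step * accepted


def tune_rule(
    rule: GatingRule,
    sample: ExpressionSample,
    tentative: LabelVector,
    params: HyperParams | None = None,
    reference_centroid: np.ndarray | None = None,
) -> TunedRule:
    """Re-derive a rule's thresholds against the tentative labels of a sample.

    Conditions are tuned sequentially in root-to-leaf order, one full pass;
    each 1-D sweep runs over cells satisfying all *other* (current)
    conditions.

    When the rule's reference centroid is supplied, the sweep counts a
    tentatively ungated cell as a positive if it lies inside the rule's
    *centroid-translated* region (every threshold displaced by the tentative
    centroid's offset from the reference centroid).  Under a batch shift the
    cells of the type that slipped outside the reference boundaries are
    tentatively ungated and sit directly beyond the old threshold; counting
    them as negatives would pin every boundary at its reference position, so
    the reference rule carried to the tentative centroid's frame -- the
    centroid is assumed to lie within the boundaries -- decides which ungated
    cells the expansion may absorb.  Cells of other tentative types always
    count as negatives.

    A rule whose type has no tentative cells is returned untuned with a
    logged warning (the type may be absent from this sample).
    """
    params = params or HyperParams()
    if len(tentative) != sample.n_cells:
        raise SampleError("tentative labels and sample must have equal length")
    positives = tentative.labels == rule.cell_type
    thresholds = [c.threshold for c in rule.conditions]
    if not positives.any():
        logger.warning(
            "no tentative cells of type %r; rule returned untuned", rule.cell_type
        )
        region = _region_mask(sample, rule.conditions, thresholds)
        impurity = float((~positives[region]).mean()) if region.any() else 0.0
        return TunedRule(rule, tuple(thresholds), impurity)

    centroid = sample.matrix[positives].mean(axis=0)
    sweep_positives = positives
    if reference_centroid is not None:
        reference_centroid = np.asarray(reference_centroid, dtype=float)
        translated = [
            c.threshold
            + centroid[sample.marker_index(c.marker)]
            - reference_centroid[sample.marker_index(c.marker)]
            for c in rule.conditions
        ]
        in_translated = _region_mask(sample, rule.conditions, translated)
        ungated = tentative.labels == tentative.ungated_sentinel
        sweep_positives = positives | (ungated & in_translated)

    for k, cond in enumerate(rule.conditions):
        others = _region_mask(sample, rule.conditions, thresholds, skip=k)
        col = sample.marker_column(cond.marker)
        lo, hi = float(col.min()), float(col.max())
        thresholds[k] = _sweep_threshold(
            col[others],
            sweep_positives[others],
            start=float(centroid[sample.marker_index(cond.marker)]),
            direction=cond.direction,
            lo=lo,
            hi=hi,
            params=params,
        )
    region = _region_mask(sample, rule.conditions, thresholds)
    impurity = float((~positives[region]).mean()) if region.any() else 0.0
    return TunedRule(rule, tuple(thresholds), impurity)


def reclassify(
    tuned_rules: Sequence[TunedRule],
    sample: ExpressionSample,
    tentative: LabelVector,
) -> LabelVector:
    """Assign every cell with the tuned rules; multi-matches go to lowest impurity.

    Cells matching no tuned rule are ungated.  Impurity ties break to the
    first rule in (cell-type sorted) rule order.
    """
    sentinel = tentative.ungated_sentinel
    rules = sorted(tuned_rules, key=lambda r: r.cell_type)
    types = np.asarray([r.cell_type for r in rules], dtype=object)
    M = np.column_stack([r.mask(sample) for r in rules])
    imps = np.asarray([r.impurity for r in rules], dtype=float)
    matched = M.any(axis=1)
    pick = np.argmin(np.where(M, imps[None, :], np.inf), axis=1)
    labels = np.where(matched, types[pick], sentinel).astype(object)
    prov = np.where(matched, PROV_RECLASSIFIED, PROV_UNGATED).astype(object)
    return LabelVector(labels, prov, ungated_sentinel=sentinel)


def centroid_drift(
    new_centroids: CentroidSet,
    reference_centroids: CentroidSet,
    params: HyperParams | None = None,
) -> bool:
    """True iff a strict majority of types moved more than ``drift_threshold``."""
    params = params or HyperParams()
    if new_centroids.types != reference_centroids.types:
        raise SampleError(
            f"centroid type sets differ: {new_centroids.types} vs "
            f"{reference_centroids.types}"
        )
    disp = np.linalg.norm(
        new_centroids.as_matrix() - reference_centroids.as_matrix(), axis=1
    )
    return int((disp > params.drift_threshold).sum()) * 2 > len(disp)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingOutcome:
    """Result of gating one sample: final labels plus tuning diagnostics."""

    labels: LabelVector
    iterations: int
    converged: bool
    tuned_rules: tuple[TunedRule, ...]
    final_centroids: CentroidSet
    tuned: bool

    def report(self) -> str:
        lines = [
            "gating report",
            f"  refinement iterations: {self.iterations}"
            + ("" if self.converged else " (iteration cap reached with drift)"),
            f"  boundary tuning: {'on' if self.tuned else 'off'}",
            "  assigned counts:",
        ]
        for t, n in sorted(self.labels.counts().items()):
            lines.append(f"    {t}: {n}")
        if self.tuned:
            lines.append("  tuned thresholds (original -> tuned, impurity):")
            for tr in self.tuned_rules:
                conds = ", ".join(
                    f"{c.marker} {c.direction} {c.threshold:.4f} -> {t:.4f}"
                    for c, t in zip(tr.base.conditions, tr.thresholds)
                )
                lines.append(f"    {tr.cell_type}: {conds} (impurity {tr.impurity:.4f})")
        return "\n".join(lines)


def _assigned_centroids(
    sample: ExpressionSample,
    labels: LabelVector,
    previous: CentroidSet,
) -> CentroidSet:
    """Centroids of the newly assigned cells; empty types keep their previous centroid."""
    cents = {}
    for t in previous.types:
        mask = labels.labels == t
        cents[t] = sample.matrix[mask].mean(axis=0) if mask.any() else previous[t]
    return CentroidSet(marker_names=previous.marker_names, centroids=cents)


def run_gating(model, sample: ExpressionSample, tune: bool = True) -> GatingOutcome:
    """Gate a sample end to end: tentative labels, tuning, reclassification,
    and centroid-drift refinement.  Fully deterministic.
    """
    params: HyperParams = model.params
    aligned = model.prepare(sample)
    rules: tuple[GatingRule, ...] = tuple(model.rules)
    centroids: CentroidSet = model.centroids
    sentinel: str = model.ungated_sentinel

    if not tune:
        labels = tree_only_label(rules, centroids, aligned, sentinel)
        untouched = tuple(
            TunedRule(r, tuple(c.threshold for c in r.conditions), 0.0) for r in rules
        )
        return GatingOutcome(
            labels=labels,
            iterations=1,
            converged=True,
            tuned_rules=untouched,
            final_centroids=centroids,
            tuned=False,
        )

    labels: LabelVector | None = None
    tuned: tuple[TunedRule, ...] = ()
    drifted = False
    iteration = 0
    for iteration in range(1, params.max_iterations + 1):
        tentative = assign_tentative(rules, centroids, aligned, params, sentinel)
        tuned = tuple(
            tune_rule(r, aligned, tentative, params, centroids[r.cell_type])
            for r in rules
        )
        labels = reclassify(tuned, aligned, tentative)
        new_centroids = _assigned_centroids(aligned, labels, centroids)
        drifted = centroid_drift(new_centroids, centroids, params)
        rules = tuple(tr.as_rule() for tr in tuned)
        centroids = new_centroids
        if not drifted:
            break
    if drifted:
        logger.warning(
            "refinement iteration cap (%d) reached with centroid drift still "
            "present; returning last labeling",
            params.max_iterations,
        )
    return GatingOutcome(
        labels=labels,
        iterations=iteration,
        converged=not drifted,
        tuned_rules=tuned,
        final_centroids=centroids,
        tuned=True,
    )


def gate_sample(model, sample: ExpressionSample, tune: bool = True) -> LabelVector:
    """Label every cell of a new sample with the full tuned pipeline."""
    return run_gating(model, sample, tune=tune).labels
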