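"""One-vs-rest gating trees: entropy splitting and rule extraction.

Each gated cell type gets its own binary decision tree separating that type
(Target) from the remaining gated cell types (Other); ungated reference cells
take no part in training.  Splits maximise the base-2 information gain over
midpoint thresholds, and the tree always descends into the target-enriched
child, so the non-followed branches are immediate rest-leaves and the tree
collapses to a single root-to-leaf conjunction of marker threshold tests -- a
gating rule directly comparable to one arm of a manual gating hierarchy.

Growth stops when the best split's information gain is insignificant or when
descending would retain too small a fraction of the Target population; the
resulting leaf must keep more than ``target_retention`` (default 90%) of all
Target cells and be characterised by at least two distinct markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .params import HyperParams
from .sample import ExpressionSample

__all__ = [
    "GREATER",
    "AT_MOST",
    "MarkerCondition",
    "GatingRule",
    "TreeTrainingError",
    "shannon_entropy",
    "entropy_change",
    "SplitCandidate",
    "best_split",
    "train_cell_type_tree",
]

GREATER = ">"
AT_MOST = "<="


class TreeTrainingError(ValueError):
    """No gating rule satisfying the leaf constraints could be trained."""


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------

def _binary_entropy(p: np.ndarray) -> np.ndarray:
    """Vectorised base-2 binary entropy with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = (p > 0) & (p < 1)
        q = p[inner]
        out[inner] = -(q * np.log2(q) + (1 - q) * np.log2(1 - q))
    return out


def shannon_entropy(p: float) -> float:
    """Base-2 Shannon entropy of a binary Target/Other mixture.

    ``p`` is the proportion of Target cells at a node.  H(0) = H(1) = 0,
    H(0.5) = 1, and H is symmetric about 0.5.
    """
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion must lie in [0, 1], got {p}")
    return float(_binary_entropy(np.asarray(p)))


def entropy_change(
    parent_p: float, left_p: float, right_p: float, left_weight: float
) -> float:
    """Information gain of a binary split.

    ``ΔH = H(parent_p) − [w·H(left_p) + (1−w)·H(right_p)]`` where ``w`` is the
    fraction of the parent's cells sent to the left child.  The child target
    proportions must recombine to the parent's (a physically consistent
    split), in which case the gain is non-negative by concavity of H.
    """
    if not 0.0 <= left_weight <= 1.0:
        raise ValueError(f"left_weight must lie in [0, 1], got {left_weight}")
    recombined = left_weight * left_p + (1.0 - left_weight) * right_p
    if not math.isclose(recombined, parent_p, rel_tol=0.0, abs_tol=1e-9):
        raise ValueError(
            "inconsistent split: weighted child target proportions "
            f"({recombined:.6g}) do not recombine to the parent's ({parent_p:.6g})"
        )
    return (
        shannon_entropy(parent_p)
        - left_weight * shannon_entropy(left_p)
        - (1.0 - left_weight) * shannon_entropy(right_p)
    )


# ---------------------------------------------------------------------------
# Conditions and rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerCondition:
    """One threshold test on one marker (in arcsinh units)."""

    marker: str
    direction: str  # GREATER admits x > threshold, AT_MOST admits x <= threshold
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in (GREATER, AT_MOST):
            raise ValueError(f"direction must be {GREATER!r} or {AT_MOST!r}")

    def admits(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        return x > self.threshold if self.direction == GREATER else x <= self.threshold

    def describe(self) -> str:
        return f"{self.marker} {self.direction} {self.threshold:.4f}"


@dataclass(frozen=True)
class GatingRule:
    """Root-to-leaf conjunction of marker conditions defining one cell type.

    ``leaf_target_fraction`` is the fraction of all reference Target cells the
    leaf captures (> target_retention on the training reference);
    ``leaf_purity`` is the Target fraction among gated reference cells in the
    leaf.  A cell satisfies the rule iff it satisfies every condition.
    """

    cell_type: str
    conditions: tuple[MarkerCondition, ...]
    leaf_target_fraction: float
    leaf_purity: float

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c.marker for c in self.conditions))

    def mask(self, sample: ExpressionSample) -> np.ndarray:
        """Boolean mask of cells admitted by the full conjunction."""
        out = np.ones(sample.n_cells, dtype=bool)
        for cond in self.conditions:
            out &= cond.admits(sample.marker_column(cond.marker))
        return out

    def describe(self) -> str:
        conds = " AND ".join(c.describe() for c in self.conditions)
        return (
            f"{self.cell_type}: {conds} "
            f"(retention {self.leaf_target_fraction:.3f}, purity {self.leaf_purity:.3f})"
        )


def merge_conditions(conditions: Sequence[MarkerCondition]) -> tuple[MarkerCondition, ...]:
    """Collapse repeated same-marker, same-direction conditions to the tightest bound.

    The admitted region (intersection of half-spaces) is unchanged.  The first
    occurrence keeps its position in the path order.
    """
    merged: list[MarkerCondition] = []
    index: dict[tuple[str, str], int] = {}
    for cond in conditions:
        key = (cond.marker, cond.direction)
        if key in index:
            k = index[key]
            prev = merged[k]
            tighter = (
                max(prev.threshold, cond.threshold)
                if cond.direction == GREATER
                else min(prev.threshold, cond.threshold)
            )
            merged[k] = replace(prev, threshold=tighter)
        else:
            index[key] = len(merged)
            merged.append(cond)
    return tuple(merged)


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitCandidate:
    """Best threshold found for a node: marker, midpoint threshold, gain.

    ``direction`` identifies the target-enriched side of the split;
    ``enriched_targets``/``enriched_size`` describe that child.
    """

    marker: str
    marker_index: int
    threshold: float
    direction: str
    gain: float
    enriched_targets: int
    enriched_size: int


def _marker_best(
    x: np.ndarray, target: np.ndarray
) -> tuple[float, float, float, float] | None:
    """Best midpoint split of one marker within a node.

    Returns (gain, threshold, left_p, right_p) for the highest-gain candidate
    (ties -> lowest threshold), or None when the marker is constant.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ts = target[order].astype(np.float64)
    n = xs.shape[0]
    cum_t = np.cumsum(ts)
    total_t = cum_t[-1]
    boundary = np.flatnonzero(xs[1:] != xs[:-1]) + 1  # left-child sizes
    if boundary.size == 0:
        return None
    left_n = boundary.astype(np.float64)
    left_t = cum_t[boundary - 1]
    right_n = n - left_n
    right_t = total_t - left_t
    pl = left_t / left_n
    pr = right_t / right_n
    gains = (
        _binary_entropy(np.asarray(total_t / n))
        - (left_n / n) * _binary_entropy(pl)
        - (right_n / n) * _binary_entropy(pr)
    )
    j = int(np.argmax(gains))  # first maximum -> lowest threshold
    thr = float((xs[boundary[j] - 1] + xs[boundary[j]]) / 2.0)
    return float(gains[j]), thr, float(pl[j]), float(pr[j])


def best_split(
    matrix: np.ndarray,
    target_mask: np.ndarray,
    node_mask: np.ndarray | None = None,
    marker_names: Sequence[str] | None = None,
    allowed_markers: Iterable[int] | None = None,
) -> SplitCandidate | None:
    """Exhaustive best (marker, threshold) split of a node by information gain.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of each marker within the node.  Ties break to the lowest marker
    index, then the lowest threshold.  Returns None when no split has positive
    gain (the no-split signal).
    """
    matrix = np.asarray(matrix, dtype=float)
    target_mask = np.asarray(target_mask, dtype=bool)
    if node_mask is None:
        node_mask = np.ones(matrix.shape[0], dtype=bool)
    node_mask = np.asarray(node_mask, dtype=bool)
    X = matrix[node_mask]
    t = target_mask[node_mask]
    if X.shape[0] < 2:
        return None
    names = (
        tuple(marker_names)
        if marker_names is not None
        else tuple(f"M{k}" for k in range(matrix.shape[1]))
    )
    columns = (
        range(matrix.shape[1]) if allowed_markers is None else sorted(allowed_markers)
    )
    best: SplitCandidate | None = None
    for m in columns:
        found = _marker_best(X[:, m], t)
        if found is None:
            continue
        gain, thr, pl, pr = found
        if gain <= 0.0 or (best is not None and gain <= best.gain):
            continue
        direction = GREATER if pr > pl else AT_MOST
        side = X[:, m] > thr if direction == GREATER else X[:, m] <= thr
        best = SplitCandidate(
            marker=names[m],
            marker_index=m,
            threshold=thr,
            direction=direction,
            gain=gain,
            enriched_targets=int((t & side).sum()),
            enriched_size=int(side.sum()),
        )
    return best


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _constrained_split(
    X: np.ndarray,
    target: np.ndarray,
    node: np.ndarray,
    root: np.ndarray,
    names: tuple[str, ...],
    exclude_markers: set[str],
    total_targets: int,
    retention: float,
) -> SplitCandidate | None:
    """Best split on an unused marker that keeps leaf retention.

    Used only to satisfy the at-least-two-distinct-markers requirement.
    When growth stops before two distinct markers are on the path, the node
    is (close to) pure and within-node gains are driven by stray cells, so
    candidates are scored at the root -- the globally most discriminative
    unused marker, as the second defining marker in manual gating -- while
    the retention constraint is still evaluated on the current node.
    Within-node candidates are the last resort.
    """
    allowed = [k for k, nm in enumerate(names) if nm not in exclude_markers]

    def search(score_mask: np.ndarray) -> SplitCandidate | None:
        best: SplitCandidate | None = None
        for m in allowed:
            cand = best_split(X, target, score_mask, names, allowed_markers=[m])
            if cand is None:
                continue
            cond = MarkerCondition(cand.marker, cand.direction, cand.threshold)
            kept = node & cond.admits(X[:, m])
            if int((kept & target).sum()) / total_targets <= retention:
                continue
            if best is None or cand.gain > best.gain:
                best = cand
        return best

    return search(root) or search(node)


def train_cell_type_tree(
    reference: ExpressionSample, cell_type: str, params: HyperParams | None = None
) -> GatingRule:
    """Grow the one-vs-rest tree for one cell type and extract its gating rule.

    The reference must be arcsinh-transformed and labelled.  Target is the
    given type; Other is every other gated type (ungated cells are excluded
    from training).  Only the target-enriched child is descended into, so the
    learned classifier is the conjunction of conditions along that path.
    """
    params = params or HyperParams()
    if reference.is_raw:
        raise TreeTrainingError("reference must be arcsinh-transformed before training")
    if reference.labels is None:
        raise TreeTrainingError("reference must carry cell-type labels")
    labels = reference.labels
    target = labels == cell_type
    total_targets = int(target.sum())
    if cell_type == reference.ungated_sentinel:
        raise TreeTrainingError("cannot train a rule for the ungated sentinel")
    if total_targets < 2:
        raise TreeTrainingError(
            f"cell type {cell_type!r}: needs at least 2 reference cells, "
            f"found {total_targets}"
        )
    X = reference.matrix
    names = reference.marker_names
    node = reference.gated_mask().copy()
    conditions: list[MarkerCondition] = []

    while True:
        merged = merge_conditions(conditions)
        distinct = len({c.marker for c in merged})
        satisfied = len(merged) >= 2 and distinct >= 2
        node_n = int(node.sum())
        node_t = int((node & target).sum())

        if (
            params.stop_rule == "purity"
            and satisfied
            and node_n > 0
            and node_t / node_n >= params.target_retention
        ):
            break
        if len(conditions) >= params.max_depth:
            if satisfied:
                break
            raise TreeTrainingError(
                f"cell type {cell_type!r}: depth cap reached before a rule with "
                "two distinct markers was found"
            )

        cand = best_split(X, target, node, names)
        stop = cand is None or cand.gain <= params.min_entropy_gain
        if (
            not stop
            and params.stop_rule == "retention"
            and cand.enriched_targets / total_targets <= params.target_retention
        ):
            stop = True
        if stop:
            if satisfied:
                break
            # The leaf must test at least two distinct markers: keep splitting
            # on an unused marker while any positive-gain, retention-keeping
            # split exists.
            cand = _constrained_split(
                X, target, node, reference.gated_mask(), names,
                exclude_markers={c.marker for c in merged},
                total_targets=total_targets,
                retention=params.target_retention,
            )
            if cand is None:
                raise TreeTrainingError(
                    f"cell type {cell_type!r}: no informative split satisfying the "
                    "two-marker and target-retention constraints"
                )

        cond = MarkerCondition(cand.marker, cand.direction, cand.threshold)
        conditions.append(cond)
        node &= cond.admits(X[:, cand.marker_index])

    merged = merge_conditions(conditions)
    leaf_n = int(node.sum())
    leaf_t = int((node & target).sum())
    fraction = leaf_t / total_targets
    purity = leaf_t / leaf_n if leaf_n else 0.0
    if fraction <= params.target_retention:
        raise TreeTrainingError(
            f"cell type {cell_type!r}: leaf retains only {fraction:.3f} of Target "
            f"cells (needs > {params.target_retention})"
        )
    return GatingRule(
        cell_type=cell_type,
        conditions=merged,
        leaf_target_fraction=fraction,
        leaf_purity=purity,
    )
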