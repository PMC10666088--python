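"""Tentative labeling: decision-tree labels reconciled with nearest centroids.

Cells of a new, unassigned sample are first labelled by the reference gating
rules; a cell matching no rule is tentatively ungated, and a cell matching
several rules is resolved to the nearest-centroid member of the match set.
Because marker expression levels drift between batches, the tree label *i*
is then reconciled against the nearest-reference-centroid label *j* using
Euclidean distance over all classification markers:

* gated tree label, ``i == j``                       -> keep *i*
* gated tree label, ``Ed(i) − Ed(j) > d1``           -> override to *j*
* gated tree label otherwise                         -> keep *i*
* tree-ungated and ``Ed(j) < d2``                    -> rescue to *j*
* tree-ungated otherwise                             -> stay ungated
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .params import HyperParams
from .sample import CentroidSet, ExpressionSample, SampleError
from .trees import GatingRule

__all__ = [
    "PROV_TREE",
    "PROV_OVERRIDE",
    "PROV_RESCUE",
    "PROV_UNGATED",
    "PROV_RECLASSIFIED",
    "LabelVector",
    "tree_label",
    "nearest_centroid",
    "tentative_label",
    "assign_tentative",
    "tree_only_label",
]

PROV_TREE = "tree-label"
PROV_OVERRIDE = "centroid-override"
PROV_RESCUE = "centroid-rescue"
PROV_UNGATED = "ungated"
PROV_RECLASSIFIED = "reclassified"


@dataclass(frozen=True)
class LabelVector:
    """Per-cell assigned labels plus the provenance of each assignment."""

    labels: np.ndarray
    provenance: np.ndarray
    ungated_sentinel: str = "ungated"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        prov = np.asarray(self.provenance, dtype=object)
        if labels.shape != prov.shape:
            raise ValueError("labels and provenance must have equal length")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "provenance", prov)

    def __len__(self) -> int:
        return self.labels.shape[0]

    def counts(self) -> dict[str, int]:
        types, n = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(types.tolist(), n.tolist()))

    def gated_mask(self) -> np.ndarray:
        return self.labels != self.ungated_sentinel


# ---------------------------------------------------------------------------
# Single-cell operations
# ---------------------------------------------------------------------------

def _check_alignment(sample: ExpressionSample, rules: Sequence[GatingRule]) -> None:
    for rule in rules:
        for cond in rule.conditions:
            if cond.marker not in sample.marker_names:
                raise SampleError(
                    f"sample lacks marker {cond.marker!r} required by rule "
                    f"{rule.cell_type!r}"
                )


def tree_label(
    model, cell: np.ndarray
) -> str | tuple[str, ...]:
    """Evaluate every gating rule on one cell vector.

    Returns the single matching type, the ungated sentinel for zero matches,
    or the sorted tuple of matching types when several rules fire (resolved
    downstream).  The cell must be aligned to the model's marker ordering.
    """
    cell = np.asarray(cell, dtype=float)
    if cell.shape != (len(model.marker_names),):
        raise SampleError(
            f"cell vector has {cell.shape[0] if cell.ndim else 0} entries, "
            f"model expects {len(model.marker_names)}"
        )
    index = {m: k for k, m in enumerate(model.marker_names)}
    matches = []
    for rule in model.rules:
        if all(bool(c.admits(cell[index[c.marker]])) for c in rule.conditions):
            matches.append(rule.cell_type)
    if not matches:
        return model.ungated_sentinel
    if len(matches) == 1:
        return matches[0]
    return tuple(sorted(matches))


def nearest_centroid(cell: np.ndarray, centroids: CentroidSet) -> tuple[str, float]:
    """Type of the nearest centroid by Euclidean distance, with the distance.

    Ties break deterministically to the lexicographically first type name.
    """
    if len(centroids) == 0:
        raise SampleError("empty centroid set")
    d = centroids.distances(np.asarray(cell, dtype=float)[None, :])[0]
    j = int(np.argmin(d))  # first minimum -> lexicographically first type
    return centroids.types[j], float(d[j])


# ---------------------------------------------------------------------------
# Vectorised sample-level labeling
# ---------------------------------------------------------------------------

def _match_matrix(
    rules: Sequence[GatingRule], sample: ExpressionSample
) -> np.ndarray:
    """(n_cells, n_rules) rule-satisfaction matrix, columns in rule order."""
    return np.column_stack([r.mask(sample) for r in rules])


def assign_tentative(
    rules: Sequence[GatingRule],
    centroids: CentroidSet,
    sample: ExpressionSample,
    params: HyperParams,
    ungated_sentinel: str,
) -> LabelVector:
    """Tentative labels for every cell of a transformed, aligned sample.

    ``rules`` must be ordered by cell type, matching ``centroids.types``.
    """
    if sample.is_raw:
        raise SampleError("sample must be arcsinh-transformed before labeling")
    _check_alignment(sample, rules)
    types = np.asarray(centroids.types, dtype=object)
    rule_types = tuple(r.cell_type for r in rules)
    if rule_types != centroids.types:
        raise SampleError(
            f"rule types {rule_types} do not match centroid types {centroids.types}"
        )
    n = sample.n_cells
    M = _match_matrix(rules, sample)
    X = sample.subset_markers(centroids.marker_names).matrix
    D = centroids.distances(X)

    j_idx = np.argmin(D, axis=1)
    d_j = np.take_along_axis(D, j_idx[:, None], axis=1)[:, 0]

    # tree label i: unique match, or nearest-centroid member of the match set
    Dm = np.where(M, D, np.inf)
    i_idx = np.argmin(Dm, axis=1)
    d_i = np.take_along_axis(Dm, i_idx[:, None], axis=1)[:, 0]

    gated = M.any(axis=1)
    labels = np.empty(n, dtype=object)
    prov = np.empty(n, dtype=object)

    override = gated & (i_idx != j_idx) & (d_i - d_j > params.d1)
    keep = gated & ~override
    labels[keep] = types[i_idx[keep]]
    prov[keep] = PROV_TREE
    labels[override] = types[j_idx[override]]
    prov[override] = PROV_OVERRIDE

    unmatched = ~gated
    rescue = unmatched & (d_j < params.d2)
    labels[rescue] = types[j_idx[rescue]]
    prov[rescue] = PROV_RESCUE
    rest = unmatched & ~rescue
    labels[rest] = ungated_sentinel
    prov[rest] = PROV_UNGATED
    return LabelVector(labels, prov, ungated_sentinel=ungated_sentinel)


def tentative_label(model, sample: ExpressionSample) -> LabelVector:
    """Tentative labeling of a new sample using a trained gate model."""
    aligned = model.prepare(sample)
    return assign_tentative(
        model.rules, model.centroids, aligned, model.params, model.ungated_sentinel
    )


def tree_only_label(
    rules: Sequence[GatingRule],
    centroids: CentroidSet,
    sample: ExpressionSample,
    ungated_sentinel: str,
) -> LabelVector:
    """Pure reference-rule labels (no d1/d2 reconciliation); ablation mode.

    Multi-matches are still resolved to the nearest-centroid member of the
    match set, since a LabelVector carries exactly one label per cell.
    """
    if sample.is_raw:
        raise SampleError("sample must be arcsinh-transformed before labeling")
    _check_alignment(sample, rules)
    types = np.asarray(centroids.types, dtype=object)
    M = _match_matrix(rules, sample)
    X = sample.subset_markers(centroids.marker_names).matrix
    D = centroids.distances(X)
    Dm = np.where(M, D, np.inf)
    i_idx = np.argmin(Dm, axis=1)
    gated = M.any(axis=1)
    labels = np.where(gated, types[i_idx], ungated_sentinel).astype(object)
    prov = np.where(gated, PROV_TREE, PROV_UNGATED).astype(object)
    return LabelVector(labels, prov, ungated_sentinel=ungated_sentinel)
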