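"""Model/results facade: ``CellGater`` is configured on a labelled reference
sample and ``fit()`` returns a ``GateModel`` results object that carries the
trained gating rules, reference centroids, per-rule diagnostics, a
``summary()`` table, serialisation, and ``gate()`` for new samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import HyperParams
from .sample import (
    DEFAULT_UNGATED,
    CentroidSet,
    ExpressionSample,
    SampleError,
    compute_centroids,
    ensure_transformed,
    read_sample_csv,
)
from .trees import (
    GatingRule,
    MarkerCondition,
    TreeTrainingError,
    train_cell_type_tree,
)

__all__ = ["CellGater", "GateModel", "train_model"]

_MODEL_FORMAT = "gatetree-model"
_MODEL_VERSION = 1


@dataclass(frozen=True)
class GateModel:
    """Trained gating classifier: one rule and one centroid per gated type.

    Rules are stored in sorted cell-type order, matching the centroid set.
    """

    rules: tuple[GatingRule, ...]
    centroids: CentroidSet
    params: HyperParams
    marker_names: tuple[str, ...]
    ungated_sentinel: str = DEFAULT_UNGATED

    def __post_init__(self) -> None:
        rules = tuple(sorted(self.rules, key=lambda r: r.cell_type))
        object.__setattr__(self, "rules", rules)
        rule_types = tuple(r.cell_type for r in rules)
        if rule_types != self.centroids.types:
            raise SampleError(
                f"rule types {rule_types} and centroid types "
                f"{self.centroids.types} must cover the same set"
            )

    @property
    def cell_types(self) -> tuple[str, ...]:
        return tuple(r.cell_type for r in self.rules)

    def rule_for(self, cell_type: str) -> GatingRule:
        for r in self.rules:
            if r.cell_type == cell_type:
                return r
        raise KeyError(cell_type)

    # -- sample preparation --------------------------------------------

    def prepare(self, sample: ExpressionSample) -> ExpressionSample:
        """Align a sample to the model: check markers, reorder, arcsinh if raw."""
        missing = [m for m in self.marker_names if m not in sample.marker_names]
        if missing:
            raise SampleError(f"sample lacks model markers: {missing}")
        aligned = sample.subset_markers(self.marker_names)
        return ensure_transformed(aligned, self.params.cofactor)

    # -- inference ------------------------------------------------------

    def gate(self, sample: ExpressionSample, tune: bool = True):
        """Gate a new sample; returns a GatingOutcome (see ``.labels``)."""
        from .tuning import run_gating

        return run_gating(self, sample, tune=tune)

    def tentative(self, sample: ExpressionSample):
        from .labeling import tentative_label

        return tentative_label(self, sample)

    # -- reporting ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Gating model",
            f"  markers ({len(self.marker_names)}): {', '.join(self.marker_names)}",
            f"  cell types ({len(self.rules)}):",
        ]
        for r in self.rules:
            lines.append("    " + r.describe())
        lines.append("  hyperparameters:")
        for k, v in self.params.to_dict().items():
            lines.append(f"    {k} = {v}")
        return "\n".join(lines)

    def diagnostics(self) -> pd.DataFrame:
        """Per-type training diagnostics: conditions, leaf retention, purity."""
        rows = [
            {
                "cell_type": r.cell_type,
                "n_conditions": len(r.conditions),
                "conditions": " AND ".join(c.describe() for c in r.conditions),
                "leaf_target_fraction": r.leaf_target_fraction,
                "leaf_purity": r.leaf_purity,
            }
            for r in self.rules
        ]
        return pd.DataFrame(rows)

    # -- serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": _MODEL_FORMAT,
            "version": _MODEL_VERSION,
            "ungated_sentinel": self.ungated_sentinel,
            "marker_names": list(self.marker_names),
            "params": self.params.to_dict(),
            "rules": [
                {
                    "cell_type": r.cell_type,
                    "conditions": [
                        {
                            "marker": c.marker,
                            "direction": c.direction,
                            "threshold": c.threshold,
                        }
                        for c in r.conditions
                    ],
                    "leaf_target_fraction": r.leaf_target_fraction,
                    "leaf_purity": r.leaf_purity,
                }
                for r in self.rules
            ],
            "centroids": {
                t: [float(v) for v in self.centroids[t]] for t in self.centroids.types
            },
        }

    def save(self, path: str | Path) -> None:
        """Serialise to a human-readable structured text (JSON) file."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "GateModel":
        if d.get("format") != _MODEL_FORMAT:
            raise SampleError("not a gatetree model file")
        rules = tuple(
            GatingRule(
                cell_type=r["cell_type"],
                conditions=tuple(
                    MarkerCondition(c["marker"], c["direction"], float(c["threshold"]))
                    for c in r["conditions"]
                ),
                leaf_target_fraction=float(r["leaf_target_fraction"]),
                leaf_purity=float(r["leaf_purity"]),
            )
            for r in d["rules"]
        )
        markers = tuple(d["marker_names"])
        centroids = CentroidSet(
            marker_names=markers,
            centroids={t: np.asarray(v, dtype=float) for t, v in d["centroids"].items()},
        )
        return cls(
            rules=rules,
            centroids=centroids,
            params=HyperParams.from_dict(d["params"]),
            marker_names=markers,
            ungated_sentinel=d["ungated_sentinel"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "GateModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_model(
    reference: ExpressionSample, params: HyperParams | None = None
) -> GateModel:
    """Train one gating rule per gated type plus the reference centroids.

    Deterministic given its input.  Per-type training failures are collected
    and re-raised together with the full list of failing types.
    """
    params = params or HyperParams()
    reference = ensure_transformed(reference, params.cofactor)
    if reference.labels is None:
        raise TreeTrainingError("reference must carry cell-type labels")
    types = reference.gated_types()
    if not types:
        raise TreeTrainingError("reference contains no gated cell types")
    rules: list[GatingRule] = []
    failures: list[str] = []
    for t in types:
        try:
            rules.append(train_cell_type_tree(reference, t, params))
        except TreeTrainingError as exc:
            failures.append(f"{t}: {exc}")
    if failures:
        raise TreeTrainingError(
            "training failed for cell types:\n  " + "\n  ".join(failures)
        )
    centroids = compute_centroids(reference, cell_types=types)
    return GateModel(
        rules=tuple(rules),
        centroids=centroids,
        params=params,
        marker_names=reference.marker_names,
        ungated_sentinel=reference.ungated_sentinel,
    )


class CellGater:
    """Gating model configured on a manually gated reference sample.

    Parameters
    ----------
    reference : ExpressionSample
        Labelled reference; raw samples are arcsinh-transformed at fit time.
    params : HyperParams, optional
        Pipeline hyperparameters (defaults follow the method's standard
        settings: d1 = 1, d2 = 0.05, minimum gain 0.1, retention 0.9,
        density stop 1%, cofactor 5).
    markers : sequence of str, optional
        Classification-marker subset; defaults to every marker column.

    Examples
    --------
    >>> gater = CellGater.from_csv("reference.csv", label_column="cell_type")
    >>> model = gater.fit()
    >>> outcome = model.gate(new_sample)
    >>> outcome.labels.counts()
    """

    def __init__(
        self,
        reference: ExpressionSample,
        params: HyperParams | None = None,
        markers: Sequence[str] | None = None,
    ) -> None:
        if reference.labels is None:
            raise SampleError("reference sample must carry cell-type labels")
        if markers is not None:
            reference = reference.subset_markers(markers)
        self.params = params or HyperParams()
        self.reference = ensure_transformed(reference, self.params.cofactor)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        label_column: str = "cell_type",
        ungated_sentinel: str = DEFAULT_UNGATED,
        markers: Sequence[str] | None = None,
        params: HyperParams | None = None,
        pre_transformed: bool = False,
    ) -> "CellGater":
        sample = read_sample_csv(
            path, label_column=label_column, ungated_sentinel=ungated_sentinel
        )
        if pre_transformed:
            sample = ExpressionSample(
                matrix=sample.matrix,
                marker_names=sample.marker_names,
                cell_ids=sample.cell_ids,
                labels=sample.labels,
                is_raw=False,
                ungated_sentinel=sample.ungated_sentinel,
            )
        return cls(sample, params=params, markers=markers)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = "cell_type",
        ungated_sentinel: str = DEFAULT_UNGATED,
        markers: Sequence[str] | None = None,
        params: HyperParams | None = None,
        pre_transformed: bool = False,
    ) -> "CellGater":
        labels = df[label_column].astype(str).to_numpy(dtype=object)
        data = df.drop(columns=[label_column])
        sample = ExpressionSample(
            matrix=data.to_numpy(dtype=float),
            marker_names=tuple(data.columns),
            labels=labels,
            is_raw=not pre_transformed,
            ungated_sentinel=ungated_sentinel,
        )
        return cls(sample, params=params, markers=markers)

    def fit(self) -> GateModel:
        """Train the per-type gating trees and reference centroids."""
        return train_model(self.reference, self.params)
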