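"""Hyperparameters shared across the gating pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Any, Mapping

from .sample import DEFAULT_COFACTOR

__all__ = ["HyperParams"]

_STOP_RULES = ("retention", "purity")


@dataclass(frozen=True)
class HyperParams:
    """Tunable constants of the gating pipeline (all in arcsinh units).

    Attributes
    ----------
    d1 : float
        Margin by which the nearest-centroid distance must beat the tree-label
        centroid distance before a tentative tree label is overridden.
    d2 : float
        Distance cap under which a tree-ungated cell is rescued to the nearest
        centroid's type.
    min_entropy_gain : float
        Minimum information gain (base-2 entropy reduction) for a tree split.
    target_retention : float
        A leaf must keep more than this fraction of all reference Target cells.
    density_stop_fraction : float
        Boundary tuning stops once a sweep step introduces fewer cells than
        this fraction of the densest point inside the current boundaries.
    cofactor : float
        arcsinh cofactor for raw ion counts.
    drift_threshold : float
        Euclidean centroid displacement above which a type counts as drifted.
    max_iterations : int
        Cap on tentative-label / tune / reclassify refinement rounds.
    max_depth : int
        Cap on the number of conditions along a gating rule's path.
    sweep_bins : int
        Grid resolution of the tuning sweep: step = marker range / sweep_bins.
    stop_rule : str
        Reading of the split-node stopping criterion: ``"retention"`` (fraction
        of all Target cells kept on the followed path, default) or ``"purity"``
        (stop once the followed node's Target purity reaches target_retention).
    """

    d1: float = 1.0
    d2: float = 0.05
    min_entropy_gain: float = 0.1
    target_retention: float = 0.9
    density_stop_fraction: float = 0.01
    cofactor: float = DEFAULT_COFACTOR
    drift_threshold: float = 0.1
    max_iterations: int = 5
    max_depth: int = 6
    sweep_bins: int = 200
    stop_rule: str = "retention"

    def __post_init__(self) -> None:
        for name in (
            "d1", "d2", "min_entropy_gain", "cofactor",
            "drift_threshold", "max_iterations", "max_depth", "sweep_bins",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.target_retention < 1:
            raise ValueError("target_retention must lie in (0, 1)")
        if not 0 < self.density_stop_fraction < 1:
            raise ValueError("density_stop_fraction must lie in (0, 1)")
        if self.stop_rule not in _STOP_RULES:
            raise ValueError(f"stop_rule must be one of {_STOP_RULES}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "HyperParams":
        return cls(**dict(d))

    def replace(self, **kw: Any) -> "HyperParams":
        return replace(self, **kw)
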