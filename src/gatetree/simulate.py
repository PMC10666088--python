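"""Seeded synthetic CyTOF-like samples with exact ground truth.

Populations are Gaussian per marker in arcsinh space (the space the
classifier operates in, which keeps centroid and threshold recovery
analytically checkable).  The stock layout emulates a multicenter-style
design: four cell types over eight markers, each type elevated on its own
marker pair, plus ~25% ungated background drawn from a broad diffuse
component and low-density Gaussian "bridge" waypoints between type
centroids (cells lacking distinguishing characteristics).  Batch effects
are per-marker affine maps (``scale·x + shift``) applied in arcsinh space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np

from .sample import DEFAULT_UNGATED, ExpressionSample, SampleError, write_sample_csv

__all__ = [
    "PopulationSpec",
    "BatchEffectSpec",
    "generate_sample",
    "apply_batch_effect",
    "multicenter_like_populations",
    "BenchmarkSuite",
    "standard_benchmark_suite",
    "write_suite",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One Gaussian cell population: per-marker location/spread, arcsinh units.

    ``background`` populations are truly ungated: their cells carry the
    ungated sentinel as ground truth.
    """

    label: str
    means: tuple[float, ...]
    scales: tuple[float, ...]
    count: int
    background: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", tuple(float(v) for v in self.means))
        object.__setattr__(self, "scales", tuple(float(v) for v in self.scales))
        if len(self.means) != len(self.scales):
            raise ValueError("means and scales must have equal length")
        if any(s <= 0 for s in self.scales):
            raise ValueError("spreads must be strictly positive")
        if self.count < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class BatchEffectSpec:
    """Per-marker affine batch effect in arcsinh space: x -> scale*x + shift."""

    shifts: tuple[float, ...]
    scales: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        shifts = tuple(float(v) for v in self.shifts)
        scales = (
            tuple(float(v) for v in self.scales)
            if len(self.scales)
            else (1.0,) * len(shifts)
        )
        if len(scales) != len(shifts):
            raise ValueError("shifts and scales must have equal length")
        if any(s <= 0 for s in scales):
            raise ValueError("scales must be strictly positive")
        object.__setattr__(self, "shifts", shifts)
        object.__setattr__(self, "scales", scales)


def generate_sample(
    populations: list[PopulationSpec],
    seed: int,
    marker_names: tuple[str, ...] | None = None,
    ungated_sentinel: str = DEFAULT_UNGATED,
) -> ExpressionSample:
    """Draw a labelled sample from Gaussian populations in arcsinh space.

    Background populations are labelled with the ungated sentinel; cell
    order is shuffled deterministically by the seed.
    """
    if not populations:
        raise ValueError("population list must be nonempty")
    n_markers = len(populations[0].means)
    gated = [p.label for p in populations if not p.background]
    if len(gated) != len(set(gated)):
        raise ValueError("duplicate gated cell type labels")
    for p in populations:
        if len(p.means) != n_markers:
            raise ValueError("all populations must share the marker dimension")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for p in populations:
        blocks.append(rng.normal(p.means, p.scales, size=(p.count, n_markers)))
        labels.extend([ungated_sentinel if p.background else p.label] * p.count)
    matrix = np.vstack(blocks)
    labels = np.asarray(labels, dtype=object)
    order = rng.permutation(matrix.shape[0])
    names = marker_names or tuple(f"M{k + 1}" for k in range(n_markers))
    return ExpressionSample(
        matrix=matrix[order],
        marker_names=names,
        labels=labels[order],
        is_raw=False,
        ungated_sentinel=ungated_sentinel,
    )


def apply_batch_effect(
    sample: ExpressionSample, effect: BatchEffectSpec
) -> ExpressionSample:
    """Apply a per-marker affine batch effect; labels are unchanged."""
    if sample.is_raw:
        raise SampleError("batch effects apply in arcsinh space (transformed samples)")
    if len(effect.shifts) != sample.n_markers:
        raise SampleError(
            f"effect has {len(effect.shifts)} markers, sample {sample.n_markers}"
        )
    scales = np.asarray(effect.scales)
    shifts = np.asarray(effect.shifts)
    return replace(sample, matrix=sample.matrix * scales + shifts)


# ---------------------------------------------------------------------------
# Stock multicenter-like layout
# ---------------------------------------------------------------------------

_TYPE_LAYOUT = (
    ("cd4_t", (0, 1)),
    ("cd8_t", (2, 3)),
    ("b_cell", (4, 5)),
    ("monocyte", (6, 7)),
)
_N_MARKERS = 8
_LOW, _HIGH, _SPREAD = 0.8, 3.2, 0.45
_BG_MEAN, _BG_SPREAD = 1.0, 0.6
_BRIDGE_FRACTION = 0.15
_BRIDGE_SPREAD = 0.18
_BRIDGE_WAYPOINTS = (0.25, 0.5, 0.75)


def _type_centroid(high_markers: tuple[int, ...]) -> np.ndarray:
    c = np.full(_N_MARKERS, _LOW)
    c[list(high_markers)] = _HIGH
    return c


def multicenter_like_populations(
    cells_per_type: int = 750, background_cells: int = 1000
) -> list[PopulationSpec]:
    """Four types x eight markers plus ~25% diffuse-and-bridge background.

    Each type is elevated on its own marker pair (arcsinh means 3.2 high /
    0.8 low, spread 0.45).  The background mixes a broad diffuse component
    with low-density bridge waypoints between every pair of type centroids.
    """
    pops = [
        PopulationSpec(
            label=name,
            means=tuple(_type_centroid(markers)),
            scales=(_SPREAD,) * _N_MARKERS,
            count=cells_per_type,
        )
        for name, markers in _TYPE_LAYOUT
    ]
    pairs = list(combinations(range(len(_TYPE_LAYOUT)), 2))
    n_waypoints = len(pairs) * len(_BRIDGE_WAYPOINTS)
    per_waypoint = max(1, int(background_cells * _BRIDGE_FRACTION) // n_waypoints)
    n_diffuse = background_cells - per_waypoint * n_waypoints
    pops.append(
        PopulationSpec(
            label="diffuse_background",
            means=(_BG_MEAN,) * _N_MARKERS,
            scales=(_BG_SPREAD,) * _N_MARKERS,
            count=n_diffuse,
            background=True,
        )
    )
    centroids = [_type_centroid(m) for _, m in _TYPE_LAYOUT]
    for a, b in pairs:
        for t in _BRIDGE_WAYPOINTS:
            mid = (1 - t) * centroids[a] + t * centroids[b]
            pops.append(
                PopulationSpec(
                    label=f"bridge_{a}{b}_{t:.2f}",
                    means=tuple(mid),
                    scales=(_BRIDGE_SPREAD,) * _N_MARKERS,
                    count=per_waypoint,
                    background=True,
                )
            )
    return pops


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkSuite:
    """Reference + paired same-batch/shifted-batch targets with exact truth.

    ``shifted_batch[k]`` is ``same_batch[k]`` with ``effects[k]`` applied, so
    the two batches differ only by the affine effect.
    """

    reference: ExpressionSample
    same_batch: tuple[ExpressionSample, ...]
    shifted_batch: tuple[ExpressionSample, ...]
    effects: tuple[BatchEffectSpec, ...]
    seed: int
    label_column: str = "cell_type"
    ungated_sentinel: str = DEFAULT_UNGATED

    @property
    def targets(self) -> tuple[ExpressionSample, ...]:
        return self.same_batch + self.shifted_batch


def _batch_shift_spec(rng: np.random.Generator, n_markers: int) -> BatchEffectSpec:
    """Per-marker shifts of magnitude U(0.35, 0.5) with alternating sign.

    Even-indexed markers shift down and odd-indexed up, so every type of the
    stock layout has at least one down-shifted defining marker (real batch
    effects move channels in both directions).
    """
    mags = rng.uniform(0.35, 0.5, size=n_markers)
    signs = np.where(np.arange(n_markers) % 2 == 0, -1.0, 1.0)
    return BatchEffectSpec(shifts=tuple(mags * signs))


def standard_benchmark_suite(
    seed: int,
    n_targets: int = 3,
    cells_per_type: int = 750,
    background_cells: int = 1000,
) -> BenchmarkSuite:
    """Stock end-to-end fixture: 1 reference + ``n_targets`` same-batch and
    ``n_targets`` shifted-batch targets (4 types, 8 markers, ~25% background).
    """
    pops = multicenter_like_populations(cells_per_type, background_cells)
    ss = np.random.SeedSequence(seed)
    child = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_targets + 2)]
    reference = generate_sample(pops, seed=child[0])
    draws = tuple(
        generate_sample(pops, seed=child[1 + k]) for k in range(n_targets)
    )
    eff_rng = np.random.default_rng(child[-1])
    effects = tuple(_batch_shift_spec(eff_rng, _N_MARKERS) for _ in range(n_targets))
    shifted = tuple(apply_batch_effect(s, e) for s, e in zip(draws, effects))
    return BenchmarkSuite(
        reference=reference,
        same_batch=draws,
        shifted_batch=shifted,
        effects=effects,
        seed=seed,
    )


def write_suite(suite: BenchmarkSuite, directory: str | Path) -> Path:
    """Write the suite as CSVs plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {"reference": "reference.csv", "same_batch": [], "shifted_batch": []}
    write_sample_csv(
        suite.reference, directory / "reference.csv", label_column=suite.label_column
    )
    for k, s in enumerate(suite.same_batch, start=1):
        name = f"target_same_{k}.csv"
        write_sample_csv(s, directory / name, label_column=suite.label_column)
        files["same_batch"].append(name)
    for k, s in enumerate(suite.shifted_batch, start=1):
        name = f"target_shifted_{k}.csv"
        write_sample_csv(s, directory / name, label_column=suite.label_column)
        files["shifted_batch"].append(name)
    manifest = {
        "seed": suite.seed,
        "label_column": suite.label_column,
        "ungated_sentinel": suite.ungated_sentinel,
        "pre_transformed": True,
        "files": files,
        "effects": [
            {"shifts": list(e.shifts), "scales": list(e.scales)} for e in suite.effects
        ],
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
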