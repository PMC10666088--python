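"""Shared fixtures: the standard synthetic benchmark suite and a fitted model.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from gatetree import CellGater, ExpressionSample, standard_benchmark_suite

SUITE_SEED = 20240915


@pytest.fixture(scope="session")
def suite():
    """Stock benchmark suite: 1 reference + 3 same-batch + 3 shifted targets."""
    return standard_benchmark_suite(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def model(suite):
    """Gate model trained on the suite reference."""
    return CellGater(suite.reference).fit()


def make_sample(
    matrix,
    markers=None,
    labels=None,
    is_raw=False,
    ungated_sentinel="ungated",
) -> ExpressionSample:
    matrix = np.asarray(matrix, dtype=float)
    markers = tuple(markers) if markers else tuple(f"m{k+1}" for k in range(matrix.shape[1]))
    return ExpressionSample(
        matrix=matrix,
        marker_names=markers,
        labels=np.asarray(labels, dtype=object) if labels is not None else None,
        is_raw=is_raw,
        ungated_sentinel=ungated_sentinel,
    )
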