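"""Shared fixtures: small random inputs and the expensive end-to-end runs
on well-separated planted data, computed once per session."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from mogasvm import (GAConfig, SyntheticSpec, adjusted_rand, generate,
                     run_mogasvm)

# The fallback path logs loudly when K exceeds the planted structure;
# keep test output readable.
logging.getLogger("mogasvm").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_1d():
    """The hand-checkable 1-D dataset {0, 2, 10, 12} as a column matrix."""
    return np.array([[0.0], [2.0], [10.0], [12.0]])


def _pipeline_runs(effect_size: float, seeds: range) -> list[dict]:
    runs = []
    for s in seeds:
        ds = generate(SyntheticSpec(seed=s, effect_size=effect_size))
        res = run_mogasvm(ds.X.values, 4, GAConfig(seed=s))
        runs.append({
            "dataset": ds,
            "result": res,
            "ari": adjusted_rand(ds.true_labels, res.labels),
        })
    return runs


@pytest.fixture(scope="session")
def delta3_runs():
    """Ten full pipeline runs on well-separated data (effect size 3,
    4 classes x 15 samples, 200 genes, default GA/ensemble parameters)."""
    return _pipeline_runs(3.0, range(100, 110))


@pytest.fixture(scope="session")
def delta2_runs():
    """Ten full pipeline runs in the moderate regime (effect size 2)."""
    return _pipeline_runs(2.0, range(500, 510))
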