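"""Shared fixtures: small ground-truthed synthetic samples.

Everything is generated at test time; nothing is read from disk except
files the tests themselves write into tmp paths.
"""

from __future__ import annotations

import warnings

import pytest

from ctcdetect.pipeline import PipelineConfig, run_outlier_pass
from ctcdetect.sim import SimConfig, generate_dataset


SMALL = dict(n_cells=700, n_rare=2, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """700 background cells + 2 spiked rare cells, default gene roster."""
    return generate_dataset(SimConfig(**SMALL))


@pytest.fixture(scope="session")
def small_outlier_run(small_dataset):
    """Full outlier pass on the small sample (cached: several tests share it)."""
    cm, truth = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_outlier_pass(cm, PipelineConfig(seed=11))
    return cm, truth, res
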