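"""Shared fixtures: the canonical synthetic benchmark cohort.

The benchmark (120 samples x 1500 genes, 30% cyclic genes with peak-to-
trough amplitudes U(0.5, 2), residual noise sd 0.5 log2 units, stage-label
jitter sd 4 percentage points) is generated once per session and reused by
every test that needs a realistic cohort; the supervised pipeline result on
it is likewise computed once.
"""

import numpy as np
import pandas as pd
import pytest

from cyclestage.pipeline import run_full_pipeline
from cyclestage.simulate import SimConfig, label_with_pathology, simulate_cycle

BENCHMARK_SEED = 11


@pytest.fixture(scope="session")
def benchmark():
    """(expression, truth, annotation) for the canonical cohort."""
    cfg = SimConfig(seed=BENCHMARK_SEED)
    em, truth = simulate_cycle(cfg)
    ann = label_with_pathology(truth)
    return em, truth, ann


@pytest.fixture(scope="session")
def benchmark_pipeline(benchmark):
    """Supervised pipeline result on the canonical cohort."""
    em, truth, ann = benchmark
    return run_full_pipeline(em, ann)


@pytest.fixture(scope="session")
def secretory_cohort():
    """Synthetic secretory-only cohort: 90 samples, 500 genes, true POD
    uniform over the secretory window, noisy two-pathologist POD calls."""
    cfg = SimConfig(
        n_samples=90,
        n_genes=500,
        frac_cyclic=0.4,
        noise_sd=0.5,
        label_error_sd=2.0,
        pod_error_days=1.0,
        percentage_range=(58.0, 100.0),
        seed=101,
    )
    em, truth = simulate_cycle(cfg)
    ann = label_with_pathology(truth)
    return em, truth, ann


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
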