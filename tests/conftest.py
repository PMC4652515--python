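"""Shared fixtures: a tiny simulated two-clone dataset for module tests and
one full-scale dataset (session scope) for the end-to-end suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kmerphylo import (
    SimConfig,
    count_dataset,
    make_reference,
    preprocess,
    simulate_dataset,
    two_clone_profiles,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """Small two-clone dataset (4 kb genome, 4 cells/clone) through counting
    and normalization; fast enough for unit-level assertions."""
    out = tmp_path_factory.mktemp("tiny_sim")
    ref = make_reference(4000, 8, seed=11)
    clones = two_clone_profiles(8, 2, gain_copy_number=3)
    cfg = SimConfig(n_cells_per_clone=4, target_coverage=10.0,
                    error_rate=0.01, wga_sigma=0.2, rng_seed=17)
    paths, labels = simulate_dataset(ref, clones, cfg, out)
    counts = count_dataset(paths, k=11)
    abundance, report = preprocess(counts)
    return {
        "ref": ref,
        "clones": clones,
        "cfg": cfg,
        "paths": paths,
        "labels": dict(zip(labels.cell_id, labels.clone_id)),
        "counts": counts,
        "abundance": abundance,
        "report": report,
    }


@pytest.fixture(scope="session")
def two_clone_run(tmp_path_factory):
    """Full-scale two-clone dataset: 100 kb reference in 20 segments, a
    3-fold copy-number gain on 5 segments, 20 cells per clone, 20x coverage
    of 48 bp reads at 0.5% error, counted at k=15 and normalized."""
    out = tmp_path_factory.mktemp("two_clone_sim")
    ref = make_reference(100_000, 20, seed=101)
    clones = two_clone_profiles(20, 5, gain_copy_number=3)
    cfg = SimConfig(rng_seed=101)
    paths, labels = simulate_dataset(ref, clones, cfg, out)
    counts = count_dataset(paths, k=15)
    abundance, report = preprocess(counts)
    return {
        "labels": dict(zip(labels.cell_id, labels.clone_id)),
        "counts_report": report,
        "abundance": abundance,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
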