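"""Shared fixtures: simulated studies reused across the test modules.

Everything is generated at import-free session scope with fixed seeds so
the suite is deterministic and the expensive simulations run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ewaskit.ewas import run_cohort_ewas
from ewaskit.meta import run_meta
from ewaskit.simulate import (
    SimulationConfig,
    generate_cohorts,
    generate_manifest,
    null_config,
)

STUDY_SEED = 7
NULL_SEED = 11


def two_cohort_config(**overrides) -> SimulationConfig:
    """Small balanced two-cohort template for targeted experiments."""
    base = dict(
        n_cohorts=2,
        cohort_names=("A", "B"),
        cohort_sizes=(500, 500),
        smoking_fractions=((0.3, 0.2, 0.5),) * 2,
        female_fractions=(0.5, 0.5),
        age_means=(50.0, 50.0),
        age_sds=(5.0, 5.0),
        family_cohort=(False, False),
        n_probes=200,
        n_spiked=0,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def study():
    """Default-structure five-cohort discovery study with spiked effects.

    2500 probes, 30 spiked (4 heterogeneous), Table-like cohort sizes,
    one family cohort fitted with the mixed model. Returns a dict with
    the manifest, datasets, truth, per-cohort results and the MetaResult.
    """
    manifest = generate_manifest(2500, seed=STUDY_SEED)
    cfg = SimulationConfig(
        n_probes=2500, n_spiked=30, n_heterogeneous=4, seed=STUDY_SEED
    )
    datasets, truth = generate_cohorts(cfg, manifest)
    results = []
    for i, d in enumerate(datasets):
        mixed = bool(cfg.family_cohort[i])
        results.append(
            run_cohort_ewas(d, "current_vs_never", use_mixed=mixed, include_age=mixed)
        )
    meta = run_meta(results, manifest=manifest)
    return {
        "config": cfg,
        "manifest": manifest,
        "datasets": datasets,
        "truth": truth,
        "cohort_results": results,
        "meta": meta,
    }


@pytest.fixture(scope="session")
def null_run():
    """Balanced five-cohort null study (no spiked probes), 5000 probes."""
    cfg = null_config(n_probes=5000, seed=NULL_SEED)
    manifest = generate_manifest(5000, seed=NULL_SEED)
    datasets, truth = generate_cohorts(cfg, manifest)
    results = [run_cohort_ewas(d, "current_vs_never") for d in datasets]
    meta = run_meta(results, manifest=manifest)
    return {
        "config": cfg,
        "manifest": manifest,
        "datasets": datasets,
        "cohort_results": results,
        "meta": meta,
    }


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 200-probe two-cohort dataset for I/O and plumbing tests."""
    manifest = generate_manifest(200, seed=3)
    cfg = two_cohort_config(n_probes=200, n_spiked=5, seed=3, cohort_sizes=(60, 60))
    datasets, truth = generate_cohorts(cfg, manifest)
    return {"manifest": manifest, "datasets": datasets, "truth": truth, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
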