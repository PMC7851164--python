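"""Shared fixtures: meshes, synthetic cohorts, and heavyweight batches.

Expensive simulation batches (null-calibration fits, the recovery pipeline
run) are session-scoped so that several tests can assert different
properties of one computation.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from asymtraj.cohort import (
    CohortDesign, CognitionDesign, assign_truth_clusters, simulate_cohort,
)
from asymtraj.gamm import fit_factor_smooth
from asymtraj.mesh import build_icosphere

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def sphere_small():
    return build_icosphere(1, radius=49.0)


@pytest.fixture(scope="session")
def sphere_medium():
    return build_icosphere(2, radius=49.0)


def make_single_vertex_frame(rng, n_subjects=150, sd_subject=0.25,
                             sd_resid=0.05, diff=None, trend=None):
    """Two-rows-per-scan long frame for one vertex."""
    if trend is None:
        trend = lambda a: 2.8 - 0.005 * (a - 20.0)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0.0, sd_subject)
        n_tp = rng.choice([1, 2, 3], p=[0.3, 0.5, 0.2])
        age = rng.uniform(20.0, 87.0)
        for tp in range(n_tp):
            if tp:
                age += 2.7
            base = trend(age) + u
            d = diff(age) if diff else 0.0
            for hemi, sign in (("L", 0.5), ("R", -0.5)):
                noise = rng.normal(0.0, sd_resid) if sd_resid > 0 else 0.0
                rows.append((f"s{s}", age, hemi, base + sign * d + noise))
    return pd.DataFrame(rows, columns=["subject", "age", "hemisphere", "y"])


@pytest.fixture(scope="session")
def null_difference_pvalues():
    """500 single-vertex fits with no true LH/RH difference.

    Used both for the type-I-error band and for the null p-value
    uniformity check.
    """
    pvals = []
    for rep in range(500):
        rng = np.random.default_rng(20_000 + rep)
        frame = make_single_vertex_frame(rng)
        model = fit_factor_smooth(
            frame["y"], frame["age"], frame["hemisphere"], frame["subject"]
        )
        pvals.append(model.difference_test().pvalue)
    return np.asarray(pvals)


@pytest.fixture(scope="session")
def small_cohort(sphere_medium):
    """Discovery-style synthetic cohort on the 162-vertex sphere."""
    truth = assign_truth_clusters(sphere_medium, 3, 0.4, seed=301)
    dataset = simulate_cohort(
        sphere_medium, truth, CohortDesign(n_subjects=120), seed=302,
        cognition=CognitionDesign(),
    )
    return sphere_medium, truth, dataset


@pytest.fixture(scope="session")
def small_pipeline_run(tmp_path_factory):
    """One end-to-end pipeline run on the 162-vertex sphere."""
    from asymtraj.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline_small")
    config = PipelineConfig(
        output_dir=str(out), seed=7, icosphere_subdivisions=2,
        cohort={"n_subjects": 120}, cognition={},
        n_permutations=499, n_replications=0,
        n_initial_rois=6, n_main_rois=3,
    )
    report = run_pipeline(config)
    return config, report, out
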