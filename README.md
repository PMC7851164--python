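# asymtraj

Analysis pipeline for **longitudinal change in cortical thickness
asymmetry**: does the left–right thickness difference at homotopic surface
locations change with age, where, in what direction, and is that change
accelerated in Alzheimer's disease?

The package is written for researchers who have longitudinal surface-based
thickness data in homotopic left/right correspondence (e.g. from a
symmetric-template registration) and want a tested, reproducible
implementation of the full analysis chain — and for methodologists who want
to study its statistical behavior on synthetic cohorts with known ground
truth, which the package generates itself.

## The model

At every vertex, thickness is modeled with a **factor-smooth generalized
additive mixed model**: one penalized smooth age trajectory per hemisphere,
estimated as an average smooth and a difference smooth,

```
y_ih = β0 + βH·h + covariates + f_avg(age_i) + h·f_diff(age_i) + b_subj(i) + ε_ih
```

with hemisphere coded `h = ±1/2` (LH positive), so `f_diff(age)` **is** the
demeaned LH−RH asymmetry trajectory and `βH` the mean asymmetry. Smooths are
cubic regression splines with basis dimension `k = 6`; smoothing parameters
and the subject random-intercept variance are selected by REML. The age ×
hemisphere interaction ("does asymmetry change with age?") is tested by a
Wald F test on the difference-smooth block; vertex-wise p-values are
FDR-corrected (Benjamini–Hochberg), maps are masked at `p(FDR) < 0.001`, and
components smaller than a minimum surface area are removed.

Significant vertices are then clustered by trajectory shape: the
dissimilarity between two vertices is the sum of squared differences of
their asymmetry trajectories over a shared age grid, partitioned around
medoids (PAM) for K = 2…7, with the partition chosen by mean silhouette
width. Replication in an independent cohort is quantified by mean Dice
overlap of the matched cluster maps against a label-permutation null.
Cluster-derived ROIs feed per-hemisphere trajectory plots (with a 6-SD
residual outlier pass and percent-change curves), longitudinal
cognition models, and clinical NC-vs-AD group × time linear mixed tests.

## Worked example

A synthetic discovery analysis on a 162-vertex sphere, with three contiguous
patches whose left/right trajectories diverge nonlinearly with age:

```python
import numpy as np
from asymtraj import (build_icosphere, assign_truth_clusters, simulate_cohort,
                      CohortDesign, run_vertexwise, threshold_and_filter,
                      compute_dissimilarity, select_solution)

mesh = build_icosphere(subdivisions=2, radius=49.0)      # 162-vertex sphere
truth = assign_truth_clusters(mesh, n_clusters=3, coverage_fraction=0.4, seed=1)
cohort = simulate_cohort(mesh, truth, CohortDesign(n_subjects=120), seed=2)
print(f"{cohort.n_obs} scans from {cohort.observations.subject.nunique()} "
      f"subjects, {cohort.n_vertices} vertices")

maps, trajs = run_vertexwise(cohort, mesh, k=6, grid=100)
mask = threshold_and_filter(maps, mesh, alpha=0.001, min_area_fraction=0.01)
print(f"significant vertices after FDR + extent filter: {mask.sum()}")

D, ids = compute_dissimilarity(trajs, mask)
best, table = select_solution(D, range(2, 8), vertex_ids=ids, trajs=trajs)
print(f"selected K = {best.K}, mean silhouette = {best.mean_silhouette:.3f}")

from sklearn.metrics import adjusted_rand_score
on_truth = truth.vertex_cluster_label[best.vertex_ids] > 0
ari = adjusted_rand_score(truth.vertex_cluster_label[best.vertex_ids][on_truth],
                          best.labels[on_truth])
print(f"adjusted Rand index vs ground truth: {ari:.3f}")
```

printed output:

```
225 scans from 120 subjects, 162 vertices
significant vertices after FDR + extent filter: 66
selected K = 3, mean silhouette = 0.974
adjusted Rand index vs ground truth: 1.000
```

Reading: the cohort has 120 subjects with 1–3 visits each (225 scans). Of
162 vertices, 66 survive the interaction test at `p(FDR) < 0.001` plus the
extent filter — these are the vertices inside the three simulated patches.
Silhouette-based model selection picks K = 3, and the partition reproduces
the generating patch structure exactly (adjusted Rand index 1.0).

The same analysis is available as a CLI over a YAML config:

```bash
asymtraj simulate --out cohort/ --seed 1 --subjects 120 --subdivisions 2
asymtraj validate --cohort-dir cohort/
asymtraj run --config analysis.yaml --out results/
```

Core model classes follow the scikit-learn estimator protocol
(`FactorSmoothGAMM(k=6).fit(X, y)`, `PAM(n_clusters=3).fit(D)` with
precomputed dissimilarities), so they compose with sklearn tooling.

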