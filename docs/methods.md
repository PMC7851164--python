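# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `asymtraj`.

## The factor-smooth model of hemispheric thickness trajectories

Each scan contributes one left-hemisphere and one right-hemisphere row.
With hemisphere coded h = +1/2 (LH) / −1/2 (RH), the model at a vertex (or
for an ROI mean) is

    y = β0 + βH·h + covariates + f_avg(age) + h·f_diff(age) + b_subject + ε,

so the two hemisphere trajectories are f_L = f_avg + ½f_diff and
f_R = f_avg − ½f_diff, the fitted f_diff is directly the demeaned LH−RH
asymmetry trajectory, and βH is the mean asymmetry in mm. Covariates (sex,
scanner) enter as fixed effects; b_subject is a subject random intercept;
ε is i.i.d. Gaussian. No within-scan LH/RH residual correlation or
per-subject asymmetry random effect is modeled — the random structure is a
single intercept per subject.

**Basis.** Both smooths use cubic regression splines in the cardinal
(natural-spline) construction: k knots at evenly spaced quantiles of the
observed unique ages, coefficients equal to the function values at the
knots, natural-cubic-spline interpolation between knots and linear
extrapolation beyond them. The roughness penalty is the integrated squared
second derivative, rank k−2 with a linear null space. A sum-to-zero
constraint over the observed ages is absorbed by an orthogonal
reparameterization, leaving k−1 = 5 identifiable coefficients per smooth at
the default k = 6 (kept low to limit overfitting of lifespan trajectories).

**Estimation.** Smoothing parameters, the random-intercept variance and σ²
are selected by restricted maximum likelihood. σ² is profiled out
analytically; the profiled REML criterion is minimized over the log
smoothing parameters with Nelder–Mead (relative tolerance 1e-8, multi-start
and fresh-simplex fallbacks on non-convergence). Two numerical devices keep
this robust and fast:

- a gentle quadratic barrier on |log λ| > 18 restores curvature in the
  asymptotically flat linear/unshrunk limits, where the simplex otherwise
  stalls (λ = e^18 is far past the point where a smooth is numerically
  linear);
- when the random-intercept block is contiguous, identity-penalized and has
  a diagonal normal-equation block (always true here — each row belongs to
  one subject), the criterion is evaluated by Schur-complement elimination
  of the subject columns, so the per-evaluation cost scales with the ~14
  dense columns rather than with the number of subjects. The generic and
  eliminated evaluations agree to ~1e-10 and the final covariance is always
  computed on the full system.

The accepted-step REML trace is recorded and is non-increasing by
construction; tests assert it.

**The age × hemisphere interaction test.** Because every scan contributes
both hemispheres, the difference-smooth design block (h·B columns, plus the
h column itself) is exactly orthogonal to every hemisphere-symmetric term
(intercept, covariates, average smooth, subject dummies). The default test
exploits this: the difference block is refit without its roughness penalty
(other smoothing parameters held at their REML estimates) and the classical
Wald F on the full block — equivalent to a regression F test of the
within-scan LH−RH differences on the spline basis — is referenced to
F(k−1, n−EDF). Its null p-values are exactly uniform under the model
(measured: rejection 0.048 at α = 0.05 and Kolmogorov–Smirnov p = 0.52
against uniform over 500 null replicates) because no data-driven rank or
smoothing selection enters the statistic.

The EDF-based Wald test on the penalized fit (rank-truncated pseudo-inverse
with a fractional-EDF two-by-two correction and a chi-square-mixture
reference) is also implemented (`difference_test(method="penalized")`).
It is tail-calibrated but mildly mid-range anti-conservative, because the
truncation rank is selected from the same data; this behavior is shared by
the standard R implementation of the same test (verified empirically on
identical data designs) and is why it is not the default. The hemisphere
main effect is tested two-sided by a t statistic on βH.

**Trajectory extraction.** Fitted curves, their pointwise standard errors
(from the Bayesian coefficient covariance) and the asymmetry trajectory are
evaluated on an age grid via the linear-predictor construction; adding βH
gives the absolute asymmetry trajectory. The default grid is 100 equally
spaced points over the observed age range — dense enough that the
clustering dissimilarities are grid-stable.

## Vertex-wise mapping, FDR and extent filtering

The design matrix depends only on the cohort table, so it is assembled once
and refit against each vertex's thickness values; the REML start point is
fixed for all vertices by a preliminary fit to the surface-mean signal.
Results are therefore independent of vertex processing order. Interaction
and hemisphere-effect maps are FDR-adjusted with Benjamini–Hochberg
(valid under positive regression dependency; Benjamini–Yekutieli is
available), each map across its analyzed vertices. The significance mask at
p(FDR) < 0.001 is cleaned by removing connected components below a minimum
surface area — 300 mm² at cortical scale, or a configurable fraction
(default 1%) of total area for small synthetic meshes. Vertex areas use
barycentric lumping (one third of each incident triangle); adjacency is
shared-edge.

## Trajectory clustering and model selection

The dissimilarity between two retained vertices is the sum over grid ages
of squared differences of their demeaned asymmetry trajectories; mean
asymmetry offsets do not influence it. Partitioning around medoids runs
BUILD (greedy cost-minimizing medoid additions) followed by best-improvement
SWAP passes. Because the swap neighborhood has genuine local optima even on
small instances, the search restarts deterministically from the ten
lowest-total-dissimilarity first medoids and keeps the best converged
solution; this reaches the exhaustive optimum on ≥95% of random small
instances while remaining fully deterministic. K = 2…7 are fit and the
partition with the highest mean silhouette width wins (ties toward smaller
K); cluster ids are renumbered by descending trajectory value at the
youngest grid age so that "cluster 1" is always the most
leftward-asymmetric-in-youth family.

## Replication

A replication cohort is analyzed with the same vertex-wise model; its
trajectories are clustered over exactly the discovery vertex set at the
discovery K. Cluster labels are matched by maximum-total-overlap assignment
(Hungarian algorithm; ties broken by total Dice, which makes the result
invariant to relabeling), per-label Dice coefficients and their mean are
reported, and significance comes from permuting one map's vertex labels
(label counts preserved): p = (1 + #{null ≥ observed})/(1 + n_perm), with
10,000 permutations by default. With matching disabled, the permutation
null mean has the closed form 2·n_Al·n_Bl/(N(n_Al+n_Bl)) averaged over
labels, used as an oracle in tests. Label permutation ignores spatial
autocorrelation; a spatially constrained null (spin/variogram) is out of
scope and the p-values should be read accordingly.

## ROI analyses

Cluster labels are split into connected components; the 13 largest are
ranked by the equal-weight sum of an area rank and a mean-|LH−RH| rank, and
the top 8 become the main ROIs (both counts configurable; the rank-sum rule
is this package's formalization of "size and degree of asymmetry").
Per ROI, hemisphere trajectories are fit to ROI-mean thickness, scans with
residuals ≥ 6 SD in either hemisphere are removed from both hemispheres,
and the model is refit once (fixed-point iteration available by flag).
Percent change rescales each fitted trajectory by its value at the youngest
grid age.

**Cognition.** The verbal-memory composite is the first principal component
of z-scored learning/immediate/delayed recall scores, sign-oriented so the
delayed-recall loading is positive. Per ROI and measure, an additive mixed
model with smooth terms for ROI asymmetry, mean thickness and age (sex and
test version controlled, subject random intercept) tests the asymmetry
smooth; p-values are FDR-corrected over the ROI × measure family. Age's
variance share is the population-level R² drop (fitted values excluding
subject intercepts) when the age smooth is removed. The joint model adds
all ROI asymmetry smooths to the age base model; its likelihood-ratio
statistic is referenced to a chi-square with the **full dimension** of the
added blocks, not their EDF — the penalized improvement is bounded by the
unpenalized one, so this reference is valid though conservative, whereas an
EDF-based df is anti-conservative because the smoothing parameters are
selected from the same data (measured on null simulations).

**Clinical.** Longitudinal groups come from diagnosis sequences with
severity NC < MCI < AD: any severity decrease excludes the subject;
all-normal sequences are NC-long; sequences ending in AD are AD-long;
ending at MCI excludes. When only birth year is known, age is computed from
July 1 of the birth year plus a uniform ±0.5-year jitter, deterministic per
(subject, seed). Per ROI, asymmetry is modeled as
Group + Time + Group×Time + baseline age + sex + scanner with a subject
random intercept (REML via statsmodels MixedLM; a singular subject variance
falls back to OLS with cluster-robust errors, with a warning); the two-sided
Group×Time p-values are BH-FDR-corrected across ROIs.

## The synthetic-data generator

The generator emulates a multi-site longitudinal lifespan study:

- **Ages** 20–90 from the mixture 0.45·U(20,45) + 0.15·U(45,60) +
  0.40·U(60,90), reproducing a bimodal lifespan histogram with
  mid-adulthood underrepresented; 1/2/3 visits with probabilities
  0.3/0.5/0.2 and follow-up intervals ~N(2.7, 0.8²) years (truncated at
  0.5; late follow-ups may run slightly past 90).
- **True trajectories** are piecewise linear-plus-quadratic per hemisphere,
  thickness = baseline + slope·(age−20) + accel·max(0, age−60)², chosen
  deliberately outside the spline family so recovery tests cannot commit an
  inverse crime. The default three families are: leftward asymmetry
  (+0.2 mm at age 20) lost through faster LH thinning with extra
  acceleration past 60, crossing zero in the mid 70s; a weak/mixed leftward
  family; and the mirror rightward-loss family. Background vertices have
  identical LH/RH parameters. Truth patches are grown by seeded
  breadth-first region growing to a target area fraction (default 3
  clusters, 40% coverage), contiguous and disjoint.
- **Noise structure**: subject random intercept SD 0.25 mm, per-subject
  asymmetry offset SD 0.05 mm, sex offset 0.04 mm, two scanners with a
  0.02 mm offset, and residual SD 0.05 mm applied as white vertex noise
  smoothed 3 iterations on the mesh (rescaled to preserve the marginal SD),
  so significance maps face spatially correlated noise as real smoothed
  thickness maps do.
- **Cognition**: a latent trait declines monotonically (and faster past 60)
  with age; subtests are loadings times the trait plus uniqueness. The
  latent age-R² is analytically inflated by the PC1 attenuation factor
  L²/(L²+U²) so that the *emitted composite* hits the configured age-R²
  (default 0.30). Cognition is generated independently of asymmetry given
  age unless an asymmetry effect is configured.
- **Clinical cohort**: 41 AD-long vs 128 NC-long subjects with 2–4 visits
  1.6 years apart, monotone diagnosis sequences (a configurable reversion
  rate exists only to exercise group derivation), a common baseline
  asymmetry and slope, and a group-specific additional slope (default
  −0.004 mm/year) in the affected ROIs.

Everything is deterministic given a seed (byte-identical tables).

**What passing tests do and do not show.** The generator's covariance
structure matches the fitted model (plus the asymmetry offset and spatial
noise smoothing it omits), so recovery and calibration results demonstrate
correctness of the implementation, not robustness to real-data violations:
registration error, site-by-age interactions, non-Gaussian thickness noise,
survivor bias and diagnosis error are all absent. The synthetic mesh is a
sphere at ~1% of cortical vertex count; extent thresholds scale by area
fraction accordingly.

## Default problem sizes

The acceptance computation uses a 642-vertex sphere with 250 subjects for
the discovery and replication cohorts, 500 replicates for null calibration
of the interaction test, 2,000 Dice permutations in the pipeline (10,000 is
the analysis default), and 200 + 100 clinical simulations; these sizes give
Monte-Carlo error comfortably below the tolerances tested while keeping a
full run under ten minutes on one core.

## Known limitations

- Tensor-product smooths, non-Gaussian families and autocorrelated
  residuals are out of scope; so are cortical reconstruction, symmetric
  template construction, inter-resolution resampling and cluster-based
  inference (TFCE or cluster-mass permutation).
- The interaction test's exact calibration relies on the LH/RH design
  pairing; with missing single-hemisphere rows it reduces to the usual
  approximate Wald behavior.
- The label-permutation Dice null underestimates chance agreement under
  strong spatial autocorrelation of the cluster maps.
- PAM with deterministic restarts is a local search; global optimality is
  verified only on small instances against exhaustive search.
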