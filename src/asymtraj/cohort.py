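"""Synthetic longitudinal cohorts with known asymmetry-trajectory structure.

The generator emulates the statistical structure of a multi-visit adult
lifespan MRI study: a bimodal 20-90 age distribution with mid-adulthood
underrepresented, one to three visits per subject with a ~2.7-year mean
follow-up interval, spatially contiguous cortical patches whose left and
right mean thickness trajectories diverge nonlinearly with age, subject
random intercepts, sex and scanner offsets, and spatially smoothed
measurement noise.  Alongside thickness it can generate longitudinal
cognitive scores with a configured age-driven variance share and a clinical
cohort with diagnosis sequences and a group-specific asymmetry slope.

The true hemispheric trajectories are piecewise linear-plus-quadratic with
a breakpoint (default age 60) — deliberately *not* splines, so recovery
tests never share the fitting basis with the truth:

    thickness(age) = baseline + slope * (age - 20) +
                     accel * max(0, age - break)^2
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh, connected_components, smooth_vertex_data

AGE_MIN, AGE_MAX = 20.0, 90.0


@dataclass
class HemiParams:
    """One hemisphere's trajectory parameters (mm, mm/year, mm/year^2)."""

    baseline: float
    slope: float
    accel: float = 0.0

    def thickness(self, age) -> np.ndarray:
        age = np.asarray(age, float)
        t = (self.baseline + self.slope * (age - AGE_MIN)
             + self.accel * np.maximum(0.0, age - TrajectoryParams.BREAK) ** 2)
        return t


@dataclass
class TrajectoryParams:
    """Left/right trajectory pair for one cluster (or the background)."""

    BREAK = 60.0

    left: HemiParams
    right: HemiParams

    def asymmetry(self, age) -> np.ndarray:
        return self.left.thickness(age) - self.right.thickness(age)

    def validate(self) -> None:
        ages = np.linspace(AGE_MIN, AGE_MAX, 201)
        for hemi in (self.left, self.right):
            t = hemi.thickness(ages)
            if t.min() <= 0.5 or t.max() >= 5.5:
                raise ValueError(
                    "implied thickness leaves the plausible (0.5, 5.5) mm band"
                )


def default_cluster_params() -> dict[int, TrajectoryParams]:
    """Three trajectory families plus a symmetric background (label 0).

    Cluster 1: leftward asymmetry in young adulthood lost with age (LH thins
    faster, extra acceleration past 60, trajectories cross in the mid 70s).
    Cluster 2: weak/mixed leftward loss.  Cluster 3: mirror of cluster 1 —
    rightward asymmetry lost through faster RH thinning.
    """
    return {
        0: TrajectoryParams(HemiParams(2.80, -0.0050, -5e-5),
                            HemiParams(2.80, -0.0050, -5e-5)),
        1: TrajectoryParams(HemiParams(2.90, -0.0070, -11e-5),
                            HemiParams(2.70, -0.0035, -6e-5)),
        2: TrajectoryParams(HemiParams(2.84, -0.0058, -7e-5),
                            HemiParams(2.76, -0.0048, -5e-5)),
        3: TrajectoryParams(HemiParams(2.70, -0.0035, -6e-5),
                            HemiParams(2.90, -0.0070, -11e-5)),
    }


@dataclass
class GroundTruth:
    """Vertex cluster labels and the generating parameters."""

    vertex_cluster_label: np.ndarray          # 0 = background, 1..C clusters
    cluster_params: dict[int, TrajectoryParams]
    subject_intercepts: dict = field(default_factory=dict)
    subject_asym_offsets: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.vertex_cluster_label.max())

    def asymmetry_curve(self, label: int, ages) -> np.ndarray:
        return self.cluster_params[label].asymmetry(ages)


@dataclass
class CohortDataset:
    """Long-format scan observations with paired LH/RH vertex thickness."""

    observations: pd.DataFrame       # subject, age, sex, scanner, timepoint
    thickness_lh: np.ndarray         # (n_obs, n_vertices) mm
    thickness_rh: np.ndarray
    cognition: pd.DataFrame | None = None

    def __post_init__(self):
        if self.thickness_lh.shape != self.thickness_rh.shape:
            raise ValueError("LH/RH thickness arrays must share shape")
        if len(self.observations) != self.thickness_lh.shape[0]:
            raise ValueError("observations/thickness row mismatch")
        ages = self.observations.groupby("subject")["age"].apply(
            lambda a: bool(np.all(np.diff(a.to_numpy()) > 0))
        )
        if not ages.all():
            raise ValueError("ages must be strictly increasing within subject")

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    @property
    def n_vertices(self) -> int:
        return self.thickness_lh.shape[1]

    def asymmetry(self) -> np.ndarray:
        return self.thickness_lh - self.thickness_rh

    def to_long(self, vertex: int) -> tuple[pd.DataFrame, np.ndarray]:
        """Stack one vertex into the two-rows-per-scan long format."""
        obs = self.observations
        frames = []
        for hemi, arr in (("L", self.thickness_lh), ("R", self.thickness_rh)):
            f = obs[["subject", "age", "sex", "scanner"]].copy()
            f["hemisphere"] = hemi
            f["y"] = arr[:, vertex]
            frames.append(f)
        long = pd.concat(frames, ignore_index=True)
        return long.drop(columns="y"), long["y"].to_numpy()


# ---------------------------------------------------------------------------
# design configuration


@dataclass
class CohortDesign:
    """Study-design knobs of the thickness generator."""

    n_subjects: int = 250
    timepoint_probs: tuple = (0.3, 0.5, 0.2)    # P(1), P(2), P(3) visits
    followup_mean: float = 2.7                  # years between visits
    followup_sd: float = 0.8
    sigma_subject: float = 0.25                 # random-intercept SD (mm)
    sigma_asym_subject: float = 0.05            # per-subject asymmetry SD (mm)
    sigma_noise: float = 0.05                   # residual SD per vertex (mm)
    noise_smooth_iterations: int = 3            # spatial smoothing of noise
    sex_offset: float = 0.04                    # additive male-female (mm)
    scanner_offsets: tuple = (0.0, 0.02)        # additive per scanner (mm)
    # bimodal adult-lifespan age mixture: young / middle / older
    age_bins: tuple = ((20.0, 45.0), (45.0, 60.0), (60.0, 90.0))
    age_weights: tuple = (0.45, 0.15, 0.40)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        probs = np.asarray(self.timepoint_probs, float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("timepoint probabilities must be >= 0 and sum to 1")
        for name in ("sigma_subject", "sigma_asym_subject", "sigma_noise",
                     "followup_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(sum(self.age_weights) - 1.0) > 1e-9:
            raise ValueError("age weights must sum to 1")


@dataclass
class CognitionDesign:
    """Cognitive-score generator: age-driven decline plus subject effects.

    ``age_r2`` is the share of total score variance attributable to the age
    trend under the cohort's age distribution.
    """

    age_r2: float = 0.30
    subject_sd_frac: float = 0.4      # subject-intercept share of non-age SD
    n_versions: int = 2               # test versions (nuisance factor)
    loadings: tuple = (0.9, 0.95, 0.85)   # learning/immediate/delayed on PC
    asymmetry_effect: float = 0.0     # per-mm effect of ROI asymmetry on score

    def validate(self) -> None:
        if not 0.0 <= self.age_r2 < 1.0:
            raise ValueError("age_r2 must be in [0, 1)")


# ---------------------------------------------------------------------------
# truth-cluster assignment


def assign_truth_clusters(
    mesh: SurfaceMesh,
    n_clusters: int,
    coverage_fraction: float,
    seed: int,
    cluster_params: dict[int, TrajectoryParams] | None = None,
) -> GroundTruth:
    """Seeded region growing of contiguous, disjoint truth patches.

    Random seed vertices are grown breadth-first (largest-deficit patch
    first) until the requested fraction of total surface area is labeled.
    If growth is blocked (patches collide) before reaching the target, a
    warning is issued and the reachable labeling is returned.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if not 0.0 < coverage_fraction < 1.0:
        raise ValueError("coverage_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = mesh.n_vertices
    areas = mesh.vertex_area
    target_each = coverage_fraction * areas.sum() / n_clusters
    labels = np.zeros(n, dtype=int)
    # spread seeds: random first seed, then greedily far-apart seeds
    seeds = [int(rng.integers(n))]
    coords = mesh.coords
    while len(seeds) < n_clusters:
        d = np.min(
            [np.linalg.norm(coords - coords[s], axis=1) for s in seeds], axis=0
        )
        # sample among the farthest decile for reproducible spread with jitter
        cand = np.argsort(d)[-max(1, n // 10):]
        seeds.append(int(rng.choice(cand)))
    frontier: dict[int, list[int]] = {}
    grown_area = {c: 0.0 for c in range(1, n_clusters + 1)}
    for c, s in enumerate(seeds, start=1):
        labels[s] = c
        grown_area[c] = float(areas[s])
        frontier[c] = [s]
    blocked: set[int] = set()
    while len(blocked) < n_clusters:
        deficits = {
            c: target_each - grown_area[c]
            for c in grown_area if c not in blocked
        }
        if not deficits or max(deficits.values()) <= 0:
            break
        c = max(deficits, key=deficits.get)
        candidates = []
        for v in frontier[c]:
            candidates.extend(
                w for w in mesh.neighbors(v) if labels[w] == 0
            )
        candidates = sorted(set(candidates))
        if not candidates:
            blocked.add(c)
            continue
        w = int(rng.choice(candidates))
        labels[w] = c
        grown_area[c] += float(areas[w])
        frontier[c].append(w)
    if len(blocked) == n_clusters and any(
        target_each - grown_area[c] > areas.mean() for c in grown_area
    ):
        warnings.warn("cluster growth blocked before reaching target coverage")
    params = cluster_params or default_cluster_params()
    missing = set(range(n_clusters + 1)) - set(params)
    if missing:
        raise ValueError(f"missing trajectory parameters for labels {missing}")
    return GroundTruth(vertex_cluster_label=labels, cluster_params=params)


# ---------------------------------------------------------------------------
# thickness + cognition simulation


def _sample_ages(rng: np.random.Generator, n: int, design: CohortDesign):
    bins = np.asarray(design.age_bins, float)
    which = rng.choice(len(bins), size=n, p=np.asarray(design.age_weights))
    return rng.uniform(bins[which, 0], bins[which, 1])


def simulate_cohort(
    mesh: SurfaceMesh,
    truth: GroundTruth,
    design: CohortDesign | None = None,
    seed: int = 0,
    cognition: CognitionDesign | None = None,
) -> CohortDataset:
    """Simulate a longitudinal thickness cohort from the ground truth.

    thickness(obs, v, hemi) = truth trajectory(age, hemi, cluster of v)
      + subject intercept + hemi-signed subject asymmetry offset / 2
      + sex offset + scanner offset + spatially smoothed noise.

    Baseline ages follow the configured lifespan mixture; follow-up visits
    are spaced by a truncated-normal interval (mean 2.7 y).  The result is
    byte-deterministic for a fixed seed.
    """
    design = design or CohortDesign()
    design.validate()
    for p in truth.cluster_params.values():
        p.validate()
    rng = np.random.default_rng(seed)
    n_subj = design.n_subjects
    n_tp = rng.choice(
        np.arange(1, len(design.timepoint_probs) + 1),
        size=n_subj, p=np.asarray(design.timepoint_probs),
    )
    base_age = _sample_ages(rng, n_subj, design)
    sex = rng.integers(0, 2, size=n_subj)
    scanner = rng.integers(0, len(design.scanner_offsets), size=n_subj)
    u_subj = rng.normal(0.0, design.sigma_subject, size=n_subj)
    u_asym = (rng.normal(0.0, design.sigma_asym_subject, size=n_subj)
              if design.sigma_asym_subject > 0 else np.zeros(n_subj))

    rows = []
    for s in range(n_subj):
        age = float(np.clip(base_age[s], AGE_MIN, AGE_MAX - 0.01))
        for tp in range(int(n_tp[s])):
            if tp > 0:
                # follow-ups may run slightly past the nominal upper age
                gap = max(0.5, rng.normal(design.followup_mean, design.followup_sd))
                age = age + gap
            rows.append((f"sub-{s:04d}", age, int(sex[s]),
                         f"scanner{scanner[s]}", tp))
    obs = pd.DataFrame(
        rows, columns=["subject", "age", "sex", "scanner", "timepoint"]
    )
    n_obs = len(obs)
    nv = mesh.n_vertices
    labels = truth.vertex_cluster_label
    ages = obs["age"].to_numpy()

    th_lh = np.empty((n_obs, nv))
    th_rh = np.empty((n_obs, nv))
    for lab in np.unique(labels):
        cols = labels == lab
        pars = truth.cluster_params[int(lab)]
        th_lh[:, cols] = pars.left.thickness(ages)[:, None]
        th_rh[:, cols] = pars.right.thickness(ages)[:, None]

    subj_idx = obs["subject"].str.slice(4).astype(int).to_numpy()
    common = (u_subj[subj_idx]
              + design.sex_offset * obs["sex"].to_numpy()
              + np.asarray(design.scanner_offsets)[
                  obs["scanner"].str.slice(7).astype(int).to_numpy()])
    th_lh += common[:, None] + 0.5 * u_asym[subj_idx][:, None]
    th_rh += common[:, None] - 0.5 * u_asym[subj_idx][:, None]

    if design.sigma_noise > 0:
        for arr in (th_lh, th_rh):
            noise = rng.standard_normal((n_obs, nv))
            if design.noise_smooth_iterations > 0:
                noise = smooth_vertex_data(
                    mesh, noise, design.noise_smooth_iterations
                )
                # restore unit marginal SD after averaging
                noise /= max(noise.std(), 1e-12)
            arr += design.sigma_noise * noise

    if np.any(th_lh <= 0) or np.any(th_rh <= 0):
        raise ValueError("simulated thickness non-positive; check parameters")

    truth.subject_intercepts = {
        f"sub-{s:04d}": float(u_subj[s]) for s in range(n_subj)
    }
    truth.subject_asym_offsets = {
        f"sub-{s:04d}": float(u_asym[s]) for s in range(n_subj)
    }

    cog = None
    if cognition is not None:
        cog = _simulate_cognition(rng, obs, cognition, truth, th_lh, th_rh)
    return CohortDataset(observations=obs, thickness_lh=th_lh,
                         thickness_rh=th_rh, cognition=cog)


def _cognitive_age_trend(age: np.ndarray) -> np.ndarray:
    """Monotone-declining latent ability trend (z-score units)."""
    a = np.asarray(age, float)
    return -0.025 * (a - AGE_MIN) - 0.0006 * np.maximum(0.0, a - 60.0) ** 2


def _simulate_cognition(rng, obs, design: CognitionDesign, truth,
                        th_lh, th_rh) -> pd.DataFrame:
    design.validate()
    ages = obs["age"].to_numpy()
    trend = _cognitive_age_trend(ages)
    var_age = float(np.var(trend))
    # calibrate the latent trait so the *emitted* composite hits the
    # configured age-R^2: subtest uniqueness attenuates the first principal
    # component by roughly L^2/(L^2 + U^2) with L = sum of loadings and
    # U^2 = total uniqueness
    r2 = design.age_r2
    loads = np.asarray(design.loadings, float)
    L2 = loads.sum() ** 2
    U2 = float(np.sum(1.0 - loads ** 2))
    atten = L2 / (L2 + U2)
    r2_lat = min(0.95, r2 / atten) if r2 > 0 else 0.0
    var_resid = (var_age * (1.0 - r2_lat) / r2_lat if r2_lat > 0 else 1.0)
    sd_subj = np.sqrt(var_resid) * design.subject_sd_frac
    sd_noise = np.sqrt(max(var_resid - sd_subj ** 2, 1e-12))
    subjects = obs["subject"].to_numpy()
    levels = pd.unique(subjects)
    u = dict(zip(levels, rng.normal(0.0, sd_subj, size=len(levels))))
    g = trend + np.array([u[s] for s in subjects])
    if design.asymmetry_effect != 0.0:
        mean_asym = (th_lh - th_rh).mean(axis=1)
        g = g + design.asymmetry_effect * mean_asym
    g = g + rng.normal(0.0, sd_noise, size=len(g))
    version = rng.integers(0, design.n_versions, size=len(g))
    out = obs[["subject", "age"]].copy()
    out["test_version"] = version
    sd_total = np.sqrt(var_age / r2_lat) if r2_lat > 0 else 1.0
    scale = 10.0  # raw-score units per z unit
    for name, load in zip(
        ("cvlt_learning", "cvlt_immediate", "cvlt_delayed"), design.loadings
    ):
        uniq = np.sqrt(max(1.0 - load ** 2, 0.0))
        out[name] = 50.0 + scale * (
            load * g + uniq * rng.normal(0.0, sd_total, size=len(g))
        )
    # fluid-reasoning score: high loading so its own age-R^2 matches the
    # configured target after the same attenuation logic
    m_load, m_uniq = 0.97, np.sqrt(1.0 - 0.97 ** 2)
    out["matrix_raw"] = 25.0 + 8.0 * (
        m_load * g + m_uniq * rng.normal(0.0, sd_total, size=len(g))
    )
    return out


# ---------------------------------------------------------------------------
# clinical cohort


@dataclass
class ClinicalDesign:
    """Clinical (dementia) cohort design."""

    n_ad: int = 41
    n_nc: int = 128
    visit_probs: tuple = (0.0, 0.5, 0.3, 0.2)    # P(1..4 visits); min 2
    visit_interval: float = 1.6                  # years
    base_slope: float = -0.001                   # mm/year asymmetry drift (NC)
    sigma_subject: float = 0.08
    sigma_noise: float = 0.03
    roi_base_asym: float = 0.15                  # mm leftward at baseline
    reversion_rate: float = 0.0                  # P(spurious severity decrease)
    birth_year_range: tuple = (1920, 1955)
    n_scanners: int = 2

    def validate(self) -> None:
        probs = np.asarray(self.visit_probs, float)
        if probs[0] != 0.0:
            raise ValueError("clinical subjects need >= 2 visits")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("visit probabilities must sum to 1")


@dataclass
class ClinicalDataset:
    """Longitudinal clinical rows with per-ROI asymmetry values."""

    rows: pd.DataFrame        # subject, timepoint, diagnosis, years_since_baseline,
                              # birth_year, test_date, sex, scanner, group_truth
    roi_asymmetry: pd.DataFrame   # one column per ROI (mm, LH-RH)
    affected_rois: list = field(default_factory=list)
    effect: float = 0.0


def simulate_clinical(
    rois: list[str],
    effect: float,
    design: ClinicalDesign | None = None,
    seed: int = 0,
    affected_rois: list[str] | None = None,
) -> ClinicalDataset:
    """Simulate the clinical cohort with a group-specific asymmetry slope.

    Subjects in the dementia group receive an asymmetry slope of
    ``base_slope + effect`` (mm/year) in the affected ROIs; controls the
    base slope everywhere.  Diagnosis sequences are monotone in severity
    (NC < MCI < AD) unless ``reversion_rate`` injects spurious reversions
    for group-derivation testing.
    """
    if not rois:
        raise ValueError("rois must be non-empty")
    if not np.isfinite(effect):
        raise ValueError("effect must be finite")
    design = design or ClinicalDesign()
    design.validate()
    affected = list(affected_rois) if affected_rois is not None else list(rois)
    unknown = set(affected) - set(rois)
    if unknown:
        raise ValueError(f"affected ROIs not in roi list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    asym_rows = []
    n_visits_choices = np.arange(1, len(design.visit_probs) + 1)
    for group, n_grp in (("AD", design.n_ad), ("NC", design.n_nc)):
        for i in range(n_grp):
            sid = f"{group.lower()}-{i:04d}"
            nv = int(rng.choice(n_visits_choices, p=np.asarray(design.visit_probs)))
            birth = int(rng.integers(*design.birth_year_range))
            sex = int(rng.integers(0, 2))
            scanner = f"scanner{rng.integers(0, design.n_scanners)}"
            u = rng.normal(0.0, design.sigma_subject)
            base_date_year = 2008 + rng.uniform(0, 4)
            if group == "AD":
                # progressive sequence ending in AD by the final visit
                onset = int(rng.integers(0, nv))
                diags = ["NC"] * onset + ["MCI"] * max(0, nv - onset - 1) + ["AD"]
                diags = diags[-nv:]
            else:
                diags = ["NC"] * nv
            if design.reversion_rate > 0:
                for t in range(1, nv):
                    if rng.uniform() < design.reversion_rate:
                        order = {"NC": 0, "MCI": 1, "AD": 2}
                        if order[diags[t - 1]] > 0:
                            diags[t] = "NC"
            for t in range(nv):
                years = t * design.visit_interval
                date_year = base_date_year + years
                rows.append((sid, t, diags[t], years, birth,
                             f"{int(date_year)}-{int(1 + (date_year % 1) * 12):02d}-15",
                             sex, scanner, f"{group}-long"))
                slope = design.base_slope
                vals = {}
                for roi in rois:
                    s = slope + (effect if (group == "AD" and roi in affected) else 0.0)
                    vals[roi] = (design.roi_base_asym + u + s * years
                                 + rng.normal(0.0, design.sigma_noise))
                asym_rows.append(vals)
    rows_df = pd.DataFrame(
        rows,
        columns=["subject", "timepoint", "diagnosis", "years_since_baseline",
                 "birth_year", "test_date", "sex", "scanner", "group_truth"],
    )
    asym_df = pd.DataFrame(asym_rows)
    return ClinicalDataset(rows=rows_df, roi_asymmetry=asym_df,
                           affected_rois=affected, effect=effect)


# ---------------------------------------------------------------------------
# on-disk layout


def save_cohort(dataset: CohortDataset, truth: GroundTruth | None,
                out_dir, seed: int | None = None) -> None:
    """Write observations.csv, per-hemisphere thickness matrices (TSV),
    optional cognition.csv and a truth.json sidecar."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.observations.to_csv(out / "observations.csv", index=False)
    np.savetxt(out / "thickness_lh.tsv", dataset.thickness_lh, delimiter="\t")
    np.savetxt(out / "thickness_rh.tsv", dataset.thickness_rh, delimiter="\t")
    if dataset.cognition is not None:
        dataset.cognition.to_csv(out / "cognition.csv", index=False)
    if truth is not None:
        payload = {
            "seed": seed,
            "vertex_cluster_label": truth.vertex_cluster_label.tolist(),
            "cluster_params": {
                str(k): asdict(v) for k, v in truth.cluster_params.items()
            },
            "subject_intercepts": truth.subject_intercepts,
            "subject_asym_offsets": truth.subject_asym_offsets,
        }
        (out / "truth.json").write_text(json.dumps(payload))


def load_cohort(in_dir) -> CohortDataset:
    from pathlib import Path

    d = Path(in_dir)
    obs = pd.read_csv(d / "observations.csv")
    lh = np.loadtxt(d / "thickness_lh.tsv", delimiter="\t", ndmin=2)
    rh = np.loadtxt(d / "thickness_rh.tsv", delimiter="\t", ndmin=2)
    cog = None
    if (d / "cognition.csv").exists():
        cog = pd.read_csv(d / "cognition.csv")
    return CohortDataset(observations=obs, thickness_lh=lh, thickness_rh=rh,
                         cognition=cog)


def load_truth(in_dir) -> GroundTruth:
    from pathlib import Path

    payload = json.loads((Path(in_dir) / "truth.json").read_text())
    params = {
        int(k): TrajectoryParams(HemiParams(**v["left"]), HemiParams(**v["right"]))
        for k, v in payload["cluster_params"].items()
    }
    gt = GroundTruth(
        vertex_cluster_label=np.asarray(payload["vertex_cluster_label"], int),
        cluster_params=params,
    )
    gt.subject_intercepts = payload.get("subject_intercepts", {})
    gt.subject_asym_offsets = payload.get("subject_asym_offsets", {})
    return gt
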