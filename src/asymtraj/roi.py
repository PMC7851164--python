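"""Region-of-interest analyses downstream of the trajectory clustering.

ROIs are connected components of the cluster partition ranked by surface
area and mean asymmetry magnitude.  Per ROI the package fits hemispheric
age trajectories (with a residual-based outlier pass and percent-change
curves), models longitudinal cognitive scores against asymmetry change,
and tests clinical groups for accelerated asymmetry change (Group x Time
linear mixed models with FDR correction).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import gamm as G
from .basis import build_basis
from .clustering import Partition
from .cohort import ClinicalDataset, CohortDataset
from .mesh import SurfaceMesh, connected_components
from .vertexwise import fdr_adjust


# ---------------------------------------------------------------------------
# ROI derivation


@dataclass
class ROISpec:
    roi_id: int
    source_cluster: int
    vertices: np.ndarray
    area_mm2: float
    mean_asym_mm: float          # cohort-mean |LH-RH| over ROI vertices


def derive_rois(
    partition: Partition,
    mesh: SurfaceMesh,
    dataset: CohortDataset,
    n_initial: int = 13,
    n_main: int = 8,
) -> list[ROISpec]:
    """Connected components of the partition ranked to main ROIs.

    Each cluster label is split into connected components; all components
    are ranked by area and the ``n_initial`` largest kept; those are then
    ranked by the equal-weight sum of area rank and asymmetry-magnitude
    rank, keeping ``n_main``.
    """
    labels = partition.labels_on_mesh(mesh.n_vertices)
    mean_asym_map = np.abs(
        (dataset.thickness_lh - dataset.thickness_rh).mean(axis=0)
    )
    comps = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        for members, area in connected_components(mesh, labels == lab):
            comps.append((int(lab), members, float(area),
                          float(mean_asym_map[members].mean())))
    comps.sort(key=lambda t: -t[2])
    if len(comps) < n_main:
        warnings.warn(
            f"only {len(comps)} connected components; returning all"
        )
    initial = comps[:n_initial]
    area_rank = {i: r for r, i in enumerate(
        sorted(range(len(initial)), key=lambda i: -initial[i][2]))}
    asym_rank = {i: r for r, i in enumerate(
        sorted(range(len(initial)), key=lambda i: -initial[i][3]))}
    scored = sorted(
        range(len(initial)), key=lambda i: (area_rank[i] + asym_rank[i], i)
    )[:n_main]
    rois = []
    for rid, i in enumerate(sorted(scored), start=1):
        lab, members, area, masym = initial[i]
        rois.append(ROISpec(roi_id=rid, source_cluster=lab,
                            vertices=members, area_mm2=area,
                            mean_asym_mm=masym))
    return rois


# ---------------------------------------------------------------------------
# per-ROI hemispheric trajectories with outlier pruning


@dataclass
class ROITrajectoryResult:
    roi_id: int
    grid: np.ndarray
    left: np.ndarray                 # fitted mean thickness (mm)
    right: np.ndarray
    left_ci: np.ndarray              # (G, 2) 95% interval
    right_ci: np.ndarray
    percent_change_left: np.ndarray
    percent_change_right: np.ndarray
    n_obs_before: int
    n_obs_after: int
    outlier_sd: float
    removed_observations: np.ndarray = field(default=None)


def _roi_long_frame(dataset: CohortDataset, vertices: np.ndarray):
    obs = dataset.observations
    lh = dataset.thickness_lh[:, vertices].mean(axis=1)
    rh = dataset.thickness_rh[:, vertices].mean(axis=1)
    frames, ys = [], []
    for hemi, vals in (("L", lh), ("R", rh)):
        f = obs[["subject", "age", "sex", "scanner"]].copy()
        f["hemisphere"] = hemi
        f["scan"] = np.arange(len(obs))
        frames.append(f)
        ys.append(vals)
    return pd.concat(frames, ignore_index=True), np.concatenate(ys)


def fit_roi_trajectories(
    dataset: CohortDataset,
    roi: ROISpec,
    outlier_sd: float = 6.0,
    grid: np.ndarray | int = 100,
    k: int = 6,
    iterate_outliers: bool = False,
) -> ROITrajectoryResult:
    """Hemispheric trajectories of ROI-mean thickness with outlier pruning.

    The model is fit, scans whose residual magnitude reaches ``outlier_sd``
    residual standard deviations in either hemisphere are dropped (from
    both hemispheres), and the model is refit once (or to a fixed point
    with ``iterate_outliers``).  Percent change rescales each fitted
    trajectory by its value at the youngest grid age.
    """
    if len(roi.vertices) == 0:
        raise ValueError("empty ROI")
    frame, y = _roi_long_frame(dataset, roi.vertices)
    covs = [c for c in ("sex", "scanner") if frame[c].nunique() > 1]
    est = G.FactorSmoothGAMM(k=k, covariates=covs).fit(frame, y)
    n_before = len(dataset.observations)
    keep_mask = np.ones(n_before, dtype=bool)
    removed: list[int] = []
    for _ in range(100 if iterate_outliers else 1):
        resid = est.residuals(frame, y)
        sd = resid.std()
        flag_rows = np.abs(resid) >= outlier_sd * sd
        flagged_scans = np.unique(frame.loc[flag_rows, "scan"])
        flagged_scans = [s for s in flagged_scans if keep_mask[s]]
        if not flagged_scans:
            break
        keep_mask[flagged_scans] = False
        removed.extend(int(s) for s in flagged_scans)
        if not keep_mask.any():
            raise RuntimeError(
                "all observations flagged as outliers; check the data"
            )
        sub = frame[frame["scan"].map(lambda s: keep_mask[s])]
        est = G.FactorSmoothGAMM(k=k, covariates=covs).fit(
            sub.reset_index(drop=True), y[sub.index.to_numpy()]
        )
        frame, y = sub.reset_index(drop=True), y[sub.index.to_numpy()]
    if isinstance(grid, (int, np.integer)):
        lo, hi = est.age_range_
        grid = np.linspace(lo, hi, int(grid))
    grid = np.asarray(grid, float)
    traj = est.trajectories(grid)
    level = est.intercept_
    left = traj.f_left + level
    right = traj.f_right + level
    zcrit = stats.norm.ppf(0.975)
    left_ci = np.column_stack(
        [left - zcrit * traj.se_left, left + zcrit * traj.se_left]
    )
    right_ci = np.column_stack(
        [right - zcrit * traj.se_right, right + zcrit * traj.se_right]
    )

    def pct(curve):
        return 100.0 * (curve - curve[0]) / curve[0]

    return ROITrajectoryResult(
        roi_id=roi.roi_id, grid=grid, left=left, right=right,
        left_ci=left_ci, right_ci=right_ci,
        percent_change_left=pct(left), percent_change_right=pct(right),
        n_obs_before=n_before, n_obs_after=int(keep_mask.sum()),
        outlier_sd=outlier_sd,
        removed_observations=np.array(sorted(removed), dtype=int),
    )


# ---------------------------------------------------------------------------
# cognition


def composite_memory_score(subtests: pd.DataFrame) -> np.ndarray:
    """First principal component of z-scored verbal-memory subtests.

    Expects columns for the learning, immediate and delayed free-recall raw
    scores; the component is sign-oriented so the delayed-recall loading is
    positive.  Scores are centered (mean 0).
    """
    arr = subtests.to_numpy(dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 complete observations")
    if np.any(~np.isfinite(arr)):
        raise ValueError("missing values in subtest table")
    sd = arr.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance subtest")
    z = (arr - arr.mean(axis=0)) / sd
    cov = np.cov(z, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    pc = evecs[:, -1]
    if pc[-1] < 0:         # delayed recall is the last column by convention
        pc = -pc
    return z @ pc


@dataclass
class SmoothTermResult:
    name: str
    edf: float
    F: float
    pvalue: float


@dataclass
class AdditiveFit:
    """Penalized additive model with subject random intercept."""

    fit: G.PenalizedFit
    terms: dict[str, SmoothTermResult]
    r2_population: float
    loglik: float
    edf_total: float
    n_obs: int
    smooth_slices: dict[str, slice] = field(default_factory=dict)


def _additive_fit(
    y: np.ndarray,
    smooth_vars: dict[str, np.ndarray],
    linear: pd.DataFrame | None,
    subjects: np.ndarray,
    k: int = 6,
) -> AdditiveFit:
    y = np.asarray(y, float)
    n = len(y)
    cols = [np.ones((n, 1))]
    names = ["Intercept"]
    if linear is not None and linear.shape[1]:
        cols.append(linear.to_numpy(dtype=float))
        names.extend(linear.columns)
    Xf = np.hstack(cols)
    n_fixed = Xf.shape[1]
    parts, blocks_info = [Xf], []
    pos = n_fixed
    bases = {}
    for name, xvals in smooth_vars.items():
        nuniq = len(np.unique(xvals))
        kk = min(k, nuniq)
        if kk < 3:
            raise ValueError(f"smooth term {name!r} has too few unique values")
        b = build_basis(np.asarray(xvals, float), kk)
        Bm = b.evaluate(np.asarray(xvals, float))
        parts.append(Bm)
        blocks_info.append((name, slice(pos, pos + Bm.shape[1]), b.penalty, Bm))
        bases[name] = b
        pos += Bm.shape[1]
    subj_codes, levels = pd.factorize(subjects)
    Z = np.zeros((n, len(levels)))
    Z[np.arange(n), subj_codes] = 1.0
    parts.append(Z)
    sl_subj = slice(pos, pos + Z.shape[1])
    Xfull = np.hstack(parts)
    XtX = Xfull.T @ Xfull
    blocks = []
    for name, sl, S_raw, _Bm in blocks_info:
        S, scale = G.scale_penalty(S_raw, XtX[sl, sl])
        rank, ld = G._penalty_rank_logdet(S)
        blocks.append(G.PenaltyBlock(name, sl, S, rank, ld, False, scale))
    S, scale = G.scale_penalty(np.eye(Z.shape[1]), XtX[sl_subj, sl_subj])
    rank, ld = G._penalty_rank_logdet(S)
    blocks.append(G.PenaltyBlock("subject", sl_subj, S, rank, ld, True, scale))
    fit = G.fit_penalized(Xfull, y, blocks)
    terms = {}
    for name, sl, _S, Bm in blocks_info:
        res = G.wald_smooth_test(
            fit.beta[sl], fit.cov[sl, sl], fit.edf1[name],
            fit.df_residual, X_block=Bm,
        )
        terms[name] = SmoothTermResult(
            name=name, edf=fit.edf[name], F=res.statistic, pvalue=res.pvalue
        )
    pop_cols = np.ones(Xfull.shape[1], dtype=bool)
    pop_cols[sl_subj] = False
    yhat_pop = Xfull[:, pop_cols] @ fit.beta[pop_cols]
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat_pop) ** 2)) / tss if tss > 0 else np.nan
    resid = y - Xfull @ fit.beta
    rss = float(np.sum(resid ** 2))
    loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
    return AdditiveFit(fit=fit, terms=terms, r2_population=r2,
                       loglik=loglik, edf_total=fit.edf_total, n_obs=n,
                       smooth_slices={name: sl for name, sl, _S, _B
                                      in blocks_info})


@dataclass
class CognitiveChangeResult:
    effect_table: pd.DataFrame       # roi, measure, edf, F, p, fdr_p
    age_variance_explained: dict[str, float]
    joint_comparison: dict[str, dict]


def cognitive_change_model(
    cognition: pd.DataFrame,
    roi_asymmetry: pd.DataFrame,
    mean_thickness: np.ndarray,
    subjects: np.ndarray,
    ages: np.ndarray,
    covariates: pd.DataFrame | None = None,
    k: int = 6,
) -> CognitiveChangeResult:
    """Longitudinal cognition against per-ROI asymmetry change.

    For each ROI and each cognitive measure, fits an additive mixed model
    with smooth terms for the ROI's asymmetry (LH-RH), mean thickness and
    age (covariates and a subject random intercept included) and records
    the asymmetry smooth's test; p-values are FDR-corrected across the full
    ROI x measure family.  Age's variance share is the population-level R^2
    drop when the age smooth is removed.  A joint model with all ROI
    asymmetry smooths is compared to the age-plus-covariates base model by
    a likelihood-ratio test with EDF-based degrees of freedom.
    """
    measures: dict[str, np.ndarray] = {}
    mem_cols = [c for c in cognition.columns if c.startswith("cvlt_")]
    if len(mem_cols) >= 3:
        measures["memory"] = composite_memory_score(cognition[mem_cols])
    if "matrix_raw" in cognition.columns:
        measures["fluid"] = cognition["matrix_raw"].to_numpy(dtype=float)
    if not measures:
        raise ValueError("no usable cognitive measures in table")
    lin = covariates.reset_index(drop=True) if covariates is not None else None

    rows = []
    age_var = {}
    joint = {}
    for mname, score in measures.items():
        base = _additive_fit(score, {"age": ages}, lin, subjects, k=k)
        noage = _additive_fit(score, {}, lin, subjects, k=k)
        age_var[mname] = base.r2_population - noage.r2_population
        for roi in roi_asymmetry.columns:
            fitr = _additive_fit(
                score,
                {
                    f"asym_{roi}": roi_asymmetry[roi].to_numpy(float),
                    "thickness": np.asarray(mean_thickness, float),
                    "age": ages,
                },
                lin, subjects, k=k,
            )
            t = fitr.terms[f"asym_{roi}"]
            rows.append({"roi": roi, "measure": mname, "edf": t.edf,
                         "F": t.F, "p": t.pvalue})
        # joint model: all ROI asymmetry smooths at once
        smooths = {f"asym_{r}": roi_asymmetry[r].to_numpy(float)
                   for r in roi_asymmetry.columns}
        smooths["age"] = ages
        full = _additive_fit(score, smooths, lin, subjects, k=k)
        lr = 2.0 * (full.loglik - base.loglik)
        # reference the (shrunken) LR to the full dimension of the added
        # blocks: the penalized improvement is bounded by the unpenalized
        # one, so this chi-square reference is valid if conservative —
        # EDF-based df is anti-conservative because the smoothing
        # parameters are selected from the same data
        df = float(sum(
            sl.stop - sl.start
            for name_, sl in full.smooth_slices.items()
            if name_.startswith("asym_")
        ))
        joint[mname] = {
            "lr_statistic": float(max(lr, 0.0)),
            "df": df,
            "edf_gain": float(full.edf_total - base.edf_total),
            "pvalue": float(stats.chi2.sf(max(lr, 0.0), df)),
        }
    table = pd.DataFrame(rows)
    table["fdr_p"] = fdr_adjust(table["p"].to_numpy())
    return CognitiveChangeResult(
        effect_table=table, age_variance_explained=age_var,
        joint_comparison=joint,
    )


# ---------------------------------------------------------------------------
# clinical: group derivation, age jitter, Group x Time tests

_SEVERITY = {"NC": 0, "MCI": 1, "AD": 2}


def define_longitudinal_groups(diagnoses: pd.DataFrame) -> pd.Series:
    """Assign NC-long / AD-long / excluded from diagnosis sequences.

    Subjects normal at every timepoint are NC-long; subjects diagnosed AD
    throughout or by their final timepoint are AD-long; subjects whose
    severity ever decreases across consecutive timepoints (diagnostic
    reversion) or who end at MCI are excluded.
    """
    bad = set(diagnoses["diagnosis"]) - set(_SEVERITY)
    if bad:
        raise ValueError(f"unknown diagnosis codes: {sorted(bad)}")
    out = {}
    for sid, grp in diagnoses.sort_values("timepoint").groupby("subject"):
        seq = [_SEVERITY[d] for d in grp["diagnosis"]]
        if any(b < a for a, b in zip(seq, seq[1:])):
            out[sid] = "excluded"
        elif all(s == 0 for s in seq):
            out[sid] = "NC-long"
        elif seq[-1] == 2:
            out[sid] = "AD-long"
        else:
            out[sid] = "excluded"
    return pd.Series(out, name="group")


def estimate_jittered_age(
    birth_year: int, test_date: str | pd.Timestamp, seed: int,
    subject: str = "",
) -> float:
    """Age from mid-year of the birth year to the test date, jittered.

    Only year of birth is assumed known: age is computed from July 1 of the
    birth year and a uniform jitter on [-0.5, +0.5] years is added,
    deterministic per (subject, seed).
    """
    td = pd.Timestamp(test_date)
    mid = pd.Timestamp(year=int(birth_year), month=7, day=1)
    if td <= mid:
        raise ValueError("test date precedes mid-year of birth year")
    base = (td - mid).days / 365.25
    sub_hash = zlib.crc32(str(subject).encode())
    rng = np.random.default_rng(np.random.SeedSequence([seed, sub_hash]))
    age = base + rng.uniform(-0.5, 0.5)
    if age <= 0:
        raise ValueError("jittered age non-positive")
    return float(age)


@dataclass
class GroupChangeResult:
    table: pd.DataFrame              # roi, estimate, se, p, fdr_p
    n_ad: int
    n_nc: int
    n_obs: int


def group_change_test(
    clinical: ClinicalDataset,
    rois: list[str] | None = None,
    seed: int = 0,
) -> GroupChangeResult:
    """Per-ROI Group x Time linear mixed tests of asymmetry change.

    Groups are derived from diagnosis sequences; per ROI the model is
    asymmetry ~ Group + Time + Group:Time + baseline age + sex + scanner
    with a subject random intercept, and the Group x Time interaction
    (mm/year difference in asymmetry slope) is tested two-sided; p-values
    are BH-FDR corrected across ROIs.
    """
    rows = clinical.rows.reset_index(drop=True)
    rois = list(rois) if rois is not None else list(clinical.roi_asymmetry.columns)
    groups = define_longitudinal_groups(
        rows[["subject", "timepoint", "diagnosis"]]
    )
    rows = rows.assign(group=rows["subject"].map(groups))
    keep = rows["group"].isin(["NC-long", "AD-long"]).to_numpy()
    rows_k = rows[keep].reset_index(drop=True)
    asym_k = clinical.roi_asymmetry.reset_index(drop=True)[keep].reset_index(drop=True)
    n_ad = rows_k.loc[rows_k["group"] == "AD-long", "subject"].nunique()
    n_nc = rows_k.loc[rows_k["group"] == "NC-long", "subject"].nunique()
    if n_ad < 2 or n_nc < 2:
        raise ValueError("both groups need >= 2 subjects")

    ages = np.array([
        estimate_jittered_age(by, td, seed, subject=s)
        for by, td, s in zip(rows_k["birth_year"], rows_k["test_date"],
                             rows_k["subject"])
    ])
    baseline_age = pd.Series(ages).groupby(rows_k["subject"]).transform("min")
    is_ad = (rows_k["group"] == "AD-long").astype(float)
    time = rows_k["years_since_baseline"].astype(float)
    design = pd.DataFrame({
        "group_ad": is_ad,
        "time": time,
        "group_time": is_ad * time,
        "age_baseline": baseline_age.to_numpy(),
        "sex": rows_k["sex"].astype(float),
    })
    scanners = pd.get_dummies(rows_k["scanner"], prefix="scanner",
                              drop_first=True)
    for c in scanners.columns:
        design[c] = scanners[c].astype(float)

    out = []
    for roi in rois:
        fit = G.fit_lme(asym_k[roi].to_numpy(float), design,
                        rows_k["subject"].to_numpy())
        out.append({
            "roi": roi,
            "estimate": float(fit.params["group_time"]),
            "se": float(fit.bse["group_time"]),
            "p": float(fit.pvalues["group_time"]),
        })
    table = pd.DataFrame(out)
    table["fdr_p"] = fdr_adjust(table["p"].to_numpy())
    return GroupChangeResult(table=table, n_ad=int(n_ad), n_nc=int(n_nc),
                             n_obs=len(rows_k))
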