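"""End-to-end orchestration of the asymmetry-trajectory analysis.

A single declarative config drives: cohort simulation (or loading),
vertex-wise factor-smooth modeling, FDR thresholding and cluster-extent
filtering, trajectory clustering with silhouette-based K selection,
cross-cohort replication, ROI trajectory/cognition analyses, and the
clinical Group x Time tests.  Every stage writes its outputs before the
next starts, and a rerun with identical config and seeds is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clustering, replication, roi as roi_mod, vertexwise
from .cohort import (
    ClinicalDesign, CohortDesign, CognitionDesign, assign_truth_clusters,
    load_cohort, save_cohort, simulate_clinical, simulate_cohort,
)
from .mesh import build_icosphere, load_mesh_gifti, load_mesh_off

log = logging.getLogger("asymtraj.pipeline")


@dataclass
class PipelineConfig:
    """Declarative parameters of a full run (defaults = study constants)."""

    output_dir: str = "asymtraj_out"
    seed: int = 0
    # mesh: either a path or an icosphere spec
    mesh_path: str | None = None
    icosphere_subdivisions: int = 3
    icosphere_radius: float = 49.0
    # cohorts: simulate by default; or point at saved cohort directories
    simulate: bool = True
    n_truth_clusters: int = 3
    truth_coverage: float = 0.4
    discovery_dir: str | None = None
    replication_dirs: list = field(default_factory=list)
    n_replications: int = 1
    cohort: dict = field(default_factory=dict)        # CohortDesign overrides
    cognition: dict | None = None                     # CognitionDesign overrides
    clinical: dict | None = field(default_factory=dict)  # ClinicalDesign / None
    clinical_effect: float = -0.004
    # model constants
    k: int = 6
    grid_size: int = 100
    fdr_alpha: float = 0.001
    min_area_mm2: float | None = None
    min_area_fraction: float = 0.01
    K_range: tuple = (2, 7)
    outlier_sd: float = 6.0
    n_permutations: int = 10_000
    n_initial_rois: int = 13
    n_main_rois: int = 8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["K_range"] = list(self.K_range)
        return d


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    selected_K: int | None = None
    silhouette_table: list = field(default_factory=list)
    dice: list = field(default_factory=list)
    cluster_recovery: dict | None = None
    roi_table: list = field(default_factory=list)
    cognition: dict | None = None
    clinical: dict | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def validate_inputs(paths: dict) -> list[dict]:
    """Schema/consistency diagnostics for on-disk cohort inputs.

    Never raises; returns a machine-readable issue list (empty = valid).
    """
    issues = []

    def add(kind, msg):
        issues.append({"kind": kind, "message": msg})

    d = Path(paths.get("cohort_dir", "."))
    obs_path = d / "observations.csv"
    if not obs_path.exists():
        add("missing-file", str(obs_path))
        return issues
    obs = pd.read_csv(obs_path)
    for col in ("subject", "age", "sex", "scanner", "timepoint"):
        if col not in obs.columns:
            add("missing-column", f"observations.csv lacks {col!r}")
    if "subject" in obs.columns and "age" in obs.columns:
        for sid, grp in obs.groupby("subject"):
            if not np.all(np.diff(grp["age"].to_numpy()) > 0):
                add("age-monotonicity", f"subject {sid} has non-increasing ages")
    for hemi in ("lh", "rh"):
        p = d / f"thickness_{hemi}.tsv"
        if not p.exists():
            add("missing-file", str(p))
            continue
        arr = np.loadtxt(p, delimiter="\t", ndmin=2)
        if arr.shape[0] != len(obs):
            add("dimension-mismatch",
                f"{p.name}: {arr.shape[0]} rows vs {len(obs)} observations")
        if np.any(arr <= 0):
            add("invalid-value", f"{p.name}: non-positive thickness")
    mesh_path = paths.get("mesh_path")
    if mesh_path and not Path(mesh_path).exists():
        add("missing-file", str(mesh_path))
    return issues


def _load_mesh(config: PipelineConfig):
    if config.mesh_path:
        p = Path(config.mesh_path)
        if p.suffix == ".gii" or p.name.endswith(".surf.gii"):
            return load_mesh_gifti(p)
        return load_mesh_off(p)
    return build_icosphere(config.icosphere_subdivisions,
                           config.icosphere_radius)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full analysis; see module docstring for the stage order."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), version=__version__)
    t_all = time.time()

    def stage(name):
        log.info("stage=%s status=start", name)
        return time.time()

    def done(name, t0, **params):
        report.stages[name] = {"status": "ok",
                               "seconds": round(time.time() - t0, 2), **params}
        log.info("stage=%s status=ok seconds=%.2f params=%s",
                 name, time.time() - t0, params)

    rng_root = np.random.SeedSequence(config.seed)
    seeds = rng_root.spawn(8)

    def subseed(i: int) -> int:
        return int(seeds[i].generate_state(1)[0] % (2 ** 31))

    # ---- mesh + cohorts ------------------------------------------------
    t0 = stage("data")
    mesh = _load_mesh(config)
    truth = None
    if config.simulate:
        truth = assign_truth_clusters(
            mesh, config.n_truth_clusters, config.truth_coverage,
            seed=subseed(0),
        )
        design = CohortDesign(**config.cohort)
        cog_design = (CognitionDesign(**config.cognition)
                      if config.cognition is not None else None)
        discovery = simulate_cohort(mesh, truth, design, seed=subseed(1),
                                    cognition=cog_design)
        save_cohort(discovery, truth, out / "discovery", seed=config.seed)
        replications = []
        for i in range(config.n_replications):
            rep = simulate_cohort(mesh, truth, design, seed=subseed(2) + i,
                                  cognition=None)
            save_cohort(rep, None, out / f"replication{i}")
            replications.append(rep)
    else:
        if not config.discovery_dir:
            raise ValueError("discovery_dir required when simulate=false")
        discovery = load_cohort(config.discovery_dir)
        replications = [load_cohort(p) for p in config.replication_dirs]
    done("data", t0, n_obs=discovery.n_obs, n_vertices=mesh.n_vertices,
         n_replications=len(replications))

    # ---- vertex-wise model --------------------------------------------
    t0 = stage("vertexwise")
    maps, trajs = vertexwise.run_vertexwise(
        discovery, mesh, k=config.k, grid=config.grid_size
    )
    _write_maps(out, maps, trajs)
    done("vertexwise", t0,
         n_converged=int(maps.converged.sum()),
         n_signif_fdr=int(np.nansum(maps.interaction_fdr_p < config.fdr_alpha)))

    # ---- threshold + extent filter ------------------------------------
    t0 = stage("threshold")
    mask = vertexwise.threshold_and_filter(
        maps, mesh, alpha=config.fdr_alpha,
        min_area_mm2=config.min_area_mm2,
        min_area_fraction=config.min_area_fraction,
    )
    np.savetxt(out / "significant_mask.csv", mask.astype(int), fmt="%d",
               header="significant", comments="")
    report.counts["n_retained"] = int(mask.sum())
    done("threshold", t0, n_retained=int(mask.sum()))
    if mask.sum() < max(config.K_range) + 1:
        report.stages["cluster"] = {"status": "failed",
                                    "reason": "too few significant vertices"}
        (out / "report.json").write_text(report.to_json())
        raise RuntimeError("too few significant vertices to cluster")

    # ---- clustering ----------------------------------------------------
    t0 = stage("cluster")
    D, ids = clustering.compute_dissimilarity(trajs, mask)
    part, sil_table = clustering.select_solution(
        D, range(config.K_range[0], config.K_range[1] + 1),
        vertex_ids=ids, trajs=trajs,
    )
    report.selected_K = part.K
    report.silhouette_table = sil_table
    pd.DataFrame({
        "vertex": part.vertex_ids, "label": part.labels,
        "silhouette": part.silhouette,
    }).to_csv(out / "partition.csv", index=False)
    pd.DataFrame(sil_table).to_csv(out / "silhouette_by_K.csv", index=False)
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        true_lab = truth.vertex_cluster_label
        on_truth = true_lab[part.vertex_ids] > 0
        ari = adjusted_rand_score(
            true_lab[part.vertex_ids][on_truth], part.labels[on_truth]
        ) if on_truth.sum() > 1 else np.nan
        report.cluster_recovery = {
            "ari_vs_truth": float(ari),
            "n_truth_vertices_retained": int(on_truth.sum()),
        }
    done("cluster", t0, selected_K=part.K,
         mean_silhouette=round(part.mean_silhouette, 4))

    # ---- replication ---------------------------------------------------
    t0 = stage("replication")
    for i, rep in enumerate(replications):
        rep_maps, rep_trajs = vertexwise.run_vertexwise(
            rep, mesh, k=config.k, grid=trajs.grid
        )
        rep_mask = mask & rep_maps.converged
        disc_part = part
        if rep_mask.sum() < mask.sum():
            log.warning(
                "replication %d: %d discovery vertices dropped "
                "(non-converged in replication fit)",
                i, int(mask.sum() - rep_mask.sum()),
            )
            keep = rep_mask[part.vertex_ids]
            disc_part = clustering.Partition(
                labels=part.labels[keep], medoids=part.medoids,
                vertex_ids=part.vertex_ids[keep], cost=np.nan,
            )
        rep_part = replication.constrained_cluster(rep_trajs, rep_mask, part.K)
        dres = replication.dice_permutation_test(
            disc_part, rep_part, n_perm=config.n_permutations,
            seed=subseed(3) + i,
        )
        report.dice.append({
            "replication": i, "mean_dice": dres.mean_dice,
            "pvalue": dres.pvalue, "null_mean": dres.null_mean,
            "dice_per_label": dres.dice_per_label,
            "n_permutations": dres.n_permutations,
        })
        (out / f"dice_replication{i}.json").write_text(
            json.dumps(report.dice[-1], default=_jsonable)
        )
    done("replication", t0, n=len(replications))

    # ---- ROI analyses --------------------------------------------------
    t0 = stage("roi")
    rois = roi_mod.derive_rois(
        part, mesh, discovery,
        n_initial=config.n_initial_rois, n_main=config.n_main_rois,
    )
    roi_rows = []
    roi_trajres = {}
    for r in rois:
        tr = roi_mod.fit_roi_trajectories(
            discovery, r, outlier_sd=config.outlier_sd, grid=trajs.grid,
            k=config.k,
        )
        roi_trajres[r.roi_id] = tr
        roi_rows.append({
            "roi": r.roi_id, "cluster": r.source_cluster,
            "area_mm2": r.area_mm2, "mean_asym_mm": r.mean_asym_mm,
            "n_vertices": len(r.vertices),
            "n_obs_after_outliers": tr.n_obs_after,
        })
    report.roi_table = roi_rows
    pd.DataFrame(roi_rows).to_csv(out / "rois.csv", index=False)
    done("roi", t0, n_rois=len(rois))

    # ---- cognition -----------------------------------------------------
    if discovery.cognition is not None and rois:
        t0 = stage("cognition")
        cog = discovery.cognition
        asym = discovery.asymmetry()
        roi_asym = pd.DataFrame({
            f"roi{r.roi_id}": asym[:, r.vertices].mean(axis=1) for r in rois
        })
        mean_th = 0.5 * (discovery.thickness_lh + discovery.thickness_rh
                         ).mean(axis=1)
        covs = pd.DataFrame({
            "sex": discovery.observations["sex"].astype(float),
            "test_version": cog["test_version"].astype(float),
        })
        cres = roi_mod.cognitive_change_model(
            cog, roi_asym, mean_th,
            discovery.observations["subject"].to_numpy(),
            discovery.observations["age"].to_numpy(float),
            covariates=covs, k=config.k,
        )
        report.cognition = {
            "age_variance_explained": cres.age_variance_explained,
            "n_fdr_significant": int((cres.effect_table["fdr_p"] < 0.05).sum()),
            "joint_comparison": cres.joint_comparison,
        }
        cres.effect_table.to_csv(out / "cognition_effects.csv", index=False)
        done("cognition", t0)
    else:
        report.stages["cognition"] = {"status": "skipped"}

    # ---- clinical ------------------------------------------------------
    if config.clinical is not None:
        t0 = stage("clinical")
        cdesign = ClinicalDesign(**(config.clinical or {}))
        roi_names = [f"roi{r.roi_id}" for r in rois] or ["roi1"]
        affected = roi_names[: max(1, len(roi_names) // 2)]
        clin = simulate_clinical(
            roi_names, config.clinical_effect, cdesign, seed=subseed(4),
            affected_rois=affected,
        )
        gres = roi_mod.group_change_test(clin, roi_names, seed=subseed(5))
        report.clinical = {
            "n_ad": gres.n_ad, "n_nc": gres.n_nc, "n_obs": gres.n_obs,
            "effect_injected": config.clinical_effect,
            "affected_rois": affected,
            "table": gres.table.to_dict(orient="records"),
            "n_fdr_significant": int((gres.table["fdr_p"] < 0.05).sum()),
        }
        gres.table.to_csv(out / "clinical_group_change.csv", index=False)
        done("clinical", t0)
    else:
        report.stages["clinical"] = {"status": "skipped"}

    report.counts.update({
        "n_vertices": mesh.n_vertices,
        "n_observations": discovery.n_obs,
        "n_subjects": discovery.observations["subject"].nunique(),
        "total_seconds": round(time.time() - t_all, 2),
    })
    (out / "report.json").write_text(report.to_json())
    return report


def _write_maps(out: Path, maps, trajs) -> None:
    pd.DataFrame({
        "interaction_F": maps.interaction_F,
        "interaction_p": maps.interaction_p,
        "interaction_fdr_p": maps.interaction_fdr_p,
        "hemi_effect": maps.hemi_effect,
        "hemi_p": maps.hemi_p,
        "hemi_fdr_p": maps.hemi_fdr_p,
        "converged": maps.converged.astype(int),
    }).to_csv(out / "vertex_stats.csv", index=False)
    np.savetxt(out / "asymmetry_trajectories.tsv", trajs.trajectories,
               delimiter="\t")
    np.savetxt(out / "trajectory_grid.tsv", trajs.grid[None, :],
               delimiter="\t")
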