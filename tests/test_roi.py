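"""ROI derivation, trajectory/outlier handling, cognition and clinical tests."""

import numpy as np
import pandas as pd
import pytest

from asymtraj.cohort import (
    ClinicalDesign, CohortDesign, assign_truth_clusters, simulate_clinical,
    simulate_cohort,
)
from asymtraj.clustering import Partition
from asymtraj.roi import (
    ROISpec, composite_memory_score, define_longitudinal_groups, derive_rois,
    estimate_jittered_age, fit_roi_trajectories, group_change_test,
)


@pytest.fixture(scope="module")
def cohort_with_truth(sphere_medium):
    truth = assign_truth_clusters(sphere_medium, 3, 0.4, seed=50)
    ds = simulate_cohort(sphere_medium, truth, CohortDesign(n_subjects=100),
                         seed=51)
    return sphere_medium, truth, ds


def partition_from_truth(truth, mesh):
    labels = truth.vertex_cluster_label
    ids = np.flatnonzero(labels > 0)
    return Partition(labels=labels[ids], medoids=ids[:3], vertex_ids=ids,
                     cost=0.0)


class TestDeriveROIs:
    def test_truth_partition_yields_truth_rois(self, cohort_with_truth):
        mesh, truth, ds = cohort_with_truth
        part = partition_from_truth(truth, mesh)
        rois = derive_rois(part, mesh, ds, n_initial=13, n_main=3)
        assert len(rois) == 3
        for roi in rois:
            # each main ROI overlaps exactly one truth patch
            labs = truth.vertex_cluster_label[roi.vertices]
            assert len(np.unique(labs)) == 1
            truth_patch = np.flatnonzero(
                truth.vertex_cluster_label == labs[0]
            )
            jac = (len(np.intersect1d(roi.vertices, truth_patch))
                   / len(np.union1d(roi.vertices, truth_patch)))
            assert jac > 0.5

    def test_single_connected_cluster_single_roi(self, cohort_with_truth):
        mesh, truth, ds = cohort_with_truth
        labels = truth.vertex_cluster_label
        ids = np.flatnonzero(labels == 1)
        part = Partition(labels=np.ones(len(ids), int), medoids=ids[:1],
                         vertex_ids=ids, cost=0.0)
        rois = derive_rois(part, mesh, ds, n_initial=13, n_main=8)
        assert len(rois) == 1

    def test_n_main_equals_n_initial_identity(self, cohort_with_truth):
        mesh, truth, ds = cohort_with_truth
        part = partition_from_truth(truth, mesh)
        a = derive_rois(part, mesh, ds, n_initial=3, n_main=3)
        b = derive_rois(part, mesh, ds, n_initial=3, n_main=3)
        assert [set(r.vertices.tolist()) for r in a] == \
               [set(r.vertices.tolist()) for r in b]
        assert len(a) == 3

    def test_roi_vertex_sets_disjoint(self, cohort_with_truth):
        mesh, truth, ds = cohort_with_truth
        part = partition_from_truth(truth, mesh)
        rois = derive_rois(part, mesh, ds, n_initial=13, n_main=3)
        all_v = np.concatenate([r.vertices for r in rois])
        assert len(all_v) == len(set(all_v.tolist()))


class TestROITrajectories:
    def test_no_outliers_nothing_removed(self, cohort_with_truth):
        mesh, truth, ds = cohort_with_truth
        roi = ROISpec(1, 1, np.flatnonzero(truth.vertex_cluster_label == 1),
                      1.0, 0.1)
        res = fit_roi_trajectories(ds, roi, outlier_sd=6.0, grid=30)
        assert res.n_obs_after == res.n_obs_before
        assert res.removed_observations.size == 0
        # percent change is zero at the youngest grid age
        assert res.percent_change_left[0] == 0.0
        assert res.percent_change_right[0] == 0.0

    def test_injected_outlier_removed_from_both_hemispheres(
        self, cohort_with_truth
    ):
        mesh, truth, ds = cohort_with_truth
        roi_vertices = np.flatnonzero(truth.vertex_cluster_label == 1)
        lh = ds.thickness_lh.copy()
        # +10 residual SDs at one scan, LH only
        lh[7, roi_vertices] += 10 * 0.05
        from asymtraj.cohort import CohortDataset

        tampered = CohortDataset(observations=ds.observations,
                                 thickness_lh=lh,
                                 thickness_rh=ds.thickness_rh)
        roi = ROISpec(1, 1, roi_vertices, 1.0, 0.1)
        res = fit_roi_trajectories(tampered, roi, outlier_sd=6.0, grid=30)
        assert 7 in res.removed_observations.tolist()
        assert res.n_obs_after == res.n_obs_before - len(
            res.removed_observations
        )

    def test_constant_trajectory_zero_percent_change(self, sphere_small):
        from asymtraj.cohort import (GroundTruth, HemiParams,
                                     TrajectoryParams, simulate_cohort)

        params = {0: TrajectoryParams(HemiParams(2.8, 0.0, 0.0),
                                      HemiParams(2.8, 0.0, 0.0))}
        truth = GroundTruth(
            vertex_cluster_label=np.zeros(sphere_small.n_vertices, int),
            cluster_params=params,
        )
        design = CohortDesign(n_subjects=50, sigma_subject=0.0,
                              sigma_asym_subject=0.0, sigma_noise=0.0,
                              sex_offset=0.0, scanner_offsets=(0.0, 0.0))
        ds = simulate_cohort(sphere_small, truth, design, seed=60)
        roi = ROISpec(1, 0, np.arange(sphere_small.n_vertices), 1.0, 0.0)
        res = fit_roi_trajectories(ds, roi, grid=20)
        np.testing.assert_allclose(res.percent_change_left, 0.0, atol=1e-6)
        np.testing.assert_allclose(res.percent_change_right, 0.0, atol=1e-6)


class TestCompositeMemory:
    def test_perfectly_correlated_subtests(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=30)
        table = pd.DataFrame({
            "learning": 2 * g + 1, "immediate": -3 * g, "delayed": 0.5 * g
        })
        scores = composite_memory_score(table)
        # PC1 explains all variance: scores perfectly correlate with g
        assert abs(np.corrcoef(scores, g)[0, 1]) == pytest.approx(1.0)
        # sign convention: positive loading on delayed recall
        assert np.corrcoef(scores, table["delayed"])[0, 1] > 0

    def test_scores_centered(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(40, 3)),
                             columns=["l", "i", "d"])
        assert composite_memory_score(table).mean() == pytest.approx(0, abs=1e-10)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(40, 3)),
                             columns=["l", "i", "d"])
        scaled = table.copy()
        scaled["l"] = 100 + 7 * scaled["l"]
        np.testing.assert_allclose(
            composite_memory_score(table), composite_memory_score(scaled),
            atol=1e-10,
        )

    def test_five_row_eigen_oracle(self):
        table = pd.DataFrame({
            "learning": [10.0, 12.0, 8.0, 15.0, 11.0],
            "immediate": [9.0, 13.0, 7.0, 14.0, 10.0],
            "delayed": [8.0, 12.0, 6.0, 13.0, 9.0],
        })
        z = (table - table.mean()) / table.std(ddof=1)
        evals, evecs = np.linalg.eigh(np.cov(z.to_numpy(), rowvar=False))
        pc = evecs[:, -1]
        if pc[-1] < 0:
            pc = -pc
        expected = z.to_numpy() @ pc
        np.testing.assert_allclose(composite_memory_score(table), expected,
                                   atol=1e-12)

    def test_zero_variance_rejected(self):
        table = pd.DataFrame({"l": [1.0, 1.0, 1.0], "i": [1, 2, 3],
                              "d": [2, 3, 4]})
        with pytest.raises(ValueError):
            composite_memory_score(table)


class TestCognitiveChangeCalibration:
    """Multi-replicate behavior of the cognition models on null data
    (cognition generated independently of asymmetry, given age)."""

    @pytest.fixture(scope="class")
    def null_cognition_runs(self, sphere_small):
        from asymtraj.cohort import CognitionDesign, simulate_cohort
        from asymtraj.roi import cognitive_change_model

        truth = assign_truth_clusters(sphere_small, 3, 0.5, seed=80)
        results = []
        for rep in range(10):
            ds = simulate_cohort(
                sphere_small, truth, CohortDesign(n_subjects=160),
                seed=8_000 + rep, cognition=CognitionDesign(age_r2=0.30),
            )
            asym = ds.asymmetry()
            labels = truth.vertex_cluster_label
            roi_asym = pd.DataFrame({
                f"roi{lab}": asym[:, labels == lab].mean(axis=1)
                for lab in (1, 2, 3)
            })
            mean_th = 0.5 * (ds.thickness_lh + ds.thickness_rh).mean(axis=1)
            covs = pd.DataFrame({
                "sex": ds.observations["sex"].astype(float),
                "test_version": ds.cognition["test_version"].astype(float),
            })
            results.append(cognitive_change_model(
                ds.cognition, roi_asym, mean_th,
                ds.observations["subject"].to_numpy(),
                ds.observations["age"].to_numpy(float), covs,
            ))
        return results

    def test_joint_model_rarely_significant(self, null_cognition_runs):
        ok = sum(
            all(j["pvalue"] > 0.05 for j in res.joint_comparison.values())
            for res in null_cognition_runs
        )
        assert ok >= 8

    def test_fdr_significant_effects_rare(self, null_cognition_runs):
        clean = sum(
            int((res.effect_table["fdr_p"] < 0.05).sum() == 0)
            for res in null_cognition_runs
        )
        assert clean >= 8

    def test_age_variance_share_recovered(self, null_cognition_runs):
        vals = [res.age_variance_explained["memory"]
                for res in null_cognition_runs]
        assert np.mean(vals) == pytest.approx(0.30, abs=0.05)


class TestLongitudinalGroups:
    @pytest.mark.parametrize("seq,expected", [
        (("NC", "NC", "NC"), "NC-long"),
        (("NC", "MCI", "AD"), "AD-long"),
        (("AD", "AD"), "AD-long"),
        (("MCI", "NC"), "excluded"),
        (("NC", "MCI"), "excluded"),
        (("AD", "MCI", "AD"), "excluded"),
    ])
    def test_sequences(self, seq, expected):
        table = pd.DataFrame({
            "subject": ["s"] * len(seq),
            "timepoint": range(len(seq)),
            "diagnosis": seq,
        })
        assert define_longitudinal_groups(table)["s"] == expected

    def test_unknown_code_rejected(self):
        table = pd.DataFrame({"subject": ["s", "s"], "timepoint": [0, 1],
                              "diagnosis": ["NC", "??"]})
        with pytest.raises(ValueError):
            define_longitudinal_groups(table)


class TestJitteredAge:
    def test_support_bounds(self):
        # birth 1950, test 2000-07-01: mid-year age exactly 50
        ages = [estimate_jittered_age(1950, "2000-07-01", seed, subject="a")
                for seed in range(2000)]
        assert all(49.5 - 0.01 <= a <= 50.5 + 0.01 for a in ages)

    def test_mean_near_midyear_age(self):
        ages = [estimate_jittered_age(1950, "2000-07-01", seed, subject="a")
                for seed in range(10_000)]
        assert np.mean(ages) == pytest.approx(50.0, abs=0.02)

    def test_deterministic_per_subject_and_seed(self):
        a1 = estimate_jittered_age(1940, "2001-03-15", 7, subject="x")
        a2 = estimate_jittered_age(1940, "2001-03-15", 7, subject="x")
        a3 = estimate_jittered_age(1940, "2001-03-15", 7, subject="y")
        assert a1 == a2
        assert a1 != a3

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            estimate_jittered_age(2010, "2005-01-01", 0)


class TestGroupChange:
    def test_noiseless_interaction_exact(self):
        design = ClinicalDesign(sigma_subject=0.0, sigma_noise=0.0)
        clin = simulate_clinical(["roi1", "roi2"], effect=-0.004,
                                 design=design, seed=70,
                                 affected_rois=["roi1"])
        res = group_change_test(clin, seed=0)
        by_roi = res.table.set_index("roi")
        assert by_roi.loc["roi1", "estimate"] == pytest.approx(-0.004,
                                                               abs=1e-8)
        assert by_roi.loc["roi2", "estimate"] == pytest.approx(0.0, abs=1e-8)

    def test_effect_detected_with_noise(self):
        clin = simulate_clinical(
            ["roi1", "roi2", "roi3"], effect=-0.01,
            design=ClinicalDesign(), seed=71, affected_rois=["roi1"],
        )
        res = group_change_test(clin, seed=1)
        by_roi = res.table.set_index("roi")
        assert by_roi["p"].idxmin() == "roi1"
        assert res.n_ad == 41
        assert res.n_nc == 128

    def test_fdr_column_dominates_p(self):
        clin = simulate_clinical(["roi1", "roi2"], effect=0.0, seed=72)
        res = group_change_test(clin, seed=2)
        assert (res.table["fdr_p"] >= res.table["p"] - 1e-15).all()
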