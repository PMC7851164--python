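"""Synthetic-cohort generator: determinism, design structure, truth recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asymtraj.cohort import (
    ClinicalDesign, CohortDesign, CognitionDesign, GroundTruth, HemiParams,
    TrajectoryParams, assign_truth_clusters, default_cluster_params,
    load_cohort, load_truth, save_cohort, simulate_clinical, simulate_cohort,
)
from asymtraj.mesh import build_icosphere, connected_components
from asymtraj.roi import define_longitudinal_groups


class TestTruthClusters:
    def test_deterministic(self, sphere_medium):
        t1 = assign_truth_clusters(sphere_medium, 3, 0.4, seed=5)
        t2 = assign_truth_clusters(sphere_medium, 3, 0.4, seed=5)
        np.testing.assert_array_equal(
            t1.vertex_cluster_label, t2.vertex_cluster_label
        )

    def test_patches_contiguous_and_disjoint(self, sphere_medium):
        truth = assign_truth_clusters(sphere_medium, 3, 0.4, seed=6)
        labels = truth.vertex_cluster_label
        for lab in (1, 2, 3):
            comps = connected_components(sphere_medium, labels == lab)
            assert len(comps) == 1  # contiguous by construction

    def test_coverage_close_to_target(self, sphere_medium):
        truth = assign_truth_clusters(sphere_medium, 3, 0.4, seed=7)
        areas = sphere_medium.vertex_area
        covered = areas[truth.vertex_cluster_label > 0].sum() / areas.sum()
        assert covered == pytest.approx(0.4, rel=0.05)

    def test_single_seed_minimum_coverage(self, sphere_small):
        frac = 1.0 / (2 * sphere_small.n_vertices)
        truth = assign_truth_clusters(sphere_small, 1, frac, seed=8)
        assert (truth.vertex_cluster_label == 1).sum() == 1

    def test_invalid_arguments(self, sphere_small):
        with pytest.raises(ValueError):
            assign_truth_clusters(sphere_small, 0, 0.4, seed=0)
        with pytest.raises(ValueError):
            assign_truth_clusters(sphere_small, 2, 1.0, seed=0)


class TestSimulateCohort:
    def test_byte_deterministic(self, sphere_small):
        truth = assign_truth_clusters(sphere_small, 2, 0.3, seed=1)
        d1 = simulate_cohort(sphere_small, truth,
                             CohortDesign(n_subjects=40), seed=9)
        d2 = simulate_cohort(sphere_small, truth,
                             CohortDesign(n_subjects=40), seed=9)
        pd.testing.assert_frame_equal(d1.observations, d2.observations)
        np.testing.assert_array_equal(d1.thickness_lh, d2.thickness_lh)
        np.testing.assert_array_equal(d1.thickness_rh, d2.thickness_rh)

    def test_noiseless_thickness_equals_formula(self, sphere_small):
        truth = assign_truth_clusters(sphere_small, 2, 0.3, seed=2)
        design = CohortDesign(
            n_subjects=30, sigma_subject=0.0, sigma_asym_subject=0.0,
            sigma_noise=0.0, sex_offset=0.0, scanner_offsets=(0.0, 0.0),
        )
        ds = simulate_cohort(sphere_small, truth, design, seed=10)
        ages = ds.observations["age"].to_numpy()
        labels = truth.vertex_cluster_label
        for v in [0, 10, 20, 41]:
            pars = truth.cluster_params[int(labels[v])]
            np.testing.assert_allclose(ds.thickness_lh[:, v],
                                       pars.left.thickness(ages), atol=1e-12)
            np.testing.assert_allclose(ds.thickness_rh[:, v],
                                       pars.right.thickness(ages), atol=1e-12)

    def test_background_symmetric_without_subject_asymmetry(self, sphere_small):
        truth = assign_truth_clusters(sphere_small, 2, 0.3, seed=3)
        design = CohortDesign(n_subjects=30, sigma_asym_subject=0.0,
                              sigma_noise=0.0)
        ds = simulate_cohort(sphere_small, truth, design, seed=11)
        background = truth.vertex_cluster_label == 0
        asym = ds.asymmetry()[:, background]
        np.testing.assert_allclose(asym, 0.0, atol=1e-12)

    def test_timepoint_distribution(self, sphere_small):
        truth = assign_truth_clusters(sphere_small, 1, 0.2, seed=4)
        design = CohortDesign(n_subjects=100,
                              timepoint_probs=(0.3, 0.5, 0.2))
        counts = np.zeros(3)
        n_seeds = 20
        for seed in range(n_seeds):
            ds = simulate_cohort(sphere_small, truth, design, seed=seed)
            tp = ds.observations.groupby("subject")["timepoint"].max() + 1
            counts += np.bincount(tp, minlength=4)[1:4]
        total = counts.sum()
        for frac, p in zip(counts / total, (0.3, 0.5, 0.2)):
            se = np.sqrt(p * (1 - p) / total)
            assert abs(frac - p) < 3 * se + 1e-9

    def test_invalid_design_rejected(self, sphere_small):
        truth = assign_truth_clusters(sphere_small, 1, 0.2, seed=5)
        with pytest.raises(ValueError):
            simulate_cohort(sphere_small, truth,
                            CohortDesign(timepoint_probs=(0.5, 0.2, 0.2)),
                            seed=0)
        with pytest.raises(ValueError):
            simulate_cohort(sphere_small, truth,
                            CohortDesign(sigma_noise=-1.0), seed=0)

    def test_ages_strictly_increasing_within_subject(self, sphere_small):
        truth = assign_truth_clusters(sphere_small, 1, 0.2, seed=6)
        ds = simulate_cohort(sphere_small, truth,
                             CohortDesign(n_subjects=80), seed=12)
        for _, grp in ds.observations.groupby("subject"):
            assert np.all(np.diff(grp["age"].to_numpy()) > 0)

    def test_trajectory_params_validated(self, sphere_small):
        bad = {
            0: TrajectoryParams(HemiParams(2.8, -0.05), HemiParams(2.8, -0.05)),
            1: TrajectoryParams(HemiParams(2.8, -0.05), HemiParams(2.8, -0.05)),
        }
        truth = GroundTruth(
            vertex_cluster_label=(np.arange(sphere_small.n_vertices) < 5
                                  ).astype(int),
            cluster_params=bad,
        )
        with pytest.raises(ValueError, match="plausible"):
            simulate_cohort(sphere_small, truth, CohortDesign(n_subjects=25),
                            seed=0)


class TestGeneratorModelConsistency:
    def test_noiseless_single_vertex_trajectory_recovery(self, sphere_small):
        # fitting the factor-smooth model to a noiseless simulation recovers
        # the generating LH-RH curve within 1% of its dynamic range
        from asymtraj.gamm import fit_factor_smooth

        truth = assign_truth_clusters(sphere_small, 3, 0.5, seed=20)
        design = CohortDesign(
            n_subjects=200, sigma_subject=0.0, sigma_asym_subject=0.0,
            sigma_noise=0.0, sex_offset=0.0, scanner_offsets=(0.0, 0.0),
        )
        ds = simulate_cohort(sphere_small, truth, design, seed=21)
        v = int(np.flatnonzero(truth.vertex_cluster_label == 1)[0])
        frame, y = ds.to_long(v)
        model = fit_factor_smooth(y, frame["age"], frame["hemisphere"],
                                  frame["subject"])
        ages = ds.observations["age"].to_numpy()
        grid = np.linspace(ages.min(), ages.max(), 100)
        est = model.trajectories(grid, include_intercept=True).asymmetry
        true = truth.cluster_params[1].asymmetry(grid)
        dyn_range = true.max() - true.min()
        assert np.abs(est - true).max() <= 0.01 * dyn_range


class TestCognition:
    def test_cognition_table_attached(self, sphere_small):
        truth = assign_truth_clusters(sphere_small, 1, 0.2, seed=30)
        ds = simulate_cohort(sphere_small, truth, CohortDesign(n_subjects=60),
                             seed=31, cognition=CognitionDesign())
        cog = ds.cognition
        assert len(cog) == ds.n_obs
        for col in ("cvlt_learning", "cvlt_immediate", "cvlt_delayed",
                    "matrix_raw", "test_version"):
            assert col in cog.columns

    def test_scores_decline_with_age(self, sphere_small):
        truth = assign_truth_clusters(sphere_small, 1, 0.2, seed=32)
        ds = simulate_cohort(sphere_small, truth,
                             CohortDesign(n_subjects=150), seed=33,
                             cognition=CognitionDesign(age_r2=0.4))
        r = stats.pearsonr(ds.cognition["age"],
                           ds.cognition["cvlt_delayed"]).statistic
        assert r < -0.3


class TestClinical:
    def test_zero_effect_slopes_equal(self):
        design = ClinicalDesign(sigma_subject=0.0, sigma_noise=0.0)
        clin = simulate_clinical(["roi1"], effect=0.0, design=design, seed=1)
        df = clin.rows.assign(asym=clin.roi_asymmetry["roi1"])
        slopes = {}
        for grp, sub in df.groupby("group_truth"):
            slopes[grp] = np.polyfit(sub["years_since_baseline"],
                                     sub["asym"], 1)[0]
        assert slopes["AD-long"] == pytest.approx(slopes["NC-long"], abs=1e-9)

    def test_noiseless_effect_visible_in_ad_slope(self):
        design = ClinicalDesign(sigma_subject=0.0, sigma_noise=0.0)
        clin = simulate_clinical(["roi1"], effect=-0.004, design=design,
                                 seed=2)
        df = clin.rows.assign(asym=clin.roi_asymmetry["roi1"])
        slopes = {
            grp: np.polyfit(sub["years_since_baseline"], sub["asym"], 1)[0]
            for grp, sub in df.groupby("group_truth")
        }
        assert slopes["AD-long"] - slopes["NC-long"] == pytest.approx(
            -0.004, abs=1e-9
        )

    def test_row_count_bound(self):
        clin = simulate_clinical(["roi1"], effect=0.0,
                                 design=ClinicalDesign(n_ad=41, n_nc=128),
                                 seed=3)
        assert len(clin.rows) <= 4 * 169
        tp_counts = clin.rows.groupby("subject")["timepoint"].count()
        assert tp_counts.between(2, 4).all()

    def test_group_round_trip_without_reversions(self):
        clin = simulate_clinical(["roi1"], effect=-0.002,
                                 design=ClinicalDesign(reversion_rate=0.0),
                                 seed=4)
        derived = define_longitudinal_groups(
            clin.rows[["subject", "timepoint", "diagnosis"]]
        )
        truth = clin.rows.groupby("subject")["group_truth"].first()
        assert (derived.loc[truth.index] == truth).all()

    def test_reversions_excluded(self):
        clin = simulate_clinical(["roi1"], effect=0.0,
                                 design=ClinicalDesign(reversion_rate=0.5),
                                 seed=5)
        derived = define_longitudinal_groups(
            clin.rows[["subject", "timepoint", "diagnosis"]]
        )
        assert (derived == "excluded").sum() > 0

    def test_empty_roi_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_clinical([], effect=0.0, seed=0)

    def test_nonfinite_effect_rejected(self):
        with pytest.raises(ValueError):
            simulate_clinical(["roi1"], effect=np.nan, seed=0)


class TestIO:
    def test_cohort_round_trip(self, sphere_small, tmp_path):
        truth = assign_truth_clusters(sphere_small, 2, 0.3, seed=40)
        ds = simulate_cohort(sphere_small, truth, CohortDesign(n_subjects=25),
                             seed=41, cognition=CognitionDesign())
        save_cohort(ds, truth, tmp_path / "c", seed=41)
        back = load_cohort(tmp_path / "c")
        np.testing.assert_allclose(back.thickness_lh, ds.thickness_lh,
                                   rtol=1e-12)
        assert len(back.cognition) == len(ds.cognition)
        t_back = load_truth(tmp_path / "c")
        np.testing.assert_array_equal(t_back.vertex_cluster_label,
                                      truth.vertex_cluster_label)
        assert t_back.cluster_params[1].left.slope == pytest.approx(
            truth.cluster_params[1].left.slope
        )


def test_default_params_cross_in_old_age():
    # leftward/rightward-loss families lose their asymmetry in the mid 70s
    params = default_cluster_params()
    ages = np.linspace(20, 90, 500)
    for lab, sign in ((1, 1.0), (3, -1.0)):
        d = sign * params[lab].asymmetry(ages)
        assert d[0] > 0.15                     # asymmetric in young adulthood
        crossing = ages[np.argmax(d < 0)]
        assert 68 <= crossing <= 82            # total loss around mid 70s
    assert np.allclose(params[0].asymmetry(ages), 0.0)
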