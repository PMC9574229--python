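import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from msrehab import netfc, synth, wmdamage
from msrehab.battery import DEFAULT_BATTERY, TestDef
from msrehab.synth import (
    CohortConfig,
    ConfigError,
    FcGenConfig,
    SkeletonGenConfig,
    construct_network_covariance,
    generate_scores,
    generate_skeleton_maps,
    generate_timeseries,
    immediate_effect_config,
)


class TestCohortConfigValidation:
    def test_counts_must_be_at_least_two(self):
        with pytest.raises(ConfigError, match="n_hc"):
            CohortConfig(n_hc=1)

    def test_responder_fraction_bounds(self):
        with pytest.raises(ConfigError, match="responder_fraction"):
            CohortConfig(responder_fraction=1.5)

    def test_non_positive_sd_rejected(self):
        good = TestDef("TST", "attention", True, 0.0, 1.0, 0.0, 1.0, 0.0)
        with pytest.raises(ValueError, match="non-positive SD"):
            dataclasses.replace(good, hc_sd=0.0)
        with pytest.raises(ValueError, match="non-positive SD"):
            dataclasses.replace(good, patient_sd=-1.0)

    def test_gain_for_unknown_test_rejected(self):
        with pytest.raises(ConfigError, match="unknown tests"):
            CohortConfig(responder_gain={"NOPE": 1.0})


class TestGenerateScores:
    def test_same_seed_identical_tables(self):
        a = generate_scores(CohortConfig(seed=11))
        b = generate_scores(CohortConfig(seed=11))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_different_seed_differs(self):
        a, _ = generate_scores(CohortConfig(seed=11))
        b, _ = generate_scores(CohortConfig(seed=12))
        assert not a["value"].equals(b["value"])

    def test_hc_assessed_only_at_baseline(self):
        scores, _ = generate_scores(CohortConfig(seed=0))
        assert set(scores.loc[scores["arm"] == "HC", "timepoint"]) == {"T0"}
        patients = scores[scores["arm"] != "HC"]
        assert set(patients["timepoint"]) == {"T0", "T1", "T2"}

    def test_hc_followup_rows_flagged_non_canonical(self):
        scores, _ = generate_scores(CohortConfig(seed=0, include_hc_followup=True))
        hc = scores[scores["arm"] == "HC"]
        assert set(hc["timepoint"]) == {"T0", "T1", "T2"}
        assert not hc.loc[hc["timepoint"] != "T0", "canonical"].any()
        assert hc.loc[hc["timepoint"] == "T0", "canonical"].all()

    def test_complete_grid_per_subject(self):
        scores, truth = generate_scores(CohortConfig(seed=1))
        patients = scores[scores["arm"] != "HC"]
        counts = patients.groupby("subject_id").size()
        assert (counts == len(DEFAULT_BATTERY) * 3).all()
        assert truth["is_latent_responder"].sum() == round(22 / 58 * 58)

    def test_hc_sample_mean_matches_reference(self):
        # LNS healthy-control reference 11.24 (1.87): with n_hc = 2000 the
        # sample mean must fall within 3 SD / sqrt(n) of the reference.
        cfg = CohortConfig(n_hc=2000, n_waitlist=2, n_intervention=2,
                           responder_gain={}, seed=5)
        scores, _ = generate_scores(cfg)
        lns = scores[(scores["arm"] == "HC") & (scores["test_id"] == "LNS")]
        assert abs(lns["value"].mean() - 11.24) < 3 * 1.87 / np.sqrt(2000)

    def test_waitlist_change_embodies_practice_effect(self, simple_test):
        cfg = CohortConfig(n_hc=2, n_waitlist=3000, n_intervention=2,
                           test_params=(simple_test,), responder_gain={}, seed=2)
        scores, _ = generate_scores(cfg)
        wl = scores[scores["arm"] == "waitlist"].pivot(
            index="subject_id", columns="timepoint", values="value")
        change = (wl["T1"] - wl["T0"]).mean()
        se = (wl["T1"] - wl["T0"]).std() / np.sqrt(len(wl))
        assert abs(change - simple_test.practice_effect) < 4 * se

    def test_responder_gain_shifts_intervention_retest(self, simple_test):
        cfg = CohortConfig(n_hc=2, n_waitlist=2, n_intervention=4000,
                           responder_fraction=0.5,
                           test_params=(simple_test,),
                           responder_gain={"TST": 1.0}, seed=3)
        scores, truth = generate_scores(cfg)
        resp = set(truth.loc[truth["is_latent_responder"], "subject_id"])
        iv = scores[scores["arm"] == "intervention"].pivot(
            index="subject_id", columns="timepoint", values="value")
        change = iv["T1"] - iv["T0"]
        gap = change[change.index.isin(resp)].mean() - change[~change.index.isin(resp)].mean()
        assert abs(gap - 1.0 * simple_test.patient_sd) < 0.15


class TestImmediateEffectConfig:
    def test_calibrated_followup_mean(self):
        lns = next(t for t in DEFAULT_BATTERY if t.test_id == "LNS")
        cfg = immediate_effect_config(
            test=lns, baseline_mean=10.28, baseline_sd=2.69, followup_mean=11.10,
            practice_effect=-0.25, n_intervention=20000, seed=9)
        scores, _ = generate_scores(cfg)
        iv = scores[(scores["arm"] == "intervention") & (scores["timepoint"] == "T1")]
        assert abs(iv["value"].mean() - 11.10) < 0.1

    def test_zero_fraction_rejected(self):
        lns = next(t for t in DEFAULT_BATTERY if t.test_id == "LNS")
        with pytest.raises(ConfigError):
            immediate_effect_config(
                test=lns, baseline_mean=10.0, baseline_sd=2.0, followup_mean=11.0,
                practice_effect=0.0, n_intervention=10, responder_fraction=0.0)


class TestNetworkCovariance:
    def test_homogeneous_targets_give_uniform_matrix(self):
        cfg = FcGenConfig(global_mean_corr=0.3,
                          target_norm_fc={p: 1.0 for p in
                                          itertools.combinations(synth.NETWORK_ORDER, 2)})
        nc = construct_network_covariance(cfg)
        off = nc.matrix[~np.eye(nc.matrix.shape[0], dtype=bool)]
        assert np.allclose(off, 0.3, atol=1e-12)
        assert np.allclose(np.diag(nc.matrix), 1.0)

    def test_small_instance_ratio_by_brute_force(self):
        # 2 regions in each of DMN and DAN, target DMN-DAN = 0.5 at g = 0.2;
        # the achieved ratio is recomputed here by explicit pair enumeration.
        cfg = FcGenConfig(
            n_regions={"DMN": 2, "DAN": 2, "VAN": 1, "FPN": 1, "other": 1},
            global_mean_corr=0.2,
            target_norm_fc={("DMN", "DAN"): 0.5, ("DMN", "VAN"): 1.0,
                            ("DMN", "FPN"): 1.0, ("DAN", "VAN"): 1.0,
                            ("DAN", "FPN"): 1.0, ("VAN", "FPN"): 1.0},
        )
        nc = construct_network_covariance(cfg)
        mat, nets = nc.matrix, nc.networks
        ab, all_off = [], []
        n = mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                all_off.append(mat[i, j])
                if {nets[i], nets[j]} == {"DMN", "DAN"}:
                    ab.append(mat[i, j])
        assert np.mean(ab) / np.mean(all_off) == pytest.approx(0.5, abs=1e-12)
        assert np.mean(all_off) == pytest.approx(0.2, abs=1e-12)

    def test_table_level_targets_achieved_exactly(self):
        # group-level normalized-FC profile typical of non-responders
        targets = {("DMN", "DAN"): 0.92, ("DMN", "VAN"): 0.98,
                   ("DMN", "FPN"): 1.18, ("DAN", "VAN"): 1.20,
                   ("DAN", "FPN"): 1.25, ("VAN", "FPN"): 1.06}
        nc = construct_network_covariance(FcGenConfig(target_norm_fc=targets))
        assert not nc.projected
        for pair, want in targets.items():
            assert nc.achieved[pair] == pytest.approx(want, abs=1e-6)

    def test_unsatisfiable_target_names_pair(self):
        targets = {p: 1.0 for p in itertools.combinations(synth.NETWORK_ORDER, 2)}
        targets[("DMN", "VAN")] = 6.0
        with pytest.raises(ConfigError, match="DMN-VAN"):
            construct_network_covariance(
                FcGenConfig(global_mean_corr=0.2, target_norm_fc=targets))

    def test_psd_projection_reports_achieved(self):
        # wildly heterogeneous targets force an indefinite block matrix
        targets = {("DMN", "DAN"): 4.5, ("DMN", "VAN"): 0.1,
                   ("DMN", "FPN"): 4.5, ("DAN", "VAN"): 0.1,
                   ("DAN", "FPN"): 0.1, ("VAN", "FPN"): 4.5}
        nc = construct_network_covariance(
            FcGenConfig(global_mean_corr=0.2, target_norm_fc=targets))
        evals = np.linalg.eigvalsh(nc.matrix)
        assert evals[0] >= -1e-10
        if nc.projected:
            assert nc.achieved != pytest.approx(nc.requested)


class TestGenerateTimeseries:
    def test_identity_covariance_uncorrelated(self):
        ts = generate_timeseries(np.eye(12), 4000, seed=0)
        corr = np.corrcoef(ts, rowvar=False)
        off = np.abs(corr[~np.eye(12, dtype=bool)])
        assert np.quantile(off, 0.9) < 4 / np.sqrt(4000)

    def test_rank_one_covariance_degenerate(self):
        ts = generate_timeseries(np.ones((4, 4)), 100, seed=0)
        corr = np.corrcoef(ts, rowvar=False)
        assert np.allclose(corr, 1.0, atol=1e-10)

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_timeseries(bad, 10, seed=0)

    def test_round_trip_normalized_fc_converges(self):
        # generator -> correlation -> pair means -> normalization recovers
        # the configured targets at long series length
        cfg = FcGenConfig(n_timepoints=10_000)
        nc = construct_network_covariance(cfg)
        ts = generate_timeseries(nc, cfg.n_timepoints, seed=4)
        profile = netfc.network_pair_fc(netfc.timeseries_to_fc(ts), nc.networks)
        for (a, b), want in cfg.target_norm_fc.items():
            assert profile[f"norm_{a}-{b}"] == pytest.approx(want, abs=0.02)


class TestSkeletonMaps:
    def test_same_seed_identical(self):
        cfg = SkeletonGenConfig(n_voxels=50, seed=7)
        a = generate_skeleton_maps(cfg, 5)
        b = generate_skeleton_maps(cfg, 5)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_null_shift_severity_near_zero(self):
        cfg = SkeletonGenConfig(n_voxels=3000, group_shift=0.0, seed=1)
        maps, ref = generate_skeleton_maps(cfg, 200)
        damage = wmdamage.damage_summary(wmdamage.voxel_zscores(maps, ref))
        se = cfg.subject_sd / np.sqrt(200)
        assert abs(damage["severity"].mean()) < 4 * se
        assert damage["severity"].std() == pytest.approx(cfg.subject_sd, rel=0.25)

    def test_null_extent_matches_gaussian_tail(self):
        from scipy.stats import norm
        cfg = SkeletonGenConfig(n_voxels=5000, group_shift=0.0, subject_sd=0.0, seed=2)
        maps, ref = generate_skeleton_maps(cfg, 200)
        z = wmdamage.voxel_zscores(maps, ref)
        frac = (z.to_numpy() < -3.1).mean()
        expected = norm.cdf(-3.1)
        se = np.sqrt(expected * (1 - expected) / z.size)
        assert abs(frac - expected) < 4 * se

    def test_group_shift_moves_severity(self):
        cfg = SkeletonGenConfig(n_voxels=2000, group_shift=0.3, subject_sd=0.0, seed=3)
        maps, ref = generate_skeleton_maps(cfg, 100)
        damage = wmdamage.damage_summary(wmdamage.voxel_zscores(maps, ref))
        assert damage["severity"].mean() == pytest.approx(-0.3, abs=0.01)

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            SkeletonGenConfig(n_voxels=0)
        with pytest.raises(ConfigError):
            SkeletonGenConfig(hc_sd=0.0)
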