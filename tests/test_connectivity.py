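"""Nuisance filtering and global connectedness."""

import numpy as np
import pandas as pd
import pytest

import revlearn as rl
from revlearn.connectivity import (
    ConnectednessMap,
    build_filter_matrix,
    compare_sessions,
    expand_motion,
    global_connectedness,
    residualize,
    seed_peak_select,
    timebin_connectedness,
)
from revlearn.similarity import CLIP_EPS


class TestResidualize:
    def test_constant_only_demeans(self):
        rng = np.random.default_rng(0)
        B = rng.normal(3.0, 1.0, size=(50, 4))
        R = residualize(B, np.ones((50, 1)))
        assert np.allclose(R, B - B.mean(axis=0), atol=1e-12)

    def test_hand_ols_small_example(self):
        # 4 volumes, 2 voxels, regress out a single centered slope column
        B = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 4.0]])
        F = np.array([[-1.5], [-0.5], [0.5], [1.5]])
        W = np.linalg.inv(F.T @ F) @ F.T @ B  # the normal-equations formula
        assert np.allclose(residualize(B, F), B - F @ W, atol=1e-10)

    def test_b_in_span_of_f_gives_zero(self):
        rng = np.random.default_rng(1)
        F = np.column_stack([np.ones(30), np.linspace(0, 1, 30)])
        B = F @ rng.normal(size=(2, 5))
        assert np.allclose(residualize(B, F), 0.0, atol=1e-10)

    def test_projection_idempotent(self):
        rng = np.random.default_rng(2)
        B = rng.normal(size=(60, 8))
        F = np.column_stack([np.ones(60), rng.normal(size=(60, 3))])
        R1 = residualize(B, F)
        R2 = residualize(R1, F)
        assert np.allclose(R1, R2, atol=1e-10)
        assert np.max(np.abs(F.T @ R1)) < 1e-8

    def test_rank_deficient_names_columns(self):
        F = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(np.linalg.LinAlgError, match="dependent"):
            residualize(np.zeros((20, 2)), F)


class TestFilterMatrix:
    def test_columns_z_scored_except_constant(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(100, 30))
        labels = np.r_[np.ones(10), np.full(10, 2), np.full(10, 3)].astype(int)
        conf = rng.normal(2.0, 5.0, size=(100, 4))
        F = build_filter_matrix(B, labels, conf)
        assert np.allclose(F[:, -1], 1.0)  # constant last
        assert np.allclose(F[:, :-1].mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(F[:, :-1].std(axis=0), 1.0, atol=1e-10)

    def test_motion_expansion_shape(self):
        m = np.random.default_rng(4).normal(size=(50, 6))
        assert expand_motion(m).shape == (50, 24)

    def test_spike_columns(self):
        rng = np.random.default_rng(5)
        B = rng.normal(size=(40, 6))
        labels = np.array([1, 1, 2, 2, 3, 3])
        F = build_filter_matrix(B, labels, spikes=[3, 17])
        # one dummy per spike volume, z-scored
        assert F.shape[1] == 3 + 1 + 2 + 1  # tissue means, drift, spikes, constant


class TestGlobalConnectedness:
    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(6)
        R = rng.standard_normal((4000, 2))
        out = global_connectedness(R, np.ones(2, bool))
        assert np.all(out.values < 0.06)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        R = rng.standard_normal((50, 20))
        out = global_connectedness(R, np.ones(20, bool))
        # independent double loop over voxel pairs
        expect = np.zeros(20)
        for i in range(20):
            vals = []
            for j in range(20):
                if i == j:
                    continue
                r = np.corrcoef(R[:, i], R[:, j])[0, 1]
                vals.append(abs(np.arctanh(np.clip(r, -1 + CLIP_EPS, 1 - CLIP_EPS))))
            expect[i] = np.mean(vals)
        assert np.allclose(out.values, expect, atol=1e-10)

    def test_planted_hub_exceeds_background(self):
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            R = rng.standard_normal((120, 100))
            latent = rng.standard_normal(120)
            R[:, :10] += latent[:, None]  # 10-voxel hub
            out = global_connectedness(R, np.ones(100, bool))
            if out.values[:10].mean() > out.values[10:].mean():
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_voxel_order_and_scale_invariance(self):
        rng = np.random.default_rng(8)
        R = rng.standard_normal((80, 12))
        base = global_connectedness(R, np.ones(12, bool)).values
        perm = rng.permutation(12)
        permuted = global_connectedness(R[:, perm], np.ones(12, bool)).values
        assert np.allclose(permuted, base[perm], atol=1e-12)
        scaled = R.copy()
        scaled[:, 4] = 7.3 * scaled[:, 4] - 2.0
        assert np.allclose(
            global_connectedness(scaled, np.ones(12, bool)).values, base, atol=1e-10
        )

    def test_exclusion_changes_values_not_coverage(self):
        rng = np.random.default_rng(9)
        R = rng.standard_normal((60, 15))
        gray = np.ones(15, bool)
        excl = np.zeros(15, bool)
        excl[:5] = True
        full = global_connectedness(R, gray)
        part = global_connectedness(R, gray, exclude_mask=excl)
        assert np.isfinite(part.values).sum() == np.isfinite(full.values).sum()
        assert not np.allclose(part.values, full.values)

    def test_constant_voxel_dropped_with_count(self):
        rng = np.random.default_rng(10)
        R = rng.standard_normal((40, 6))
        R[:, 2] = 5.0
        out = global_connectedness(R, np.ones(6, bool))
        assert np.isnan(out.values[2])
        assert out.n_constant_dropped == 1

    def test_too_few_volumes_or_voxels(self):
        with pytest.raises(ValueError):
            global_connectedness(np.zeros((2, 5)), np.ones(5, bool))
        with pytest.raises(ValueError):
            global_connectedness(np.zeros((10, 5)), np.r_[True, np.zeros(4, bool)])


class TestTimebins:
    def test_bin_count_and_stationarity(self):
        from revlearn.synth import (
            VoxelSimConfig,
            assemble_confound_columns,
            gen_voxel_timeseries,
        )

        cfg = rl.TaskConfig(
            n_runs=3, trials_per_run=16, reversals_per_cue_per_run=1, seed=0
        )
        sched = rl.generate_schedule(cfg)
        beh = rl.simulate_agent(sched, rl.AgentParams(0.8, 5.0), 0)
        vcfg = VoxelSimConfig(
            dims=(8, 8, 6), n_vols_per_run=110, identity_amp=0, ipe_amp=0
        )
        ds = gen_voxel_timeseries(vcfg, sched, beh, seed=1, session="sham")
        conf = assemble_confound_columns(ds.confounds)
        bins = timebin_connectedness(
            ds.data, ds.run_lengths, ds.tissue_labels, ds.masks["hub"], conf
        )
        assert bins.shape == (6,)
        # stationary data: no early-vs-late trend beyond noise
        assert abs(bins[:2].mean() - bins[-2:].mean()) < 0.02

    def test_ctbs_attenuation_recovers_timecourse(self):
        from revlearn.synth import (
            VoxelSimConfig,
            assemble_confound_columns,
            gen_voxel_timeseries,
        )

        cfg = rl.TaskConfig(
            n_runs=3, trials_per_run=16, reversals_per_cue_per_run=1, seed=1
        )
        sched = rl.generate_schedule(cfg)
        beh = rl.simulate_agent(sched, rl.AgentParams(0.8, 5.0), 1)
        vcfg = VoxelSimConfig(
            dims=(8, 8, 6), n_vols_per_run=110, identity_amp=0, ipe_amp=0
        )
        diffs = np.zeros(6)
        n_rep = 6
        for rep in range(n_rep):
            dss = gen_voxel_timeseries(vcfg, sched, beh, seed=rep, session="sham")
            dsc = gen_voxel_timeseries(vcfg, sched, beh, seed=rep, session="ctbs")
            for ds, sign in ((dss, 1.0), (dsc, -1.0)):
                conf = assemble_confound_columns(ds.confounds)
                diffs += sign * timebin_connectedness(
                    ds.data, ds.run_lengths, ds.tissue_labels, ds.masks["hub"], conf
                )
        diffs /= n_rep
        # seeds are paired across sessions, so the attenuation shows up as a
        # small but systematic early-bin excess; late bins have recovered
        assert diffs[:2].mean() > 0.0004  # early sham > ctbs
        assert abs(diffs[2:].mean()) < diffs[:2].mean()

    def test_short_bin_warns(self):
        rng = np.random.default_rng(11)
        B = rng.standard_normal((12, 8))
        with pytest.warns(UserWarning, match="short"):
            timebin_connectedness(
                B, [12], np.ones(8, int), np.ones(8, bool), n_bins_per_run=2
            )


class TestCompareSessions:
    def test_identical_sessions_no_rejection(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(10, 3))
        res = compare_sessions(x, x + 0.0)
        assert (res["p"] > 0.4).all()

    def test_hand_rank_computation(self):
        # differences: +1 +2 +3 -1 +4 +5 -> positive ranks of |d|: d sorted by
        # |d| gives ranks 1.5 (the two |1|s), 3, 4, 5, 6; V = sum of ranks of
        # positive differences = 1.5 + 3 + 4 + 5 + 6 = 19.5
        sham = np.array([[2.0], [3.0], [4.0], [0.0], [5.0], [6.0]])
        ctbs = np.array([[1.0], [1.0], [1.0], [1.0], [1.0], [1.0]])
        res = compare_sessions(sham, ctbs)
        assert res.loc[0, "V"] == 19.5

    def test_small_sample_notes_exact(self):
        res = compare_sessions(np.ones((4, 1)) + np.arange(4)[:, None], np.ones((4, 1)))
        assert "exact" in res.loc[0, "note"]


class TestSeedPeak:
    def test_planted_noisy_copy_selected(self):
        rng = np.random.default_rng(13)
        n_vox = 30
        data = rng.standard_normal((200, n_vox))
        seed_mask = np.zeros(n_vox, bool)
        seed_mask[:5] = True
        search_mask = np.zeros(n_vox, bool)
        search_mask[10:20] = True
        seed_mean = data[:, :5].mean(axis=1)
        data[:, 14] = seed_mean + 0.3 * rng.standard_normal(200)
        vox, r = seed_peak_select(data, seed_mask, search_mask)
        assert vox == 14
        assert r > 0.7

    def test_all_noise_peak_correlation_small(self):
        rng = np.random.default_rng(14)
        peaks = []
        for _ in range(10):
            data = rng.standard_normal((300, 20))
            _, r = seed_peak_select(
                data, np.r_[np.ones(5, bool), np.zeros(15, bool)],
                np.r_[np.zeros(5, bool), np.ones(15, bool)],
            )
            peaks.append(r)
        assert np.mean(peaks) < 0.25

    def test_exact_tie_lowest_index(self):
        data = np.zeros((50, 4))
        t = np.sin(np.linspace(0, 6, 50))
        data[:, 0] = t  # seed
        data[:, 2] = t
        data[:, 3] = t  # exact tie with voxel 2
        vox, r = seed_peak_select(
            data, np.array([True, False, False, False]),
            np.array([False, False, True, True]),
        )
        assert vox == 2

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            seed_peak_select(np.zeros((10, 3)), np.zeros(3, bool), np.ones(3, bool))
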