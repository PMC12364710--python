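"""RSA pipeline: preprocessing, RDM construction, subset sampling,
searchlight geometry (with a brute-force lattice oracle), noise ceilings
and BH-FDR group inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capbrain as cb
from capbrain.rsa import AvgResponses
from capbrain.syndata import TrialResponses


def _avg(values, ids=None):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = np.array([f"s{i}" for i in range(values.shape[0])])
    return AvgResponses(values=values, stimulus_ids=ids)


class TestPreprocessBetas:
    def test_zscore_then_average(self):
        rng = np.random.default_rng(0)
        betas = rng.normal(size=(30, 5))
        trials = TrialResponses(
            betas=betas,
            session_id=np.repeat([0, 1], 15),
            stimulus_id=np.repeat([f"s{i}" for i in range(10)], 3),
            repetition=np.tile([0, 1, 2], 10),
        )
        avg = cb.preprocess_betas(trials)
        assert avg.values.shape == (10, 5)
        # z-scoring: per session, per voxel mean 0 / sd 1 before averaging
        for s in (0, 1):
            block = (betas[trials.session_id == s]
                     - betas[trials.session_id == s].mean(0))
            z = block / betas[trials.session_id == s].std(0)
            np.testing.assert_allclose(z.mean(0), 0, atol=1e-12)
            np.testing.assert_allclose(z.std(0), 1, atol=1e-12)

    def test_incomplete_repetitions_dropped(self):
        trials = TrialResponses(
            betas=np.arange(16, dtype=float).reshape(8, 2),
            session_id=np.zeros(8, dtype=int),
            stimulus_id=np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 2),
            repetition=np.array([0, 1, 2, 0, 1, 2, 0, 1]),
        )
        avg = cb.preprocess_betas(trials)
        assert list(avg.stimulus_ids) == ["a", "b"]

    def test_single_trial_session_raises(self):
        trials = TrialResponses(
            betas=np.ones((4, 2)),
            session_id=np.array([0, 0, 0, 3]),
            stimulus_id=np.array(["a", "b", "c", "d"]),
            repetition=np.zeros(4, dtype=int),
        )
        with pytest.raises(ValueError, match="session 3"):
            cb.preprocess_betas(trials)

    def test_constant_voxel_flagged_zero(self):
        rng = np.random.default_rng(1)
        betas = rng.normal(size=(6, 3))
        betas[:, 1] = 7.0
        trials = TrialResponses(
            betas=betas, session_id=np.zeros(6, dtype=int),
            stimulus_id=np.repeat(["a", "b", "c"], 2),
            repetition=np.tile([0, 1], 3),
        )
        with pytest.warns(UserWarning, match="constant"):
            avg = cb.preprocess_betas(trials)
        np.testing.assert_allclose(avg.values[:, 1], 0.0)

    def test_session_gains_removed_by_zscoring(self):
        # two sessions carrying the same signal at gains 1 and 10 agree
        # after z-scoring (cross-session RDM correlation ~ 1 at zero noise)
        scenes = cb.make_scenes(30, d=8, caption_noise=0.0, seed=2)
        brain = cb.build_brain_model(
            (4, 3, 2), cb.split_grid_regions((4, 3, 2), 1, 8), d=8,
            noise_sd=0.0, seed=2,
        )
        rdms = []
        for gain in (1.0, 10.0):
            trials = cb.simulate_trial_responses(
                brain, scenes, n_reps=2, n_sessions=1,
                gain_range=(gain, gain), offset_range=(3.0, 3.0), seed=2,
            )
            rdms.append(cb.compute_rdm(cb.preprocess_betas(trials)))
        assert cb.rdm_correlation(rdms[0], rdms[1]) > 0.99


class TestComputeRdm:
    def test_trivial_distances(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=6)
        vals = np.stack([base, base.copy(),
                         -(base - base.mean()) + base.mean()])
        rdm = cb.compute_rdm(_avg(vals))
        assert rdm.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm.values[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_uncorrelated_patterns_distance_one(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        rdm = cb.compute_rdm(_avg(np.stack([a, b, a + b])))
        assert rdm.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_zero_diag_range(self):
        rng = np.random.default_rng(4)
        rdm = cb.compute_rdm(_avg(rng.normal(size=(20, 15))))
        np.testing.assert_allclose(rdm.values, rdm.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rdm.values), 0.0)
        assert rdm.values.min() >= 0.0 and rdm.values.max() <= 2.0

    def test_zero_variance_pattern_neutral(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(4, 6))
        vals[2] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            rdm = cb.compute_rdm(_avg(vals))
        np.testing.assert_allclose(rdm.values[2, [0, 1, 3]], 1.0)
        assert rdm.values[2, 2] == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0),
           st.floats(-5.0, 5.0))
    def test_affine_pattern_invariance(self, seed, scale, shift):
        # per-stimulus positive-scale affine transforms leave the RDM fixed
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(8, 12))
        scales = scale * (1 + rng.random(8))[:, None]
        shifts = shift * rng.random(8)[:, None]
        a = cb.compute_rdm(_avg(vals))
        b = cb.compute_rdm(_avg(vals * scales + shifts))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestRdmCorrelation:
    def test_self_and_affine(self):
        rng = np.random.default_rng(6)
        rdm = cb.compute_rdm(_avg(rng.normal(size=(12, 9))))
        assert cb.rdm_correlation(rdm, rdm) == pytest.approx(1.0)
        scaled = cb.rsa.RDM(values=0.4 * rdm.values, stimulus_ids=rdm.stimulus_ids)
        assert cb.rdm_correlation(rdm, scaled) == pytest.approx(1.0)

    def test_upper_triangle_length_100(self):
        rng = np.random.default_rng(7)
        rdm = cb.compute_rdm(_avg(rng.normal(size=(100, 5))))
        assert rdm.upper_triangle().shape == (4950,)

    def test_id_mismatch_raises(self):
        rng = np.random.default_rng(8)
        a = cb.compute_rdm(_avg(rng.normal(size=(5, 4))))
        b = cb.compute_rdm(_avg(rng.normal(size=(5, 4)),
                                ids=np.array(list("vwxyz"))))
        with pytest.raises(ValueError, match="stimulus ids"):
            cb.rdm_correlation(a, b)


class TestSampledRsa:
    @pytest.mark.parametrize("n,expected", [(10000, 100), (6234, 62), (5445, 54)])
    def test_split_counts(self, n, expected):
        ids = np.arange(n)
        parts = cb.partition_stimuli(ids, 100, seed=0)
        assert len(parts) == expected
        used = np.concatenate(parts)
        assert len(np.unique(used)) == len(used)  # disjoint

    def test_subset_equals_full_when_size_is_n(self):
        rng = np.random.default_rng(9)
        resp = _avg(rng.normal(size=(40, 20)))
        model_feats = rng.normal(size=(40, 6))
        full = cb.rdm_correlation(cb.compute_rdm(resp),
                                  cb.compute_rdm(_avg(model_feats,
                                                      ids=resp.stimulus_ids)))
        res = cb.sampled_rsa(resp, model_feats, subset_size=40, seed=1)
        assert res.n_splits == 1
        assert res.mean_r == pytest.approx(full, abs=1e-12)

    def test_random_model_near_zero(self):
        rng = np.random.default_rng(10)
        resp = _avg(rng.normal(size=(120, 25)))
        rs = [
            cb.sampled_rsa(resp, np.random.default_rng(s).normal(size=(120, 8)),
                           subset_size=30, seed=s).mean_r
            for s in range(20)
        ]
        assert abs(np.mean(rs)) < 0.02

    def test_too_few_stimuli_raise(self):
        resp = _avg(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError):
            cb.sampled_rsa(resp, resp.values, subset_size=50)


def _brute_force_members(mask, center, radius):
    members = []
    vol_index = np.full(mask.shape, -1)
    vol_index[mask] = np.arange(mask.sum())
    total = 0
    for dx in range(-10, 11):
        for dy in range(-10, 11):
            for dz in range(-10, 11):
                if dx * dx + dy * dy + dz * dz <= radius * radius:
                    total += 1
                    x, y, z = center[0] + dx, center[1] + dy, center[2] + dz
                    if (0 <= x < mask.shape[0] and 0 <= y < mask.shape[1]
                            and 0 <= z < mask.shape[2] and mask[x, y, z]):
                        members.append(vol_index[x, y, z])
    return sorted(members), total


class TestSearchlight:
    def test_radius_zero_and_one_counts(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        r0 = cb.searchlight_spheres(mask, radius=0)
        assert all(len(s.members) == 1 for s in r0)
        r1 = cb.searchlight_spheres(mask, radius=1, min_inside_fraction=0.0)
        center = [s for s in r1 if s.center == (2, 2, 2)][0]
        assert len(center.members) == 7  # center + 6 face neighbours

    @pytest.mark.parametrize("radius", range(7))
    def test_members_match_brute_force(self, radius):
        rng = np.random.default_rng(11)
        mask = rng.random((9, 8, 7)) < 0.7
        mask[4, 4, 3] = True
        spheres = cb.searchlight_spheres(mask, radius=radius,
                                         min_inside_fraction=0.0)
        by_center = {s.center: s for s in spheres}
        for center in [(0, 0, 0), (4, 4, 3), (8, 7, 6)]:
            if not mask[center]:
                continue
            expected, _ = _brute_force_members(mask, center, radius)
            got = sorted(by_center[center].members)
            assert got == expected

    def test_strict_inclusion_threshold(self):
        # a sphere with exactly half its lattice points in the mask is
        # dropped: the rule is strictly more than the threshold
        mask = np.zeros((3, 1, 1), dtype=bool)
        mask[1:, 0, 0] = True  # radius-1 sphere at (1,0,0): 2 of 4 inside
        spheres = cb.searchlight_spheres(mask, radius=1, min_inside_fraction=0.5)
        assert (1, 0, 0) not in [s.center for s in spheres]

    def test_negative_radius_raises(self):
        with pytest.raises(ValueError):
            cb.searchlight_spheres(np.ones((2, 2, 2), bool), radius=-1)

    def test_searchlight_localizes_model_to_its_region(self):
        scenes = cb.make_scenes(80, d=12, caption_noise=0.0, seed=12)
        brain = cb.build_brain_model(
            (8, 4, 3), cb.split_grid_regions((8, 4, 3), 2, 12), d=12,
            noise_sd=0.0, seed=12,
        )
        trials = cb.simulate_trial_responses(brain, scenes, n_reps=2, seed=12)
        avg = cb.preprocess_betas(trials)
        # model carrying only region0's embedding dims
        dims = brain.regions[0].embedding_dims
        order = [list(scenes.scene_ids).index(s) for s in avg.stimulus_ids]
        model = scenes.true_embedding[order][:, dims]
        spheres = cb.searchlight_spheres(brain.in_brain, radius=1,
                                         min_inside_fraction=0.0)
        stat = cb.searchlight_rsa(avg, model, spheres, subset_size=40, seed=12)
        # map center -> in-region flag via the region_id volume
        flags = np.array([brain.region_id[s.center] == 0 for s in spheres])
        assert np.nanmean(stat[flags]) > np.nanmean(stat[~flags]) + 0.2

    def test_shuffled_model_map_near_zero(self):
        rng = np.random.default_rng(13)
        resp = _avg(rng.normal(size=(60, 24)))
        model = resp.values[rng.permutation(60)][:, :6]
        mask = np.ones((4, 3, 2), dtype=bool)
        spheres = cb.searchlight_spheres(mask, radius=1,
                                         min_inside_fraction=0.0)
        stat = cb.searchlight_rsa(resp, model, spheres, subset_size=30, seed=13)
        assert abs(np.nanmean(stat)) < 0.1


class TestNoiseCeiling:
    def test_identical_participants_ceiling_one(self):
        rng = np.random.default_rng(14)
        rdm = cb.compute_rdm(_avg(rng.normal(size=(15, 10))))
        ceilings = cb.rsa_noise_ceiling([rdm, rdm, rdm])
        np.testing.assert_allclose(ceilings, 1.0, atol=1e-12)

    def test_pure_noise_participant_near_zero(self):
        rng = np.random.default_rng(15)
        shared = rng.normal(size=(40, 30))
        rdms = [cb.compute_rdm(_avg(shared + 0.1 * rng.normal(size=shared.shape)))
                for _ in range(3)]
        rdms.append(cb.compute_rdm(_avg(rng.normal(size=shared.shape))))
        ceilings = cb.rsa_noise_ceiling(rdms)
        assert np.all(ceilings[:3] > 0.8)
        assert abs(ceilings[3]) < 0.15

    def test_ceiling_decreases_with_noise(self):
        ceilings = []
        for noise in (0.1, 1.0, 4.0):
            cohort = cb.make_cohort(
                n_participants=3, n_shared=30, n_unique=10,
                grid_shape=(4, 3, 2), d=8, noise_sd=noise, snr=None,
                caption_noise=0.0, n_reps=3, n_sessions=1, seed=16,
            )
            rdms = []
            for part in cohort.participants:
                avg = cb.preprocess_betas(part.trials)
                keep = np.isin(avg.stimulus_ids, cohort.shared_ids)
                rdms.append(cb.compute_rdm(
                    _avg(avg.values[keep], ids=avg.stimulus_ids[keep])))
            ceilings.append(cb.rsa_noise_ceiling(rdms).mean())
        assert ceilings[0] > ceilings[1] > ceilings[2]

    def test_two_participants_raise(self):
        rng = np.random.default_rng(17)
        rdm = cb.compute_rdm(_avg(rng.normal(size=(5, 4))))
        with pytest.raises(ValueError):
            cb.rsa_noise_ceiling([rdm, rdm])


def _bh_stepup_oracle(pvals, alpha):
    """Textbook Benjamini-Hochberg step-up: largest k with p_(k) <= k/m*alpha."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if below.size:
        reject[order[: below.max() + 1]] = True
    return reject


class TestGroupInference:
    def test_bh_example_three_rejections(self):
        # participants engineered to give p ~ [0.01, 0.02, 0.03, 0.5]
        p = np.array([0.01, 0.02, 0.03, 0.5])
        assert _bh_stepup_oracle(p, 0.05).sum() == 3

    def test_all_zero_values(self):
        res = cb.group_inference(np.zeros((4, 3)))
        np.testing.assert_allclose(res.t, 0.0)
        np.testing.assert_allclose(res.p, 1.0)
        assert not res.sig.any()

    def test_rejections_match_bh_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(200):
            m = rng.integers(3, 40)
            vals = rng.normal(scale=1.0, size=(6, m)) + rng.normal(size=m)
            res = cb.group_inference(vals, alpha=0.05)
            oracle = _bh_stepup_oracle(res.p, 0.05)
            np.testing.assert_array_equal(res.sig, oracle)

    def test_zero_variance_nonnull_excluded(self):
        vals = np.vstack([np.ones(3), np.ones(3), np.ones(3)])
        vals[:, 1] = np.random.default_rng(19).normal(size=3)
        vals[:, 2] = 0.0
        with pytest.warns(UserWarning, match="zero variance"):
            res = cb.group_inference(vals)
        assert np.isnan(res.p[0]) and not res.sig[0]
        assert res.p[2] == 1.0

    def test_sig_equals_q_below_alpha(self):
        rng = np.random.default_rng(20)
        vals = rng.normal(size=(8, 50)) + 0.8
        res = cb.group_inference(vals, alpha=0.05)
        ok = np.isfinite(res.q)
        np.testing.assert_array_equal(res.sig[ok], res.q[ok] <= 0.05)
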