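"""Classification arrays: weighted sums, permutation z-scoring, re-centering,
and chance-level exclusion."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from bubblerc import (
    StimulusGeometry,
    build_recenter_frame,
    exclude_guesser,
    gaussian_bubble,
    permutation_zscore,
    raw_classification_array,
    recenter_profile,
    window_kernel,
)
from bubblerc.classify import classify_participant, profiles_from_log
from bubblerc.io import read_trial_log, write_trial_log
from bubblerc.masks import temporal_profiles
from bubblerc.observer import ObserverModel, simulate_experiment


class TestRawClassificationArray:
    def test_all_correct_is_plain_sum(self, rng):
        profiles = rng.random((5, 12))
        out = raw_classification_array(profiles, [True] * 5)
        np.testing.assert_allclose(out, profiles.sum(axis=0))

    def test_one_correct_one_incorrect(self, rng):
        p, q = rng.random((2, 12))
        np.testing.assert_allclose(
            raw_classification_array([p, q], [True, False]), p - q
        )

    def test_antisymmetry_under_label_flip(self, rng):
        profiles = rng.random((20, 8))
        correct = rng.random(20) < 0.6
        a = raw_classification_array(profiles, correct)
        b = raw_classification_array(profiles, ~correct)
        np.testing.assert_allclose(a, -b)

    def test_linearity_over_concatenated_logs(self, rng):
        p1, p2 = rng.random((2, 10, 6))
        c1 = rng.random(10) < 0.5
        c2 = rng.random(10) < 0.5
        whole = raw_classification_array(
            np.concatenate([p1, p2]), np.concatenate([c1, c2])
        )
        np.testing.assert_allclose(
            whole,
            raw_classification_array(p1, c1) + raw_classification_array(p2, c2),
        )

    def test_length_mismatch_and_empty(self, rng):
        with pytest.raises(ValueError):
            raw_classification_array(rng.random((3, 4)), [True, False])
        with pytest.raises(ValueError):
            raw_classification_array(np.empty((0, 4)), [])


class TestPermutationZscore:
    def test_identical_profiles_fully_degenerate(self):
        profiles = np.tile(np.linspace(0, 1, 7), (2, 1))
        arr = permutation_zscore(profiles, [True, False], n_permutations=100, seed=1)
        np.testing.assert_allclose(arr.raw, 0)
        np.testing.assert_allclose(arr.z, 0)
        assert arr.degenerate.all()

    def test_single_label_rejected(self, rng):
        with pytest.raises(ValueError, match="one correctness label"):
            permutation_zscore(rng.random((4, 5)), [True] * 4)

    def test_matches_exhaustive_enumeration_at_four_trials(self, rng):
        # label shuffles without replacement = uniform over C(4,2)=6 assignments
        profiles = rng.random((4, 9))
        correct = np.array([True, True, False, False])
        perm_stats = []
        for pos in combinations(range(4), 2):
            w = np.full(4, -1.0)
            w[list(pos)] = 1.0
            perm_stats.append(w @ profiles)
        exact_mean = np.mean(perm_stats, axis=0)
        exact_sd = np.std(perm_stats, axis=0)
        arr = permutation_zscore(profiles, correct, n_permutations=100_000, seed=2)
        np.testing.assert_allclose(arr.perm_sd, exact_sd, rtol=0.01)
        # exact means are ~0; compare on the sd scale rather than relative
        np.testing.assert_allclose(
            (arr.perm_mean - exact_mean) / exact_sd, 0, atol=0.01
        )

    def test_invariant_to_profile_scaling(self, rng):
        profiles = rng.random((30, 11))
        correct = rng.random(30) < 0.6
        a = permutation_zscore(profiles, correct, n_permutations=500, seed=3)
        b = permutation_zscore(3.7 * profiles, correct, n_permutations=500, seed=3)
        np.testing.assert_allclose(a.z, b.z, atol=1e-10)

    def test_counts_and_coverage(self, rng):
        profiles = rng.random((10, 4))
        correct = np.array([True] * 6 + [False] * 4)
        arr = permutation_zscore(profiles, correct, n_permutations=200, seed=4)
        assert arr.n_correct == 6 and arr.n_incorrect == 4
        np.testing.assert_allclose(arr.coverage, profiles.sum(axis=0))

    def test_guesser_z_standard_normal_across_replicates(self, geometry):
        # under label exchangeability each point's z is ~ N(0, 1)
        zs = []
        for rep in range(30):
            rng = np.random.default_rng(100 + rep)
            centers = rng.uniform(0.5, 96.5, (384, 8))
            profiles = temporal_profiles(centers, 3.0, geometry)
            correct = rng.random(384) < 0.5
            arr = permutation_zscore(profiles, correct, n_permutations=500, rng=rng)
            zs.append(arr.z)
        z = np.concatenate(zs)
        assert abs(z.mean()) < 0.06
        assert 0.9 < z.std() < 1.1


class TestKernelRecovery:
    def test_rca_correlates_with_generating_kernel(self, geometry):
        # expected RCA under the linear observer model is kernel-shaped
        kernel = window_kernel(geometry, frame_window=(86, 96))
        rs = []
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            obs = ObserverModel(kernel=kernel, p_max=0.75)
            centers = rng.uniform(0.5, 96.5, (384, 8))
            profiles = temporal_profiles(centers, 3.0, geometry)
            info = profiles @ kernel / kernel.sum()
            correct = rng.random(384) < np.asarray(obs.p_correct(info))
            arr = permutation_zscore(profiles, correct, n_permutations=300, rng=rng)
            rs.append(stats.pearsonr(arr.z, kernel).statistic)
        assert np.mean(rs) > 0.5


class TestRecentering:
    def test_contact_at_origin_is_zero_padded_identity(self, small_geometry):
        frame = build_recenter_frame([(30, 20), (30, 20)], small_geometry)
        prof = gaussian_bubble((10.0, 10.0), 4.0, small_geometry)
        out, covered = recenter_profile(prof, (30, 20), frame)
        oy = frame.origin[1] - 20
        ox = frame.origin[0] - 30
        np.testing.assert_array_equal(out[oy : oy + 40, ox : ox + 60], prof)
        assert out.sum() == pytest.approx(prof.sum())
        assert covered.sum() == prof.size

    def test_bubble_at_contact_lands_on_origin(self, small_geometry):
        frame = build_recenter_frame([(12, 25)], small_geometry)
        prof = gaussian_bubble((12.0, 25.0), 3.0, small_geometry)
        out, _ = recenter_profile(prof, (12, 25), frame)
        ox, oy = frame.origin
        assert out[oy, ox] == 1.0 and out.max() == 1.0

    def test_shifted_contacts_align(self, small_geometry):
        # same profile relative to contact, different video coordinates
        frame = build_recenter_frame([(20, 15), (28, 21)], small_geometry)
        a = gaussian_bubble((25.0, 18.0), 3.0, small_geometry)
        b = gaussian_bubble((33.0, 24.0), 3.0, small_geometry)
        ra, _ = recenter_profile(a, (20, 15), frame)
        rb, _ = recenter_profile(b, (28, 21), frame)
        # identical except where domain truncation differs near edges
        ya, xa = np.nonzero(ra > 1e-6)
        np.testing.assert_allclose(
            ra[ya.min() : ya.max() + 1, xa.min() : xa.max() + 1],
            rb[ya.min() : ya.max() + 1, xa.min() : xa.max() + 1],
            atol=1e-12,
        )

    def test_canvas_too_small(self, small_geometry):
        frame = build_recenter_frame([(30, 20)], small_geometry)
        prof = np.zeros(small_geometry.spatial_shape)
        with pytest.raises(ValueError, match="canvas"):
            recenter_profile(prof, (2, 2), frame)


class TestExcludeGuesser:
    @pytest.mark.parametrize(
        "n_correct, expect_excluded",
        [(192, True), (250, False), (211, True), (212, False)],
    )
    def test_threshold_arithmetic(self, n_correct, expect_excluded):
        excluded, p = exclude_guesser(n_correct, 384)
        assert excluded is expect_excluded
        assert 0 <= p <= 1

    def test_exact_chance_binomial_tail(self):
        _, p = exclude_guesser(192, 384)
        assert p == pytest.approx(stats.binom.sf(191, 384, 0.5))
        assert 0.5 < p < 0.55

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            exclude_guesser(400, 384)


class TestClassifyFromLog:
    def test_profiles_regenerate_bit_exactly_after_round_trip(
        self, geometry, tmp_path
    ):
        obs = ObserverModel(
            kernel=window_kernel(geometry, frame_window=(86, 96)),
            participant_id="p1",
        )
        log = simulate_experiment([obs], n_trials=24, master_seed=31)
        direct = profiles_from_log(log, geometry)
        path = tmp_path / "log.csv"
        write_trial_log(log, path)
        reread = read_trial_log(path)
        np.testing.assert_array_equal(profiles_from_log(reread, geometry), direct)

    def test_spatial_pipeline_recenters(self, tmp_path):
        geometry = StimulusGeometry(width=40, height=30)
        obs = ObserverModel(kernel=np.zeros((30, 40)), p_max=0.6, participant_id="s1")
        log = simulate_experiment(
            [obs], n_trials=10, n_bubbles=4, sigma=5.0, session_type="spatial",
            geometry=geometry, master_seed=32, contact_jitter=3.0,
        )
        arr = classify_participant(log, geometry, n_permutations=100, seed=5)
        assert arr.z.ndim == 2
        assert arr.z.shape[0] >= 30 and arr.z.shape[1] >= 40
        assert np.isfinite(arr.z).all()
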