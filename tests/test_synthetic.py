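"""Design generation, RDM embedding, and synthetic EEG/ROI ground truth."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import strsa
from strsa import (
    DesignSpec,
    GroundTruth,
    LatentFeature,
    embed_rdm,
    generate_design,
    generate_eeg_trials,
    generate_roi_rdm_set,
    vectorize_rdm,
)
from strsa.synthetic import ar1_timecourses

from conftest import random_rdm


class TestGenerateDesign:
    def test_study_design_totals(self):
        """75 videos, 15 blocks, 4 catch events -> 83/block, 1245 total."""
        d = generate_design(DesignSpec(seed=0))
        assert len(d) == 1245
        for b in range(15):
            assert (d.block == b).sum() == 83

    def test_no_catch_single_block_is_permutation(self):
        d = generate_design(DesignSpec(10, 5, 1, 0, seed=1))
        assert len(d) == 10
        assert sorted(d.condition) == list(range(10))
        assert not d.is_catch.any()

    def test_each_block_has_every_condition_once_noncatch(self):
        d = generate_design(DesignSpec(seed=3))
        for b in range(15):
            sel = (d.block == b) & ~d.is_catch
            assert sorted(d.condition[sel]) == list(range(75))

    def test_catch_pairs_repeat_predecessor_condition(self):
        """Catch trials come in consecutive same-condition pairs that
        repeat the immediately preceding trial's condition."""
        d = generate_design(DesignSpec(seed=5))
        i = 0
        n_pairs = 0
        while i < len(d):
            if d.is_catch[i]:
                assert d.is_catch[i + 1]
                assert d.condition[i] == d.condition[i + 1]
                assert d.condition[i] == d.condition[i - 1]
                assert d.block[i] == d.block[i - 1]
                n_pairs += 1
                i += 2
            else:
                i += 1
        assert n_pairs == 15 * 4

    def test_deterministic_under_seed(self):
        a = generate_design(DesignSpec(seed=11))
        b = generate_design(DesignSpec(seed=11))
        assert np.array_equal(a.condition, b.condition)
        assert np.array_equal(a.is_catch, b.is_catch)

    def test_too_many_catch_events_invalid(self):
        with pytest.raises(ValueError):
            DesignSpec(n_videos=3, n_social=1, n_catch_events_per_block=4)


class TestEmbedRDM:
    def test_two_points_at_unit_distance(self):
        rdm = strsa.RDM(np.array([[0.0, 1.0], [1.0, 0.0]]))
        emb = embed_rdm(rdm, 1)
        d = abs(emb.points[0, 0] - emb.points[1, 0])
        assert d == pytest.approx(1.0)
        assert emb.stress == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_3d_configuration(self, rng):
        pts = rng.standard_normal((10, 3))
        rdm = strsa.euclidean_rdm(pts)
        emb = embed_rdm(rdm, 3)
        back = strsa.euclidean_rdm(emb.points)
        assert np.allclose(back.matrix, rdm.matrix, atol=1e-6)
        assert emb.stress < 1e-6

    def test_non_euclidean_rank2_matches_eigendecomposition(self, rng):
        """Best rank-2 embedding agrees with a direct eigendecomposition
        of the doubly centred matrix, and stress is nonzero."""
        rdm = random_rdm(rng, 8)  # generic: not embeddable in 2-D
        emb = embed_rdm(rdm, 2)
        d = rdm.matrix
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d**2) @ j
        evals, evecs = np.linalg.eigh(b)
        top = np.argsort(evals)[::-1][:2]
        ref = evecs[:, top] * np.sqrt(np.clip(evals[top], 0, None))
        ref_d = strsa.euclidean_rdm(ref).matrix
        got_d = strsa.euclidean_rdm(emb.points).matrix
        assert np.allclose(got_d, ref_d, atol=1e-8)
        assert emb.stress > 0.0

    def test_invalid_dim(self):
        with pytest.raises(ValueError):
            embed_rdm(strsa.RDM(np.zeros((2, 2))), 0)


class TestGenerateEEGTrials:
    def make(self, snr, onset=100.0, seed=0, n_channels=10):
        spec = DesignSpec(6, 3, 4, 0, seed=1)
        design = generate_design(spec)
        feat = LatentFeature("f", strsa.binary_category_rdm(spec.category_labels()),
                             onset_ms=onset, snr=snr)
        truth = GroundTruth([feat], seed=seed)
        return generate_eeg_trials(truth, design, n_channels, 500.0, (-100.0, 300.0))

    def test_condition_means_identical_before_onset(self):
        ep = self.make(snr=8.0, onset=100.0, seed=2)
        pre = ep.times < 95.0
        means = np.stack([
            ep.data[ep.labels == c][:, :, pre].mean(axis=0) for c in range(6)
        ])
        spread = means.std(axis=0).mean()
        post = ep.times > 150.0
        means_post = np.stack([
            ep.data[ep.labels == c][:, :, post].mean(axis=0) for c in range(6)
        ])
        spread_post = means_post.std(axis=0).mean()
        # pre-onset spread is pure sampling noise; post-onset adds signal
        assert spread_post > 3 * spread

    def test_fixed_seed_byte_identical(self):
        a = self.make(snr=1.0, seed=9)
        b = self.make(snr=1.0, seed=9)
        assert a.data.tobytes() == b.data.tobytes()

    def test_onset_outside_window_raises(self):
        with pytest.raises(ValueError, match="outside epoch window"):
            self.make(snr=1.0, onset=500.0)

    def test_channels_fewer_than_embedding_dim_raises(self):
        spec = DesignSpec(6, 3, 2, 0, seed=1)
        design = generate_design(spec)
        rdm = random_rdm(np.random.default_rng(0), 6)  # needs 5 dims
        truth = GroundTruth([LatentFeature("f", rdm, 100.0, 1.0)], seed=0)
        with pytest.raises(ValueError, match="embedding dimension"):
            generate_eeg_trials(truth, design, n_channels=2,
                                sample_rate=500.0, epoch_window_ms=(-100.0, 300.0),
                                embed_dim=5)

    def test_negative_snr_rejected(self, rng):
        with pytest.raises(ValueError):
            LatentFeature("f", random_rdm(rng, 4), 100.0, -1.0)


class TestGenerateROIRDMSet:
    def test_all_shared_no_noise_rank_correlate_one(self, rng):
        shared = random_rdm(rng, 12)
        uniques = [random_rdm(rng, 12) for _ in range(3)]
        out = generate_roi_rdm_set(shared, uniques, [(1.0, 0.0)] * 3, 0.0)
        vecs = [vectorize_rdm(r) for r in out.rdms.values()]
        for i in range(3):
            for j in range(i + 1, 3):
                rho = spearmanr(vecs[i], vecs[j]).statistic
                assert rho == pytest.approx(1.0)

    def test_output_rdms_valid(self, rng):
        shared = random_rdm(rng, 10)
        uniques = [random_rdm(rng, 10) for _ in range(2)]
        out = generate_roi_rdm_set(shared, uniques, [(1.0, 0.5), (0.3, 1.0)],
                                   noise_sd=0.2, seed=4)
        for r in out.rdms.values():
            m = r.matrix
            assert np.allclose(m, m.T)
            assert np.all(np.diag(m) == 0.0)
            assert np.all(m >= 0.0)

    def test_noise_degrades_component_correlation_monotonically(self, rng):
        shared = random_rdm(rng, 15)
        uniques = [random_rdm(rng, 15)]
        cors = []
        for noise in [0.0, 0.5, 2.0, 8.0]:
            out = generate_roi_rdm_set(shared, uniques, [(1.0, 1.0)],
                                       noise_sd=noise, seed=0)
            v = vectorize_rdm(out.rdms["roi0"])
            truth = out.shared_component + out.unique_components["roi0"]
            cors.append(np.corrcoef(v, truth)[0, 1])
        assert all(a > b for a, b in zip(cors, cors[1:]))

    def test_mismatched_sizes_raise(self, rng):
        with pytest.raises(ValueError):
            generate_roi_rdm_set(random_rdm(rng, 10), [random_rdm(rng, 8)],
                                 [(1.0, 1.0)])

    def test_negative_weights_raise(self, rng):
        with pytest.raises(ValueError):
            generate_roi_rdm_set(random_rdm(rng, 6), [random_rdm(rng, 6)],
                                 [(-1.0, 0.0)])


class TestAR1Timecourses:
    def test_shape_and_marginal_sd(self):
        x = ar1_timecourses(200, 150, ar=0.5, sd=2.0, seed=0)
        assert x.shape == (200, 150)
        assert x[:, 50:].std() == pytest.approx(2.0, rel=0.05)

    def test_lag1_autocorrelation(self):
        x = ar1_timecourses(100, 500, ar=0.6, sd=1.0, seed=1)
        r = np.corrcoef(x[:, :-1].ravel(), x[:, 1:].ravel())[0, 1]
        assert r == pytest.approx(0.6, abs=0.03)
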