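"""Pseudo-trials, noise normalization, and pairwise SVM decoding."""

import numpy as np
import pytest
from sklearn.svm import SVC

import strsa
from strsa import (
    DesignSpec,
    EpochSet,
    GroundTruth,
    LatentFeature,
    decoding_to_rdms,
    generate_design,
    generate_eeg_trials,
    make_pseudotrials,
    noise_normalize,
    pairwise_decode,
    sliding_windows,
)
from strsa.decoding import PseudoTrialSet, whitening_matrix


def make_epochs(rng, n_cond=4, trials_per_cond=14, n_channels=6, n_samples=50):
    labels = np.repeat(np.arange(n_cond), trials_per_cond)
    data = rng.standard_normal((len(labels), n_channels, n_samples))
    times = np.arange(n_samples) * 2.0
    return EpochSet(data, times, 500.0, labels)


class TestMakePseudotrials:
    def test_14_trials_group_7_single_fold_partition(self, rng):
        ep = make_epochs(rng, n_cond=1, trials_per_cond=14)
        ps = make_pseudotrials(ep, n_folds=1, group_size=7, seed=0)
        assert len(ps.labels) == 2
        # disjoint groups covering all 14: the two pseudo-trial sums
        # add up to the total over all trials
        total = ep.data.sum(axis=0)
        assert np.allclose(ps.data[0] * 7 + ps.data[1] * 7, total)

    def test_identical_source_trials_reproduced(self, rng):
        ep = make_epochs(rng, n_cond=2, trials_per_cond=8)
        for c in range(2):
            sel = np.flatnonzero(ep.labels == c)
            ep.data[sel] = ep.data[sel[0]]
        ps = make_pseudotrials(ep, n_folds=2, seed=1)
        for i, lab in enumerate(ps.labels):
            src = ep.data[np.flatnonzero(ep.labels == lab)[0]]
            assert np.allclose(ps.data[i], src)

    def test_same_seed_same_grouping(self, rng):
        ep = make_epochs(rng)
        a = make_pseudotrials(ep, seed=42)
        b = make_pseudotrials(ep, seed=42)
        assert np.allclose(a.data, b.data)
        assert np.array_equal(a.fold, b.fold)

    def test_group_size_resolves_to_7_for_15_trials_2_folds(self, rng):
        ep = make_epochs(rng, n_cond=2, trials_per_cond=15)
        ps = make_pseudotrials(ep, n_folds=2, seed=0)
        assert ps.group_size == 7

    def test_too_few_trials_raises(self, rng):
        ep = make_epochs(rng, n_cond=2, trials_per_cond=3)
        with pytest.raises(ValueError, match="fewer than 2"):
            make_pseudotrials(ep, n_folds=2, seed=0)

    def test_folds_partition_source_trials(self, rng):
        ep = make_epochs(rng, n_cond=3, trials_per_cond=12)
        ps = make_pseudotrials(ep, n_folds=2, seed=3)
        src = ps.meta["source_fold"]
        assert set(np.unique(src)) == {0, 1}
        for c in range(3):
            sel = ep.labels == c
            assert sorted(np.bincount(src[sel])) == [6, 6]


class TestNoiseNormalize:
    def make_pseudo(self, data, labels):
        n = len(labels)
        return PseudoTrialSet(
            data, np.asarray(labels), np.zeros(n, dtype=int),
            np.arange(data.shape[2]) * 2.0, 500.0, group_size=2,
        )

    def test_white_noise_transform_close_to_identity_scaling(self, rng):
        data = rng.standard_normal((400, 4, 20))
        ps = self.make_pseudo(data, np.zeros(400))
        w = whitening_matrix(ps.data, ps.labels, shrinkage=0.0)
        off = w - np.diag(np.diag(w))
        assert np.abs(off).max() < 0.08
        assert np.allclose(np.diag(w), 1.0, atol=0.08)

    def test_whitened_residual_covariance_near_identity(self, rng):
        # correlated noise
        mix = rng.standard_normal((4, 4))
        data = np.einsum("ij,njt->nit", mix, rng.standard_normal((600, 4, 25)))
        ps = self.make_pseudo(data, np.zeros(600))
        out = noise_normalize(ps, ps, shrinkage=0.0)
        flat = np.moveaxis(out.data, 1, 2).reshape(-1, 4)
        cov = np.cov(flat.T)
        assert np.linalg.norm(cov - np.eye(4)) < 0.1

    def test_full_shrinkage_diagonal_scaling_only(self, rng):
        data = rng.standard_normal((50, 3, 10))
        ps = self.make_pseudo(data, np.zeros(50))
        w = whitening_matrix(ps.data, ps.labels, shrinkage=1.0)
        assert np.allclose(w, np.diag(np.diag(w)))

    def test_singular_with_zero_shrinkage_raises(self, rng):
        # rank-deficient: one channel duplicates another
        data = rng.standard_normal((30, 3, 10))
        data[:, 2] = data[:, 1]
        ps = self.make_pseudo(data, np.zeros(30))
        with pytest.raises(np.linalg.LinAlgError):
            noise_normalize(ps, ps, shrinkage=0.0)


class TestSlidingWindows:
    def test_default_geometry_at_500hz(self):
        times = np.arange(100) * 2.0
        idx, centers = sliding_windows(times, 500.0)
        assert len(idx[0]) == 5           # 10 ms at 500 Hz
        assert idx[1][0] - idx[0][0] == 2  # 4 ms step
        assert centers[1] - centers[0] == pytest.approx(4.0)

    def test_native_resolution_mode(self):
        times = np.arange(10) * 2.0
        idx, centers = sliding_windows(times, 500.0, window_ms=None)
        assert len(idx) == 10
        assert np.array_equal(centers, times)


class TestPairwiseDecode:
    def test_chance_level_on_pure_noise(self, rng):
        ep = make_epochs(rng, n_cond=6, trials_per_cond=8, n_samples=40)
        res = pairwise_decode(ep, n_reps=3, seed=0)
        grand = np.nanmean(res.mean_accuracy())
        n_eff = 15 * 3 * 2  # pairs x reps x folds
        half_width = 1.96 * 0.5 / np.sqrt(n_eff)
        assert abs(grand - 0.5) < half_width

    def test_separable_clusters_decode_perfectly(self, rng):
        ep = make_epochs(rng, n_cond=2, trials_per_cond=10, n_samples=30)
        ep.data *= 0.01
        ep.data[ep.labels == 1] += 5.0
        res = pairwise_decode(ep, n_reps=2, seed=0)
        assert np.nanmin(res.accuracy[0, 1]) >= 0.99

    def test_relabeling_conditions_permutes_result(self, rng):
        ep = make_epochs(rng, n_cond=3, trials_per_cond=8, n_samples=20)
        ep.data[ep.labels == 2] += 1.0
        res = pairwise_decode(ep, n_reps=2, seed=5)
        swapped = EpochSet(ep.data, ep.times, ep.sample_rate,
                           np.array([{0: 1, 1: 0, 2: 2}[l] for l in ep.labels]))
        res_sw = pairwise_decode(swapped, n_reps=2, seed=5)
        # pair (0,2) in original == pair (1,2) after swapping labels 0<->1
        assert np.allclose(res.accuracy[0, 2], res_sw.accuracy[1, 2])

    def test_symmetry_of_accuracy_array(self, rng):
        ep = make_epochs(rng, n_cond=3, trials_per_cond=8, n_samples=20)
        res = pairwise_decode(ep, n_reps=1, seed=2)
        a = res.accuracy
        assert np.allclose(a[0, 1], a[1, 0])
        assert np.all(np.isnan(a[0, 0]))

    def test_fast_path_matches_svc_predictions(self, rng):
        """With one training pseudo-trial per class, the nearest-template
        rule must reproduce the linear SVM's predictions exactly."""
        for trial in range(50):
            x0, x1 = rng.standard_normal((2, 5))
            tests = rng.standard_normal((6, 5))
            clf = SVC(kernel="linear", C=1.0)
            clf.fit(np.stack([x0, x1]), [0, 1])
            svm_pred = clf.predict(tests)
            d0 = ((tests - x0) ** 2).sum(axis=1)
            d1 = ((tests - x1) ** 2).sum(axis=1)
            template_pred = (d1 < d0).astype(int)
            assert np.array_equal(svm_pred, template_pred)


class TestDecodingToRDMs:
    def test_flat_chance_rdm(self):
        acc = np.full((3, 3, 4), 0.5)
        ii = np.arange(3)
        acc[ii, ii, :] = np.nan
        res = strsa.DecodingResult(acc, np.arange(4.0), [0, 1, 2], 1, 2)
        tr = decoding_to_rdms(res)
        for w in range(4):
            m = tr.dissimilarities[w]
            assert np.all(np.diag(m) == 0.0)
            off = m[~np.eye(3, dtype=bool)]
            assert np.all(off == 0.5)

    def test_round_trip_with_vectorize(self, rng):
        ep = make_epochs(rng, n_cond=3, trials_per_cond=8, n_samples=20)
        res = pairwise_decode(ep, n_reps=1, seed=0)
        tr = decoding_to_rdms(res)
        v = tr.vectors()
        assert np.allclose(v[:, 0], res.accuracy[0, 1, :])
        back = strsa.devectorize_rdm(v[2])
        assert np.allclose(back.matrix, tr.dissimilarities[2])

    def test_out_of_range_accuracy_rejected(self):
        acc = np.full((2, 2, 1), 1.5)
        res = strsa.DecodingResult(acc, np.zeros(1), [0, 1], 1, 2)
        with pytest.raises(ValueError):
            decoding_to_rdms(res)


class TestLatencyFidelity:
    def test_above_chance_only_after_onset(self, rng):
        """Injected 150-ms onset: decodable at/after onset only."""
        spec = DesignSpec(6, 3, 10, 0, seed=1)
        design = generate_design(spec)
        model = strsa.binary_category_rdm(spec.category_labels())
        truth = GroundTruth([LatentFeature("cat", model, 150.0, 3.0)], seed=2)
        ep = generate_eeg_trials(truth, design, 10, 500.0, (-60.0, 260.0))
        res = pairwise_decode(ep, n_reps=2, seed=3)
        ma = res.mean_accuracy()
        cen = res.window_centers_ms
        pre = ma[cen < 146.0]   # one window step of slack around onset
        post = ma[(cen > 170.0) & (cen < 250.0)]
        assert abs(pre.mean() - 0.5) < 0.05
        assert post.mean() > 0.7
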