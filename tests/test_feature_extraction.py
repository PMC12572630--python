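"""Splitting, Sinkhorn assignment, swapped loss, both backends, robustness."""

import numpy as np
import pandas as pd
import pytest

from mimiclens.feature_extraction import (MorphometricExtractor,
                                          TrainerConfig, evaluate_robustness,
                                          extract_features,
                                          morphometric_features,
                                          sinkhorn_normalize, split_dataset,
                                          swav_swapped_loss, train_extractor)

from conftest import spot_count_templates


def _manifest(n, taxa=("a",)):
    rng = np.random.default_rng(1)
    return pd.DataFrame({"specimen_id": [f"s{i}" for i in range(n)],
                         "taxon_id": rng.choice(list(taxa), n)})


class TestSplitDataset:
    def test_ten_items_one_taxon_is_8_1_1(self):
        sp = split_dataset(_manifest(10), seed=0)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (8, 1, 1)

    def test_251_items_floor_rule(self):
        # floor(251/10) = 25 to val and test, remainder 201 to train
        sp = split_dataset(_manifest(251), seed=3)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (201, 25, 25)

    def test_partition_properties(self):
        man = _manifest(97, taxa="abc")
        sp = split_dataset(man, seed=5)
        all_ids = set(sp.train) | set(sp.val) | set(sp.test)
        assert all_ids == set(man["specimen_id"])
        assert not (set(sp.train) & set(sp.val))
        assert not (set(sp.train) & set(sp.test))
        assert not (set(sp.val) & set(sp.test))

    def test_stratified_and_deterministic(self):
        man = _manifest(60, taxa="abc")
        sp1 = split_dataset(man, seed=2)
        sp2 = split_dataset(man, seed=2)
        assert sp1.train == sp2.train and sp1.test == sp2.test
        lab = man.set_index("specimen_id")["taxon_id"]
        for taxon, grp in man.groupby("taxon_id"):
            n = len(grp)
            assert sum(lab[s] == taxon for s in sp1.test) == n // 10

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(_manifest(10), ratios=(0, 0, 0))


class TestSinkhorn:
    def test_single_entry(self):
        assert np.allclose(sinkhorn_normalize(np.array([[3.0]])), 1.0)

    def test_constant_scores_give_uniform_assignment(self):
        Q = sinkhorn_normalize(np.full((2, 2), 0.7))
        assert np.allclose(Q, 0.25)

    def test_marginals_match_oracle_iteration(self):
        """Independent oracle: plain alternating row/column scaling applied
        to exp(scores) from scratch."""
        rng = np.random.default_rng(4)
        S = rng.normal(size=(8, 4))
        Q = sinkhorn_normalize(S, epsilon=1.0, n_iters=100)
        M = np.exp(S)
        M /= M.sum()
        for _ in range(100):
            M /= M.sum(axis=1, keepdims=True) * 8
            M /= M.sum(axis=0, keepdims=True) * 4
        assert np.allclose(Q, M, atol=1e-10)
        assert np.max(np.abs(Q.sum(axis=1) - 1 / 8)) < 1e-6
        assert np.max(np.abs(Q.sum(axis=0) - 1 / 4)) < 1e-6
        assert np.all(Q > 0)

    def test_marginal_error_decreases_with_iterations(self):
        rng = np.random.default_rng(9)
        S = rng.normal(size=(16, 5))
        errs = []
        for iters in (1, 5, 25):
            Q = sinkhorn_normalize(S, epsilon=1.0, n_iters=iters)
            errs.append(np.max(np.abs(Q.sum(axis=1) - 1 / 16)))
        assert errs[0] >= errs[1] >= errs[2]

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            sinkhorn_normalize(np.array([[np.nan, 1.0]]))


class TestSwappedLoss:
    def test_matched_one_hot_views_near_zero(self):
        # projections exactly on distinct prototypes, tiny temperature ->
        # predictions and assignments agree
        C = np.eye(4, 8)
        z = np.eye(4, 8)
        loss = swav_swapped_loss(z, z, C, temperature=0.02,
                                 sinkhorn_epsilon=0.02, sinkhorn_iters=50)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_against_one_hot_target_is_log_k(self):
        # brute-force check on the analytic cross-entropy: -sum q log p with
        # p uniform over K gives log K regardless of q
        K = 5
        q = np.zeros(K)
        q[2] = 1.0
        p = np.full(K, 1.0 / K)
        assert -np.sum(q * np.log(p)) == pytest.approx(np.log(K))

    def test_random_batch_matches_brute_force_cross_entropy(self):
        rng = np.random.default_rng(0)
        B, D, K = 6, 16, 4
        z1 = rng.normal(size=(B, D))
        z2 = rng.normal(size=(B, D))
        C = rng.normal(size=(K, D))
        C /= np.linalg.norm(C, axis=1, keepdims=True)
        temp, eps, iters = 0.1, 0.5, 30
        loss = swav_swapped_loss(z1, z2, C, temp, eps, iters)
        # oracle: recompute -sum q log p elementwise from scratch
        def softmax(x):
            e = np.exp(x - x.max(axis=1, keepdims=True))
            return e / e.sum(axis=1, keepdims=True)
        total = 0.0
        for za, zb in ((z1, z2), (z2, z1)):
            q = sinkhorn_normalize(zb @ C.T, eps, iters) * B
            p = softmax(za @ C.T / temp)
            total += -np.sum(q * np.log(p))
        assert loss == pytest.approx(total / (2 * B), rel=1e-10)
        assert loss >= 0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            swav_swapped_loss(np.ones((2, 3)), np.ones((3, 3)), np.eye(3))


class TestMorphometricBackend:
    def test_identical_images_identical_vectors(self, five_taxon_dataset):
        imgs, _ = five_taxon_dataset
        a = morphometric_features(imgs[0]).values
        b = morphometric_features(imgs[0]).values
        assert np.array_equal(a, b)

    def test_spot_count_coordinate_differs_by_four(self):
        from mimiclens.synthetic_wings import generate_specimen
        t0, t4 = spot_count_templates()[0], spot_count_templates()[4]
        v0 = morphometric_features(generate_specimen(t0, seed=1)).values
        v4 = morphometric_features(generate_specimen(t4, seed=1)).values
        assert v4[48] - v0[48] == pytest.approx(4.0)

    def test_histogram_blocks_are_area_fractions(self, five_taxon_dataset):
        """Each channel's histogram block is the colour distribution over
        the silhouette: nonnegative, summing to one, and matching a direct
        per-pixel tally."""
        imgs, _ = five_taxon_dataset
        img = imgs[7]
        v = morphometric_features(img).values
        sil = ~np.all(img.pixels >= 245, axis=-1)
        reds = img.pixels[sil][:, 0].astype(float)
        # direct tally oracle for the R channel, interpolated binning
        t = np.clip(reds / 16.0 - 0.5, 0.0, 15.0)
        lo = np.floor(t).astype(int)
        tally = np.zeros(16)
        np.add.at(tally, lo, 1.0 - (t - lo))
        np.add.at(tally, np.minimum(lo + 1, 15), t - lo)
        assert np.allclose(v[:16], tally / len(reds))
        for c in range(3):
            block = v[c * 16:(c + 1) * 16]
            assert block.sum() == pytest.approx(1.0)
            assert np.all(block >= 0)

    def test_missing_mask_warns_and_falls_back(self, five_taxon_dataset):
        from mimiclens.synthetic_wings import SpecimenImage
        img = five_taxon_dataset[0][0]
        nomask = SpecimenImage(img.pixels, "x", "t", "dorsal", None, {})
        with pytest.warns(UserWarning, match="mask"):
            v = morphometric_features(nomask).values
        assert v.shape == (58,)


class TestExtractFeatures:
    def test_shape_and_projection_to_2048(self, five_taxon_dataset):
        imgs, _ = five_taxon_dataset
        feats = extract_features(imgs[:3], MorphometricExtractor(), D=2048)
        assert feats.shape == (3, 2048)
        assert list(feats.index) == [im.specimen_id for im in imgs[:3]]

    def test_pure_function_of_inputs(self, five_taxon_dataset):
        imgs, _ = five_taxon_dataset
        f1 = extract_features(imgs[:4], MorphometricExtractor(), D=512)
        f2 = extract_features(imgs[:4], MorphometricExtractor(), D=512)
        pd.testing.assert_frame_equal(f1, f2)

    def test_projection_roughly_preserves_cosine(self, five_taxon_dataset):
        imgs, _ = five_taxon_dataset
        raw = extract_features(imgs[:10], MorphometricExtractor())
        proj = extract_features(imgs[:10], MorphometricExtractor(), D=2048)
        def cos(M):
            X = M.to_numpy()
            X = X / np.linalg.norm(X, axis=1, keepdims=True)
            return X @ X.T
        assert np.max(np.abs(cos(raw) - cos(proj))) < 0.1


class TestSwavMiniTrainer:
    def test_plumbing_two_epochs_two_losses(self, five_taxon_dataset):
        imgs, _ = five_taxon_dataset
        cfg = TrainerConfig(epochs=2, batch_size=10, seed=0)
        ex = train_extractor(imgs[:20], cfg)
        assert len(ex.loss_trace) == 2
        assert all(np.isfinite(l) and l >= 0 for l in ex.loss_trace)

    def test_same_seed_identical_loss_trace(self, five_taxon_dataset):
        imgs, _ = five_taxon_dataset
        cfg = TrainerConfig(epochs=2, batch_size=10, seed=3)
        t1 = train_extractor(imgs[:20], cfg).loss_trace
        t2 = train_extractor(imgs[:20], cfg).loss_trace
        assert t1 == t2

    def test_batch_larger_than_dataset_rejected(self, five_taxon_dataset):
        imgs, _ = five_taxon_dataset
        with pytest.raises(ValueError, match="batch"):
            train_extractor(imgs[:4], TrainerConfig(batch_size=16))

    def test_loss_decreases_over_training(self, five_taxon_dataset):
        imgs, _ = five_taxon_dataset
        wins = 0
        for seed in range(3):
            cfg = TrainerConfig(epochs=4, batch_size=15, seed=seed)
            ex = train_extractor(imgs, cfg)
            wins += ex.loss_trace[-1] < ex.loss_trace[0]
        assert wins >= 2

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainerConfig(n_prototypes=1)
        with pytest.raises(ValueError):
            TrainerConfig(temperature=0.0)


class TestEvaluateRobustness:
    def test_one_hot_features_perfect_accuracy(self):
        from mimiclens.feature_extraction import DatasetSplit
        ids = [f"s{i}" for i in range(8)]
        lab = pd.Series(["a", "a", "b", "b", "a", "b", "a", "b"], index=ids)
        X = np.zeros((8, 2))
        X[np.arange(8), (lab == "b").astype(int)] = 1.0
        feats = pd.DataFrame(X, index=ids)
        split = DatasetSplit(train=ids[:6], val=[], test=ids[6:])
        assert evaluate_robustness(feats, lab, split) == 1.0

    def test_single_taxon_is_trivially_perfect(self):
        from mimiclens.feature_extraction import DatasetSplit
        ids = [f"s{i}" for i in range(10)]
        lab = pd.Series("a", index=ids)
        feats = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)),
                             index=ids)
        split = DatasetSplit(train=ids[:8], val=ids[8:9], test=ids[9:])
        assert evaluate_robustness(feats, lab, split) == 1.0

    def test_taxon_missing_from_train_is_an_error(self):
        from mimiclens.feature_extraction import DatasetSplit
        ids = ["s0", "s1", "s2"]
        lab = pd.Series(["a", "a", "b"], index=ids)
        feats = pd.DataFrame(np.eye(3), index=ids)
        split = DatasetSplit(train=ids[:2], val=[], test=ids[2:])
        with pytest.raises(ValueError, match="test but not train"):
            evaluate_robustness(feats, lab, split)

    def test_random_features_near_chance(self):
        """Nearest-centroid on pure-noise features over k balanced taxa hits
        ~1/k; pooled over seeds, stays inside a 99% binomial band."""
        from mimiclens.feature_extraction import DatasetSplit
        rng = np.random.default_rng(0)
        k, n = 4, 40
        hits, trials = 0, 0
        for _ in range(20):
            ids = [f"s{i}" for i in range(n)]
            lab = pd.Series(np.repeat(list("abcd"), n // k), index=ids)
            feats = pd.DataFrame(rng.normal(size=(n, 16)), index=ids)
            test = [ids[i] for i in range(0, n, 10)]
            train = [i for i in ids if i not in test]
            acc = evaluate_robustness(feats, lab,
                                      DatasetSplit(train=train, val=[],
                                                   test=test))
            hits += acc * len(test)
            trials += len(test)
        p = hits / trials
        se = np.sqrt(0.25 / k / trials) * 2.58 + 0.1
        assert abs(p - 1 / k) < se
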