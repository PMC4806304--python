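"""Feature extraction, local-classifier fusion, and post-processing."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from alfa.evaluation import dice
from alfa.fusion import (NEIGHBOUR_OFFSETS, FusionConfig, classify_voxel,
                         extract_features, fuse, gather_training,
                         largest_component_postprocess)
from alfa.phantoms import make_cohort, sample_subject
from alfa.volumes import BinaryMask, Volume


def brute_force_features(data: np.ndarray) -> np.ndarray:
    """Sliding-window [-1 0 1] oracle with replicate padding, coded plainly."""
    nx, ny, nz = data.shape
    out = np.zeros((5,) + data.shape)
    out[0] = data
    pad = np.pad(data, 1, mode="edge")
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                ip, jp, kp = i + 1, j + 1, k + 1
                dx = pad[ip + 1, jp, kp] - pad[ip - 1, jp, kp]
                dy = pad[ip, jp + 1, kp] - pad[ip, jp - 1, kp]
                dz = pad[ip, jp, kp + 1] - pad[ip, jp, kp - 1]
                out[1, i, j, k] = abs(dx)
                out[2, i, j, k] = abs(dy)
                out[3, i, j, k] = abs(dz)
                out[4, i, j, k] = np.sqrt(dx * dx + dy * dy + dz * dz)
    return out


def _feat(data: np.ndarray):
    return extract_features(Volume(data=np.asarray(data, dtype=float)))


class TestExtractFeatures:
    def test_constant_image_gives_c_and_zeros(self):
        fv = _feat(np.full((5, 5, 5), 4.2))
        np.testing.assert_allclose(fv.channels[0], 4.2)
        np.testing.assert_allclose(fv.channels[1:], 0.0)

    def test_ramp_derivative(self):
        x = np.arange(7, dtype=float)
        data = np.broadcast_to(3.0 * x[:, None, None], (7, 7, 7)).copy()
        fv = _feat(data)
        interior = fv.channels[:, 1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior[1], 6.0)
        np.testing.assert_allclose(interior[2], 0.0)
        np.testing.assert_allclose(interior[3], 0.0)
        np.testing.assert_allclose(interior[4], 6.0)

    @pytest.mark.parametrize("shape", [(5, 5, 5), (7, 6, 9)])
    def test_matches_brute_force_oracle_exactly(self, rng, shape):
        data = rng.normal(size=shape)
        fv = _feat(data)
        np.testing.assert_array_equal(fv.channels[:4],
                                      brute_force_features(data)[:4])
        np.testing.assert_allclose(fv.channels[4], brute_force_features(data)[4],
                                   rtol=1e-12)

    def test_magnitude_is_l2_of_derivatives(self, rng):
        fv = _feat(rng.normal(size=(6, 6, 6)))
        r2 = np.sum(fv.channels[1:4] ** 2, axis=0)
        np.testing.assert_allclose(fv.channels[4] ** 2, r2, rtol=1e-6)

    def test_too_small_volume_raises(self):
        with pytest.raises(ValueError):
            _feat(np.zeros((2, 5, 5)))


class TestGatherTraining:
    def _atlas(self, rng, shape=(6, 6, 6)):
        img = Volume(data=rng.normal(size=shape))
        mask = BinaryMask(data=rng.random(shape) > 0.5)
        return extract_features(img), mask

    @pytest.mark.parametrize("k,expected", [(1, 26), (3, 78), (5, 130)])
    def test_interior_sample_count_is_k_times_26(self, rng, k, expected):
        feats, masks = zip(*[self._atlas(rng) for _ in range(k)])
        ts = gather_training((3, 3, 3), list(feats), list(masks))
        assert ts.samples.shape == (expected, 5)
        assert ts.labels.shape == (expected,)

    def test_corner_voxel_truncates_to_7_per_atlas(self, rng):
        feats, masks = zip(*[self._atlas(rng) for _ in range(2)])
        ts = gather_training((0, 0, 0), list(feats), list(masks))
        assert ts.samples.shape == (14, 5)

    def test_labels_and_samples_match_direct_lookup(self, rng):
        feats, masks = zip(*[self._atlas(rng)])
        vx = np.array([2, 3, 4])
        ts = gather_training(vx, list(feats), list(masks))
        for s, (a, off) in enumerate(ts.provenance):
            p = vx + np.asarray(off)
            np.testing.assert_array_equal(
                ts.samples[s], feats[a].channels[:, p[0], p[1], p[2]])
            assert ts.labels[s] == masks[a].data[p[0], p[1], p[2]]

    def test_empty_atlas_list_raises(self):
        with pytest.raises(ValueError):
            gather_training((1, 1, 1), [], [])


class TestClassifyVoxel:
    def _toy(self, feature_dim=5):
        """1-D separable toy lifted into the feature space's first channel."""
        c0 = [0.9, 1.0, 1.1]
        c1 = [4.9, 5.0, 5.1]
        samples = np.zeros((6, feature_dim))
        samples[:3, 0] = c0
        samples[3:, 0] = c1
        labels = np.array([0, 0, 0, 1, 1, 1], dtype=np.int8)
        from alfa.fusion import LocalTrainingSet
        return LocalTrainingSet(samples=samples, labels=labels, provenance=[])

    def test_unanimous_labels_short_circuit(self):
        from alfa.fusion import LocalTrainingSet
        ts = LocalTrainingSet(samples=np.random.default_rng(0).normal(size=(78, 5)),
                              labels=np.ones(78, dtype=np.int8), provenance=[])
        assert classify_voxel(ts, np.zeros(5), FusionConfig()) == 1

    @pytest.mark.parametrize("clf", ["nb", "lda"])
    def test_decision_boundary_at_class_midpoint(self, clf):
        """Equal-variance, equal-prior Gaussian classes put the linear decision
        boundary at the midpoint of the class means (here 3.0)."""
        ts = self._toy()
        cfg = FusionConfig(classifier=clf)
        target = np.zeros(5)
        target[0] = 2.0
        assert classify_voxel(ts, target, cfg) == 0
        target[0] = 4.0
        assert classify_voxel(ts, target, cfg) == 1

    def test_nb_and_lda_agree_on_toy(self):
        ts = self._toy()
        rng = np.random.default_rng(5)
        for _ in range(20):
            target = np.zeros(5)
            target[0] = rng.uniform(0, 6)
            if abs(target[0] - 3.0) < 1e-6:
                continue
            assert classify_voxel(ts, target, FusionConfig(classifier="nb")) == \
                classify_voxel(ts, target, FusionConfig(classifier="lda"))

    def test_matches_sklearn_on_random_separable_data(self, rng):
        """Cross-check against scikit-learn's LDA and GaussianNB fitted on the
        same samples (equal class counts keep the comparison prior-free)."""
        sklearn = pytest.importorskip("sklearn")
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.naive_bayes import GaussianNB
        from alfa.fusion import LocalTrainingSet

        X = np.concatenate([rng.normal(0, 1, size=(30, 5)),
                            rng.normal(4, 1, size=(30, 5))])
        y = np.concatenate([np.zeros(30, dtype=np.int8), np.ones(30, dtype=np.int8)])
        ts = LocalTrainingSet(samples=X, labels=y, provenance=[])
        targets = rng.normal(2, 2, size=(50, 5))
        lda_ref = LinearDiscriminantAnalysis().fit(X, y).predict(targets)
        nb_ref = GaussianNB().fit(X, y).predict(targets)
        cfg_l = FusionConfig(classifier="lda", unanimity_shortcut=False)
        cfg_n = FusionConfig(classifier="nb", unanimity_shortcut=False)
        lda_mine = [classify_voxel(ts, t, cfg_l) for t in targets]
        nb_mine = [classify_voxel(ts, t, cfg_n) for t in targets]
        assert np.mean(np.asarray(lda_mine) == lda_ref) >= 0.98
        assert np.mean(np.asarray(nb_mine) == nb_ref) >= 0.98

    def test_degenerate_covariance_does_not_crash(self):
        from alfa.fusion import LocalTrainingSet
        X = np.zeros((10, 5))
        X[5:, 0] = 1.0
        y = np.array([0] * 5 + [1] * 5, dtype=np.int8)
        ts = LocalTrainingSet(samples=X, labels=y, provenance=[])
        assert classify_voxel(ts, np.full(5, 0.9),
                              FusionConfig(classifier="lda")) in (0, 1)


class TestFuse:
    def test_identical_atlases_with_true_mask_nearly_reproduce_it(self, small_cohort):
        """With k identical atlases equal to the target's truth, every voxel
        whose neighbour labels are unanimous keeps its label exactly; only
        boundary voxels with mixed neighbour labels are re-classified, so the
        overall agreement stays above 99% Dice.  The majority-vote path copies
        the mask exactly."""
        from scipy import ndimage

        subj = small_cohort[0]
        pairs = [(subj.image, subj.truth_mask)] * 3
        out = fuse(subj.image, pairs, FusionConfig(classifier="lda"))
        foot = np.ones((3, 3, 3), dtype=bool)
        foot[1, 1, 1] = False
        m = subj.truth_mask.data.astype(np.uint8)
        unanimous = (ndimage.minimum_filter(m, footprint=foot,
                                            mode="constant", cval=1) ==
                     ndimage.maximum_filter(m, footprint=foot,
                                            mode="constant", cval=0))
        np.testing.assert_array_equal(out.data[unanimous],
                                      subj.truth_mask.data[unanimous])
        assert dice(out, subj.truth_mask) > 99.0
        mv = fuse(subj.image, pairs, FusionConfig(classifier="majority_vote"))
        np.testing.assert_array_equal(mv.data, subj.truth_mask.data)

    def test_majority_vote_modal_label(self, small_template):
        full = small_template.truth_mask.with_data(
            np.ones(small_template.truth_mask.shape, dtype=bool))
        empty = small_template.truth_mask.with_data(
            np.zeros(small_template.truth_mask.shape, dtype=bool))
        img = small_template.image
        out = fuse(img, [(img, full), (img, full), (img, empty)],
                   FusionConfig(classifier="majority_vote"))
        assert out.data.all()

    def test_majority_vote_matches_per_voxel_modal_oracle(self, rng, small_template):
        img = small_template.image
        masks = [small_template.truth_mask.with_data(rng.random(img.shape) > 0.5)
                 for _ in range(3)]
        out = fuse(img, [(img, m) for m in masks],
                   FusionConfig(classifier="majority_vote"))
        stack = np.stack([m.data for m in masks])
        oracle = stack.sum(axis=0) >= 2
        np.testing.assert_array_equal(out.data, oracle)

    def test_majority_vote_even_k_tie_is_brain(self, small_template):
        img = small_template.image
        full = small_template.truth_mask.with_data(np.ones(img.shape, dtype=bool))
        empty = small_template.truth_mask.with_data(np.zeros(img.shape, dtype=bool))
        out = fuse(img, [(img, full), (img, empty)],
                   FusionConfig(classifier="majority_vote"))
        assert out.data.all()

    def test_atlas_order_invariance(self, small_spec, small_cohort):
        tgt = sample_subject(small_spec, 999)
        pairs = [(s.image, s.truth_mask) for s in small_cohort[:3]]
        m1 = fuse(tgt.image, pairs, FusionConfig(classifier="lda"))
        m2 = fuse(tgt.image, pairs[::-1], FusionConfig(classifier="lda"))
        np.testing.assert_array_equal(m1.data, m2.data)

    @pytest.mark.parametrize("clf", ["lda", "nb"])
    def test_unanimity_shortcut_never_changes_output(self, small_spec,
                                                     small_cohort, clf):
        tgt = sample_subject(small_spec, 999)
        pairs = [(s.image, s.truth_mask) for s in small_cohort[:3]]
        fast = fuse(tgt.image, pairs, FusionConfig(classifier=clf))
        slow = fuse(tgt.image, pairs,
                    FusionConfig(classifier=clf, unanimity_shortcut=False))
        np.testing.assert_array_equal(fast.data, slow.data)

    def test_grid_mismatch_raises(self, small_cohort, rng):
        tgt = Volume(data=rng.normal(size=(8, 8, 8)))
        pairs = [(s.image, s.truth_mask) for s in small_cohort[:1]]
        with pytest.raises(ValueError):
            fuse(tgt, pairs, FusionConfig())

    def test_monotone_degradation_with_extra_warps(self, small_spec):
        """Mean Dice is non-increasing as extra random warps (registration
        error surrogates) are injected into the atlases; one inversion
        tolerated across the three error levels."""
        from alfa.phantoms import _random_displacement, _warp, make_template

        tpl = make_template(small_spec)
        tgt = sample_subject(small_spec, 321)
        means = []
        for level, amp in enumerate((0.0, 1.5, 3.5)):
            ds = []
            for rep in range(5):
                spec_err = replace(small_spec, deform_amplitude=amp)
                gen = np.random.default_rng(7000 + 10 * level + rep)
                pairs = []
                for a in range(3):
                    base = sample_subject(small_spec, 500 + a)
                    err = _random_displacement(spec_err, gen)
                    img_d, msk_d = _warp(small_spec,
                                         type(tpl)(image=base.image,
                                                   truth_mask=base.truth_mask,
                                                   displacement=err), err)
                    pairs.append((base.image.with_data(img_d),
                                  base.truth_mask.with_data(msk_d)))
                out = fuse(tgt.image, pairs, FusionConfig(classifier="lda"))
                ds.append(dice(out, tgt.truth_mask))
            means.append(np.mean(ds))
        inversions = sum(1 for a, b in zip(means, means[1:]) if b > a + 1e-9)
        assert inversions <= 1


class TestPostprocess:
    def _blob(self):
        data = np.zeros((12, 12, 12), dtype=bool)
        data[3:9, 3:9, 3:9] = True
        return data

    def test_single_blob_unchanged(self):
        mask = BinaryMask(data=self._blob())
        out = largest_component_postprocess(mask)
        np.testing.assert_array_equal(out.data, mask.data)

    def test_satellite_removed(self):
        data = self._blob()
        data[0, 0, 0] = True
        out = largest_component_postprocess(BinaryMask(data=data))
        assert not out.data[0, 0, 0]
        assert out.data.sum() == self._blob().sum()

    def test_interior_cavity_filled(self):
        data = self._blob()
        data[5, 5, 5] = False
        out = largest_component_postprocess(BinaryMask(data=data))
        assert out.data[5, 5, 5]

    def test_empty_mask_warns_and_returns_unchanged(self):
        mask = BinaryMask(data=np.zeros((5, 5, 5), dtype=bool))
        with pytest.warns(UserWarning):
            out = largest_component_postprocess(mask)
        assert not out.data.any()
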