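"""Softmax fusion, vote confidence, rejection, class-map rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from slidecarto import fusion
from slidecarto.superpixels import SuperpixelMap


class _ConstantClassifier:
    def __init__(self, vectors):
        self._vectors = np.asarray(vectors, dtype=float)
        self.class_names = tuple(f"c{i}" for i in range(self._vectors.shape[-1]))

    def predict_proba(self, patches):
        return np.tile(self._vectors, (len(patches), 1))


def _random_prob_sets(seed, n_sets=50, n=12, k=7):
    rng = np.random.default_rng(seed)
    raw = rng.uniform(size=(n_sets, n, k))
    return raw / raw.sum(axis=2, keepdims=True)


class TestClassifyPatches:
    def test_valid_protocol(self):
        clf = _ConstantClassifier([0.7, 0.2, 0.1])
        out = fusion.classify_patches(clf, np.zeros((4, 8, 8, 3)), 3)
        assert out.shape == (4, 3)

    def test_empty_batch(self):
        clf = _ConstantClassifier([0.5, 0.5])
        assert fusion.classify_patches(clf, np.zeros((0, 8, 8, 3)), 2).shape == (0, 2)

    def test_unnormalized_output_rejected(self):
        clf = _ConstantClassifier([0.5, 0.6])
        with pytest.raises(fusion.ProtocolError):
            fusion.classify_patches(clf, np.zeros((2, 8, 8, 3)), 2)

    def test_wrong_class_count_rejected(self):
        clf = _ConstantClassifier([0.5, 0.5])
        with pytest.raises(fusion.ProtocolError):
            fusion.classify_patches(clf, np.zeros((2, 8, 8, 3)), 3)


class TestFuse:
    def test_single_patch_passthrough(self):
        label, mean = fusion.fuse(np.array([[0.7, 0.2, 0.1]]))
        assert label == 0
        assert np.allclose(mean, [0.7, 0.2, 0.1])

    def test_two_patch_mean(self):
        label, mean = fusion.fuse(np.array([[0.6, 0.4], [0.2, 0.8]]))
        assert label == 1
        assert np.allclose(mean, [0.4, 0.6])

    def test_matches_summation_oracle_and_permutation(self):
        for probs in _random_prob_sets(seed=0):
            label, mean = fusion.fuse(probs)
            oracle = np.zeros(probs.shape[1])
            for p in probs:               # independent summation oracle
                oracle = oracle + p
            oracle /= len(probs)
            assert np.allclose(mean, oracle, atol=1e-12)
            assert label == int(np.argmax(oracle))
            perm = np.random.default_rng(1).permutation(len(probs))
            label_p, mean_p = fusion.fuse(probs[perm])
            assert label_p == label and np.allclose(mean_p, mean)

    def test_duplication_invariance(self):
        probs = _random_prob_sets(seed=2, n_sets=1)[0]
        label, mean = fusion.fuse(probs)
        label_d, mean_d = fusion.fuse(np.vstack([probs, probs]))
        assert label_d == label
        assert np.allclose(mean_d, mean)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fusion.fuse(np.zeros((0, 3)))


def _probs_from_votes(votes, k=None):
    """One near-one-hot vector per vote over k classes."""
    if k is None:
        k = max(votes) + 2
    out = np.full((len(votes), k), 0.01 / (k - 1))
    for row, v in enumerate(votes):
        out[row, v] = 0.99
    return out


class TestVoteConfidence:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            ([0] * 7 + [1] * 2 + [2], 0.5),       # 7/2/1 of N=10
            ([3] * 10, 1.0),                      # unanimous
            ([0] * 5 + [1] * 5, 0.0),             # 5/5 tie
            ([0], 1.0),                           # single patch, v2 = 0
        ],
    )
    def test_enumerated_patterns(self, votes, expected):
        assert fusion.vote_confidence(_probs_from_votes(votes)) == pytest.approx(expected)

    @given(arrays(np.float64, (10, 5), elements=st.floats(0.01, 1.0)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounds_and_extremes(self, raw):
        probs = raw / raw.sum(axis=1, keepdims=True)
        c = fusion.vote_confidence(probs)
        assert 0.0 <= c <= 1.0
        votes = np.bincount(probs.argmax(axis=1), minlength=5)
        top = np.sort(votes)[::-1]
        assert (c == 1.0) == (top[0] == len(probs))
        assert (c == 0.0) == (top[0] == top[1])


def _labeling(confidences, k=3):
    spmap = SuperpixelMap(labels=np.arange(1, len(confidences) + 1, dtype=np.int32)[:, None] * np.ones((1, 4), dtype=np.int32))
    probs = {}
    for idx, c in enumerate(confidences, start=1):
        # N = 20 votes: majority count 10 + 10c gives Cdiffvotes exactly c
        n_major = int(round(10 * (1 + c)))
        votes = [0] * n_major + [1] * (20 - n_major)
        probs[idx] = _probs_from_votes(votes, k=k)
    return spmap, fusion.build_labeling(spmap, probs, [f"c{i}" for i in range(k)])


class TestRejection:
    def test_below_threshold_rejected_at_exact_kept(self):
        _, labeling = _labeling([0.0, 0.1, 0.2])
        out = fusion.apply_rejection(labeling, 0.1)
        statuses = [out[i].status for i in (1, 2, 3)]
        assert statuses == [fusion.Status.REJECTED, fusion.Status.LABELED, fusion.Status.LABELED]

    def test_threshold_zero_rejects_nothing(self):
        _, labeling = _labeling([0.0, 0.4])
        out = fusion.apply_rejection(labeling, 0.0)
        assert out.ids_with_status(fusion.Status.REJECTED) == []

    def test_invalid_threshold(self):
        _, labeling = _labeling([0.5])
        with pytest.raises(ValueError):
            fusion.apply_rejection(labeling, 1.5)

    def test_rejected_set_monotone_in_threshold(self):
        _, labeling = _labeling([0.0, 0.2, 0.4, 0.6, 0.8])
        previous = set()
        for thr in (0.0, 0.1, 0.3, 0.5, 0.7, 1.0):
            rejected = set(fusion.apply_rejection(labeling, thr).ids_with_status(fusion.Status.REJECTED))
            assert rejected >= previous
            previous = rejected


class TestRenderClassMap:
    def test_constant_label(self):
        spmap, labeling = _labeling([1.0, 1.0])
        cmap = fusion.render_class_map(spmap, labeling, mpp=3.54)
        assert np.all(cmap.raster == 1)   # class index 0 -> code 1

    def test_rejected_pixels_carry_sentinel(self):
        spmap, labeling = _labeling([0.0, 1.0])
        out = fusion.apply_rejection(labeling, 0.1)
        cmap = fusion.render_class_map(spmap, out, mpp=3.54)
        assert np.all(cmap.raster[spmap.labels == 1] == fusion.REJECTED)
        assert np.all(cmap.raster[spmap.labels == 2] == 1)

    def test_pixel_count_conservation(self):
        spmap, labeling = _labeling([0.3, 0.6, 0.9])
        cmap = fusion.render_class_map(spmap, labeling, mpp=3.54)
        for sp_id, size in spmap.sizes.items():
            assert np.count_nonzero(spmap.labels == sp_id) == size
        assert cmap.raster.size == sum(spmap.sizes.values())

    def test_missing_id_rejected(self):
        spmap, labeling = _labeling([0.5, 0.5])
        del labeling.records[2]
        with pytest.raises(KeyError):
            fusion.render_class_map(spmap, labeling, mpp=3.54)

    def test_background_and_unclassified_sentinels(self):
        labels = np.array([[1, 1, 2, 2], [1, 1, 2, 2]], dtype=np.int32)
        spmap = SuperpixelMap(labels=labels, background_ids={1})
        labeling = fusion.build_labeling(spmap, {}, ["a", "b"])
        cmap = fusion.render_class_map(spmap, labeling, mpp=3.54)
        assert np.all(cmap.raster[labels == 1] == fusion.BACKGROUND)
        assert np.all(cmap.raster[labels == 2] == fusion.UNCLASSIFIED)
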