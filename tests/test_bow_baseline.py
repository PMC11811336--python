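"""Bag/word geometry, features, codebook, labeling, and the full baseline."""

import numpy as np
import pytest

from gazemap.bow_baseline import (
    DESK_SCALE_BAGS,
    BagConfig,
    assign_words,
    bag_histogram,
    featurize_slide,
    fit_codebook,
    fit_predict_bow,
    label_bags,
    paint_bag_heatmap,
)
from gazemap.roi_extraction import Behavior, ViewingROI
from gazemap.slide_tiling import SlideImage


def _slide(rng, h, w, case_id="c"):
    return SlideImage(rng.integers(0, 255, (h, w, 3)).astype(np.uint8), case_id)


def _roi(rect):
    return ViewingROI(rect=rect, behavior=Behavior.fixation, duration=1.0,
                      source_index=0, case_id="c")


class TestGeometry:
    def test_single_window_slide(self, rng):
        cfg = DESK_SCALE_BAGS
        bags, feats = featurize_slide(_slide(rng, cfg.bag_size, cfg.bag_size), cfg)
        assert len(bags) == 1
        assert len(bags[0].word_indices) == 64  # 8 x 8 words per bag
        assert cfg.words_per_side == 8

    def test_default_geometry_is_1024_512_128(self):
        cfg = BagConfig()
        assert (cfg.bag_size, cfg.stride, cfg.word_size) == (1024, 512, 128)
        assert cfg.words_per_side == 8

    def test_double_size_slide_gives_3x3_bags(self, rng):
        cfg = DESK_SCALE_BAGS
        slide = _slide(rng, 2 * cfg.bag_size, 2 * cfg.bag_size)
        bags, _ = featurize_slide(slide, cfg)
        assert len(bags) == 9

    def test_bag_rects_match_bruteforce_window_enumeration(self, rng):
        cfg = DESK_SCALE_BAGS
        for h, w in [(cfg.bag_size, cfg.bag_size + cfg.stride),
                     (cfg.bag_size + 3 * cfg.stride, cfg.bag_size + cfg.stride),
                     (300, 420)]:
            slide = _slide(rng, h, w)
            bags, _ = featurize_slide(slide, cfg)
            hh, ww = max(h, cfg.bag_size), max(w, cfg.bag_size)
            expect = [
                (x, y, cfg.bag_size, cfg.bag_size)
                for y in range(0, hh - cfg.bag_size + 1, cfg.stride)
                for x in range(0, ww - cfg.bag_size + 1, cfg.stride)
            ]
            assert [b.rect for b in bags] == expect

    def test_small_slide_padded_with_white(self, rng):
        cfg = DESK_SCALE_BAGS
        bags, feats = featurize_slide(_slide(rng, 100, 90), cfg)
        assert len(bags) == 1

    def test_constant_slide_gives_identical_word_vectors(self):
        cfg = DESK_SCALE_BAGS
        slide = SlideImage(np.full((128, 128, 3), 180, dtype=np.uint8), "c")
        _, feats = featurize_slide(slide, cfg)
        assert np.allclose(feats, feats[0])


class TestCodebook:
    def test_k1_center_is_feature_mean(self, rng):
        feats = rng.random((50, 10))
        cb = fit_codebook(feats, k=1, seed=0)
        np.testing.assert_allclose(cb.centers[0], feats.mean(axis=0), atol=1e-9)

    def test_separated_blobs_map_to_distinct_centers(self, rng):
        blobs = np.concatenate([
            rng.normal(0, 0.05, (30, 4)),
            rng.normal(5, 0.05, (30, 4)),
            rng.normal(-5, 0.05, (30, 4)),
        ])
        cb = fit_codebook(blobs, k=3, seed=0)
        labels = assign_words(blobs, cb)
        assert len({tuple(np.unique(labels[i * 30:(i + 1) * 30])) for i in range(3)}) == 3
        for i in range(3):
            assert len(np.unique(labels[i * 30:(i + 1) * 30])) == 1

    def test_seeded_fit_is_deterministic(self, rng):
        feats = rng.random((100, 6))
        a = fit_codebook(feats, k=5, seed=3)
        b = fit_codebook(feats, k=5, seed=3)
        np.testing.assert_array_equal(a.centers, b.centers)

    def test_too_few_vectors_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_codebook(rng.random((10, 4)), k=40)


class TestHistogram:
    def test_probability_vector_of_codebook_length(self, rng):
        cfg = DESK_SCALE_BAGS
        bags, feats = featurize_slide(_slide(rng, 128, 128), cfg)
        cb = fit_codebook(rng.random((80, feats.shape[1])), k=40, seed=0)
        hist = bag_histogram(bags[0], cb, word_features=feats)
        assert hist.shape == (40,)
        assert hist.sum() == pytest.approx(1.0)
        assert (hist >= 0).all()

    def test_matches_bruteforce_nearest_center_count(self, rng):
        cfg = DESK_SCALE_BAGS
        bags, feats = featurize_slide(_slide(rng, 128, 128), cfg)
        cb = fit_codebook(rng.random((50, feats.shape[1])), k=7, seed=1)
        hist = bag_histogram(bags[0], cb, word_features=feats)
        counts = np.zeros(7)
        for idx in bags[0].word_indices:
            d = ((feats[idx] - cb.centers) ** 2).sum(axis=1)
            counts[int(d.argmin())] += 1
        np.testing.assert_allclose(hist, counts / 64)


class TestLabelBags:
    def test_full_overlap_is_positive(self, rng):
        cfg = DESK_SCALE_BAGS
        bags, _ = featurize_slide(_slide(rng, 128, 128), cfg)
        out = label_bags(bags, [_roi((0, 0, 128, 128))], (128, 128))
        assert out[0].label == 1

    def test_no_overlap_is_negative(self, rng):
        cfg = DESK_SCALE_BAGS
        bags, _ = featurize_slide(_slide(rng, 256, 256), cfg)
        out = label_bags(bags, [], (256, 256))
        assert all(b.label == 0 for b in out)

    def test_matches_rasterized_coverage_oracle(self, rng):
        cfg = DESK_SCALE_BAGS
        slide = _slide(rng, 256, 320)
        bags, _ = featurize_slide(slide, cfg)
        rois = [
            _roi((int(rng.integers(0, 250)), int(rng.integers(0, 200)),
                  int(rng.integers(20, 150)), int(rng.integers(20, 150))))
            for _ in range(5)
        ]
        out = label_bags(bags, rois, slide.frame, min_overlap_frac=0.3)
        covered = np.zeros((256, 320), dtype=bool)
        for r in rois:
            x, y, w, h = r.rect
            covered[y:y + h, x:x + w] = True
        for bag in out:
            x, y, w, h = bag.rect
            frac = covered[y:y + h, x:x + w].sum() / (w * h)
            assert bag.label == int(frac >= 0.3)


class TestFitPredict:
    def test_learnable_rule_reaches_high_accuracy(self, rng):
        # class == (first histogram bin dominates): train an RF on synthetic
        # histograms directly to validate the classifier wiring
        from sklearn.ensemble import RandomForestClassifier

        X = rng.dirichlet(np.ones(40), size=400)
        y = (X[:, 0] > np.median(X[:, 0])).astype(int)
        clf = RandomForestClassifier(n_estimators=100, random_state=0)
        clf.fit(X[:300], y[:300])
        assert clf.score(X[300:], y[300:]) >= 0.95

    def test_end_to_end_determinism_and_heatmap_range(self, rng):
        cfg = DESK_SCALE_BAGS
        train = []
        for i in range(3):
            slide = _slide(rng, 256, 256, f"t{i}")
            train.append((slide, [_roi((0, 0, 128, 128))]))
        test = [_slide(rng, 256, 256, "test0")]
        _, hms_a = fit_predict_bow(train, test, config=cfg, k=10, seed=0)
        _, hms_b = fit_predict_bow(train, test, config=cfg, k=10, seed=0)
        np.testing.assert_array_equal(hms_a[0].values, hms_b[0].values)
        assert 0 <= hms_a[0].values.min() and hms_a[0].values.max() <= 1

    def test_single_class_training_rejected(self, rng):
        cfg = DESK_SCALE_BAGS
        train = [(_slide(rng, 128, 128, "t"), [])]  # every bag negative
        with pytest.raises(ValueError, match="single class"):
            fit_predict_bow(train, [_slide(rng, 128, 128)], config=cfg, k=5, seed=0)


def test_paint_constant_scores_give_constant_heatmap(rng):
    cfg = DESK_SCALE_BAGS
    slide = _slide(rng, 192, 192)
    bags, _ = featurize_slide(slide, cfg)
    hm = paint_bag_heatmap(bags, [0.7] * len(bags), slide.frame)
    np.testing.assert_allclose(hm.values, 0.7)
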