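import numpy as np
import pytest

from tomatodetect import (
    BLOB_FEATURE_NAMES,
    blob_features,
    classify_blobs,
    extract_blobs,
    glcm_asm,
    grayscale,
    hist_contrast,
    train_blob_classifier,
)
from tomatodetect.blob_analysis import Blob
from tomatodetect.pixel_segmentation import CLASS_CODES

FRUIT = CLASS_CODES["fruit"]


def flood_fill_components(binary):
    """Brute-force 8-connected component oracle."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    comps = []
    for i in range(binary.shape[0]):
        for j in range(binary.shape[1]):
            if binary[i, j] and not seen[i, j]:
                stack, comp = [(i, j)], []
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if (0 <= yy < binary.shape[0] and 0 <= xx < binary.shape[1]
                                    and binary[yy, xx] and not seen[yy, xx]):
                                seen[yy, xx] = True
                                stack.append((yy, xx))
                comps.append(frozenset(comp))
    return set(comps)


def glcm_asm_oracle(gray):
    """Double-loop symmetric (0,1)-offset GLCM, normalized, sum of squares."""
    counts = {}
    h, w = gray.shape
    for i in range(h):
        for j in range(w - 1):
            a, b = int(gray[i, j]), int(gray[i, j + 1])
            counts[(a, b)] = counts.get((a, b), 0) + 1
            counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    return sum((c / total) ** 2 for c in counts.values())


class TestExtractBlobs:
    def test_no_fruit_pixels_gives_empty_list(self, rng):
        cm = np.zeros((8, 8), dtype=np.uint8)
        img = rng.integers(0, 256, (8, 8, 3), dtype=np.uint8)
        assert extract_blobs(cm, img) == []

    def test_diagonal_pixels_form_one_blob(self, rng):
        cm = np.zeros((6, 6), dtype=np.uint8)
        cm[2, 2] = FRUIT
        cm[3, 3] = FRUIT
        img = rng.integers(0, 256, (6, 6, 3), dtype=np.uint8)
        blobs = extract_blobs(cm, img)
        assert len(blobs) == 1
        assert blobs[0].bbox == (2, 2, 2, 2)

    def test_disk_plus_isolated_pixel(self, rng):
        from skimage.draw import disk

        cm = np.zeros((40, 40), dtype=np.uint8)
        rr, cc = disk((15, 15), 5)
        cm[rr, cc] = FRUIT
        cm[35, 35] = FRUIT
        img = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        blobs = extract_blobs(cm, img)
        assert len(blobs) == 2
        assert blobs[0].bbox == (11, 11, 9, 9)   # disk touches all bbox edges
        assert blobs[1].bbox == (35, 35, 1, 1)

    def test_masks_partition_fruit_set_vs_flood_fill_oracle(self, rng):
        cm = (rng.uniform(size=(20, 20)) < 0.3).astype(np.uint8) * FRUIT
        img = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        blobs = extract_blobs(cm, img)
        got = set()
        for b in blobs:
            r0, c0, _, _ = b.bbox
            rows, cols = np.nonzero(b.mask)
            got.add(frozenset((r0 + r, c0 + c) for r, c in zip(rows, cols)))
        assert got == flood_fill_components(cm == FRUIT)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            extract_blobs(np.zeros((5, 5), dtype=np.uint8),
                          rng.integers(0, 256, (6, 6, 3), dtype=np.uint8))


class TestGrayscale:
    @pytest.mark.parametrize(
        "color, expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((255, 0, 0), 76)],
    )
    def test_luma_values(self, color, expected):
        patch = np.full((2, 2, 3), color, dtype=np.uint8)
        assert np.all(grayscale(patch) == expected)


class TestGlcmAsm:
    def test_constant_patch_gives_one(self):
        assert glcm_asm(np.full((4, 4), 7, dtype=np.uint8)) == 1.0

    def test_checkerboard_hand_enumeration(self):
        # 2×2 board {0,1}: two symmetric pairs, p(0,1)=p(1,0)=0.5 -> ASM 0.5
        board = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        assert glcm_asm(board) == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_patches(self, rng):
        for _ in range(20):
            patch = rng.integers(0, 256, (8, 8), dtype=np.uint8)
            assert glcm_asm(patch) == pytest.approx(glcm_asm_oracle(patch), abs=1e-12)

    def test_single_column_patch_rejected(self):
        with pytest.raises(ValueError):
            glcm_asm(np.zeros((3, 1), dtype=np.uint8))


class TestHistContrast:
    def test_constant_patch_zero(self):
        assert hist_contrast(np.full((3, 3), 9)) == 0.0

    def test_two_level_closed_form(self):
        gray = np.array([[0, 255], [255, 0]])
        assert hist_contrast(gray) == pytest.approx(127.5**2)

    def test_matches_moment_oracle(self, rng):
        patch = rng.integers(0, 256, (9, 9))
        mean = patch.mean()
        assert hist_contrast(patch) == pytest.approx(((patch - mean) ** 2).mean())

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            hist_contrast(np.zeros((3, 3)), np.zeros((3, 3), dtype=bool))


class TestBlobFeatures:
    def test_size_and_aspect(self, rng):
        mask = np.ones((5, 10), dtype=bool)
        patch = rng.integers(0, 256, (5, 10, 3), dtype=np.uint8)
        v = blob_features(Blob(bbox=(0, 0, 5, 10), mask=mask, patch=patch))
        names = list(BLOB_FEATURE_NAMES)
        assert len(v) == 19
        assert v[names.index("size")] == 50
        assert v[names.index("aspect")] == 2.0

    def test_single_pixel_blob_degenerate_texture(self):
        blob = Blob(bbox=(3, 4, 1, 1), mask=np.ones((1, 1), dtype=bool),
                    patch=np.full((1, 1, 3), 99, dtype=np.uint8))
        v = blob_features(blob)
        names = list(BLOB_FEATURE_NAMES)
        assert v[names.index("size")] == 1
        assert v[names.index("aspect")] == 1.0
        assert v[names.index("glcm_asm")] == 1.0
        assert v[names.index("hist_contrast")] == 0.0

    def test_uniform_color_blob_means_equal_pixel_features(self):
        from tomatodetect import pixel_features

        color = (190, 40, 35)
        patch = np.full((6, 6, 3), color, dtype=np.uint8)
        blob = Blob(bbox=(0, 0, 6, 6), mask=np.ones((6, 6), dtype=bool), patch=patch)
        v = blob_features(blob)
        assert np.allclose(v[:15], pixel_features(color), atol=1e-9)


def make_size_only_training(rng, n=60):
    """Three blob classes that differ only in size."""
    feats, labels = [], []
    for label, sizes in [("non_fruit", (1, 4)), ("single_fruit", (100, 400)),
                         ("multi_fruit", (900, 2500))]:
        for _ in range(n):
            v = rng.normal(0.5, 0.05, 19)
            v[17] = rng.uniform(*sizes)   # size slot
            feats.append(v)
            labels.append(label)
    return np.array(feats), labels


class TestBlobClassifier:
    def test_size_dominates_importance_when_only_size_differs(self, rng):
        X, y = make_size_only_training(rng)
        clf = train_blob_classifier(X, y, {"n_estimators": 200}, seed=0)
        assert clf.importance_ranking()[0] == "size"
        assert all(v >= 0 for v in clf.importances.values())

    def test_separable_classes_near_zero_oob_error(self, rng):
        X, y = make_size_only_training(rng)
        clf = train_blob_classifier(X, y, {"n_estimators": 200}, seed=0)
        assert clf.forest.oob_score_ >= 0.97

    def test_label_permutation_drops_to_chance(self, rng):
        X, y = make_size_only_training(rng)
        y_perm = list(rng.permutation(y))
        clf = train_blob_classifier(X, y_perm, {"n_estimators": 200}, seed=0)
        assert clf.forest.oob_score_ < 0.5   # three balanced classes

    def test_missing_class_rejected(self, rng):
        X, y = make_size_only_training(rng)
        keep = [i for i, l in enumerate(y) if l != "multi_fruit"]
        with pytest.raises(ValueError):
            train_blob_classifier(X[keep], [y[i] for i in keep])

    def test_importance_ranking_stable_at_fixed_seed(self, rng):
        X, y = make_size_only_training(rng)
        a = train_blob_classifier(X, y, {"n_estimators": 100}, seed=3)
        b = train_blob_classifier(X, y, {"n_estimators": 100}, seed=3)
        assert a.importance_ranking() == b.importance_ranking()


class TestClassifyBlobs:
    def test_speckles_rejected_fruits_kept(self, pixel_model, blob_model, scene_config):
        from tomatodetect.pixel_segmentation import segment_pixels
        from tomatodetect.synthetic import generate_scene

        image, truth = generate_scene(scene_config, 55)
        cm = segment_pixels(pixel_model, image)
        blobs = classify_blobs(blob_model, extract_blobs(cm, image))
        assert all(b.blob_class is not None for b in blobs)
        speckles = [b for b in blobs if b.size <= 4]
        assert speckles
        frac_rejected = np.mean([b.blob_class == "non_fruit" for b in speckles])
        assert frac_rejected >= 0.9

    def test_candidate_count_collapses_after_filtering(
        self, pixel_model, blob_model, scene_config
    ):
        from tomatodetect.pixel_segmentation import segment_pixels
        from tomatodetect.synthetic import generate_scene

        image, truth = generate_scene(scene_config, 56)
        cm = segment_pixels(pixel_model, image)
        blobs = classify_blobs(blob_model, extract_blobs(cm, image))
        surviving = [b for b in blobs if b.blob_class != "non_fruit"]
        assert len(blobs) > 20 * len(surviving) or len(surviving) <= len(truth.fruits) + 3
        # filtering is a pure subset operation
        assert {b.blob_id for b in surviving} <= {b.blob_id for b in blobs}

    def test_unfitted_model_raises(self, rng):
        from sklearn.ensemble import RandomForestClassifier

        from tomatodetect.blob_analysis import BlobClassifier

        clf = BlobClassifier(forest=RandomForestClassifier(), hyperparams={}, seed=0)
        blob = Blob(bbox=(0, 0, 1, 1), mask=np.ones((1, 1), dtype=bool),
                    patch=np.zeros((1, 1, 3), dtype=np.uint8))
        with pytest.raises(RuntimeError):
            classify_blobs(clf, [blob])
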