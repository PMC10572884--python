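"""NM-mask construction: Otsu thresholding, negative mining, label encoding."""

import types

import numpy as np
import pytest

from scintiseg.labeling import (
    BG,
    M,
    NM,
    DegenerateHistogramError,
    LabelConsistencyError,
    LabelMap,
    encode_three_class,
    make_nm_mask_otsu,
    mine_negative_masks,
    mine_positive_masks,
    otsu_threshold,
)
from scintiseg.phantom import PhantomConfig, generate_phantom

from conftest import tiny_phantom_config


def brute_force_otsu(image):
    """Exhaustive search over all 256 candidate thresholds for the split
    maximizing between-class variance (smallest maximizer)."""
    img = np.clip(np.asarray(image), 0, 255).astype(np.int64).ravel()
    best_t, best_var = None, -1.0
    for t in range(255):
        lo = img[img <= t]
        hi = img[img > t]
        if lo.size == 0 or hi.size == 0:
            var = -1.0
        else:
            w0 = lo.size / img.size
            w1 = hi.size / img.size
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


class StubModel:
    """Predictor with a fixed probability output, for injecting known
    'predictions' into the mining operations."""

    def __init__(self, m_mask: np.ndarray, n_classes: int = 3):
        shape = m_mask.shape
        self.config = types.SimpleNamespace(input_shape=shape, n_classes=n_classes)
        probs = np.zeros((1, n_classes) + shape, dtype=np.float32)
        probs[0, n_classes - 1][m_mask] = 1.0
        probs[0, 0][~m_mask] = 1.0
        self._probs = probs

    def forward(self, x):
        t = types.SimpleNamespace(data=self._probs)
        return t, t


class TestOtsu:
    def test_two_valued_image(self):
        img = np.zeros((10, 10))
        img[:3] = 200
        t = otsu_threshold(img)
        assert 0 <= t < 200

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(32, 32))
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_matches_exhaustive_on_phantom(self):
        ph = generate_phantom(tiny_phantom_config(seed=21))
        assert otsu_threshold(ph.ap_view) == brute_force_otsu(ph.ap_view)

    def test_shift_equivariance(self):
        ph = generate_phantom(tiny_phantom_config(seed=22))
        img = (ph.ap_view * 0.5).astype(np.int64)  # headroom for the shift
        t = otsu_threshold(img)
        assert otsu_threshold(img + 10) == t + 10

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((8, 8), 7))


class TestOtsuNMMask:
    def test_negative_phantom_recovers_silhouette(self):
        ph = generate_phantom(PhantomConfig(seed=23, n_lesions=0))
        nm = make_nm_mask_otsu(ph.ap_view, ph.lesion_mask_ap)
        agreement = (nm.mask == ph.silhouette_ap).mean()
        assert agreement >= 0.99
        assert nm.method == "otsu"
        assert nm.source_polarity == "negative"

    def test_positive_phantom_excludes_every_lesion_pixel(self):
        ph = generate_phantom(tiny_phantom_config(seed=24))
        nm = make_nm_mask_otsu(ph.ap_view, ph.lesion_mask_ap)
        assert not (nm.mask & ph.lesion_mask_ap).any()
        assert nm.source_polarity == "positive"

    def test_all_air_image_degenerate(self):
        with pytest.raises(DegenerateHistogramError):
            make_nm_mask_otsu(np.zeros((16, 16)), np.zeros((16, 16), bool))


class TestMining:
    def test_stub_blob_becomes_nm_mask(self):
        blob = np.zeros((16, 16), bool)
        blob[4:8, 4:8] = True
        model = StubModel(blob)
        (nm,) = mine_negative_masks(model, [np.zeros((16, 16))])
        assert np.array_equal(nm.mask, blob)
        assert nm.method == "negative_mining"

    def test_stub_empty_prediction_gives_empty_mask(self):
        model = StubModel(np.zeros((16, 16), bool))
        (nm,) = mine_negative_masks(model, [np.zeros((16, 16))])
        assert not nm.mask.any()

    def test_positive_mining_subtracts_lesions(self):
        pred = np.zeros((16, 16), bool)
        pred[2:10, 2:10] = True
        lesion = np.zeros((16, 16), bool)
        lesion[4:6, 4:6] = True
        model = StubModel(pred)
        (nm,) = mine_positive_masks(model, [np.zeros((16, 16))], [lesion])
        assert np.array_equal(nm.mask, pred & ~lesion)
        disjoint_lesion = np.zeros((16, 16), bool)
        disjoint_lesion[12:14, 12:14] = True
        (nm2,) = mine_positive_masks(model, [np.zeros((16, 16))], [disjoint_lesion])
        assert np.array_equal(nm2.mask, pred)

    def test_mined_masks_on_negatives_are_false_positives(
        self, trained_two_class, tiny_dataset
    ):
        negatives = [s.image for s in tiny_dataset.negatives]
        masks = mine_negative_masks(trained_two_class, negatives)
        for s, nm in zip(tiny_dataset.negatives, masks):
            # ground truth is empty, so every mined pixel is a false positive
            assert not (nm.mask & s.m_mask).any()

    def test_otsu_nm_area_exceeds_mining_nm_area(self, trained_two_class):
        # body-wide Otsu masks vs sparse mined false positives: a statistical
        # tendency over >= 20 phantoms, not a per-sample guarantee
        cfg = tiny_phantom_config(n_lesions=0)
        from scintiseg.phantom import generate_cohort

        negatives = [s.ap_view for s in generate_cohort(0, 20, 55, cfg)]
        otsu_areas = [
            make_nm_mask_otsu(img, np.zeros(img.shape, bool)).mask.sum()
            for img in negatives
        ]
        mined_areas = [nm.mask.sum() for nm in mine_negative_masks(trained_two_class, negatives)]
        assert np.mean(otsu_areas) > np.mean(mined_areas)


class TestEncodeThreeClass:
    def test_class_proportions(self):
        nm = np.zeros((10, 10), bool)
        nm[:1] = True  # 10%
        m = np.zeros((10, 10), bool)
        m[9, :5] = True  # 5%
        lm = encode_three_class(nm, m)
        counts = np.bincount(lm.classes.ravel(), minlength=3)
        assert tuple(counts) == (85, 10, 5)

    def test_empty_masks_all_bg(self):
        lm = encode_three_class(np.zeros((4, 4), bool), np.zeros((4, 4), bool))
        assert (lm.classes == BG).all()

    def test_one_hot_round_trip(self):
        rng = np.random.default_rng(0)
        classes = rng.integers(0, 3, (12, 12)).astype(np.uint8)
        lm = LabelMap(classes=classes)
        oh = lm.one_hot()
        assert np.allclose(oh.sum(axis=0), 1.0)
        assert np.array_equal(LabelMap.from_one_hot(oh).classes, classes)

    def test_overlap_rejected(self):
        both = np.ones((4, 4), bool)
        with pytest.raises(LabelConsistencyError):
            encode_three_class(both, both)

    @pytest.mark.parametrize("method", ["otsu", "mining_stub"])
    def test_partition_invariant(self, method):
        ph = generate_phantom(tiny_phantom_config(seed=31))
        if method == "otsu":
            nm = make_nm_mask_otsu(ph.ap_view, ph.lesion_mask_ap)
        else:
            pred = np.zeros(ph.ap_view.shape, bool)
            pred[10:30, 10:30] = True
            model = StubModel(pred)
            (nm,) = mine_positive_masks(model, [ph.ap_view], [ph.lesion_mask_ap])
        assert not (nm.mask & ph.lesion_mask_ap).any()
        lm = encode_three_class(nm, ph.lesion_mask_ap)
        # BG/NM/M partition the image: one class per pixel by construction
        assert set(np.unique(lm.classes)) <= {BG, NM, M}
        assert (lm.classes[ph.lesion_mask_ap] == M).all()
        assert (lm.classes[nm.mask] == NM).all()
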