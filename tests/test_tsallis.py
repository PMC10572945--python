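"""Tsallis 3D-histogram segmentation: oracles for local statistics, the
joint histogram, class probabilities, entropy closed forms, and threshold
search."""

import numpy as np
import pytest

from sonomass import phantom as ph
from sonomass import tsallis as ts


# ---------------------------------------------------------------------------
# local statistics


def test_local_stats_center_of_ramp():
    img = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    mean_map, median_map = ts.local_stats(img)
    assert mean_map[1, 1] == 5
    assert median_map[1, 1] == 5


def test_local_stats_constant_image():
    img = np.full((5, 5), 7)
    mean_map, median_map = ts.local_stats(img)
    assert np.all(mean_map == 7)
    assert np.all(median_map == 7)


def test_local_stats_corner_with_replicate_padding():
    # corner window of the 3x3 ramp replicates to {1,1,2,1,1,2,4,4,5}:
    # rounded mean floor(21/9 + .5) = 2, median 2
    img = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    mean_map, median_map = ts.local_stats(img)
    assert mean_map[0, 0] == 2
    assert median_map[0, 0] == 2


def test_local_stats_even_window_rejected():
    with pytest.raises(ValueError, match="odd"):
        ts.local_stats(np.zeros((4, 4)), g=2)


# ---------------------------------------------------------------------------
# 3D histogram


def _brute_force_histogram(img, mean_map, median_map, k):
    counts = np.zeros((k, k, k), dtype=np.int64)
    for l, m, n in zip(img.ravel(), mean_map.ravel(), median_map.ravel()):
        counts[l, m, n] += 1
    return counts


def test_histogram_constant_image():
    img = np.full((6, 6), 5)
    hist = ts.build_histogram3d(img, img, img, k=8)
    assert hist.prob[5, 5, 5] == 1.0
    assert hist.counts.sum() == 36


def test_histogram_matches_per_pixel_counting(rng):
    img = rng.integers(0, 8, size=(4, 4))
    mean_map, median_map = ts.local_stats(img)
    hist = ts.build_histogram3d(img, mean_map, median_map, k=8)
    assert np.array_equal(
        hist.counts, _brute_force_histogram(img, mean_map, median_map, 8)
    )
    assert hist.prob.sum() == pytest.approx(1.0, abs=1e-12)


def test_histogram_rejects_out_of_range():
    img = np.full((3, 3), 9)
    with pytest.raises(ValueError, match="outside"):
        ts.build_histogram3d(img, img, img, k=8)


# ---------------------------------------------------------------------------
# class probabilities


def test_single_class_when_threshold_at_top():
    img = np.full((4, 4), 5)
    hist = ts.build_histogram3d(img, img, img, k=8)
    thr = ts.ThresholdSet(t=(6,), a=(6,), b=(6,), lam=2.0)
    p = ts.class_probability(hist, thr)
    assert p == pytest.approx([1.0, 0.0])


def test_constant_image_above_threshold_fills_upper_class():
    img = np.full((4, 4), 5)
    hist = ts.build_histogram3d(img, img, img, k=8)
    thr = ts.ThresholdSet(t=(2,), a=(2,), b=(2,), lam=2.0)
    p = ts.class_probability(hist, thr)
    assert p == pytest.approx([0.0, 1.0])


def test_class_probability_matches_pixel_partition_oracle(rng):
    img = rng.integers(0, 8, size=(8, 8))
    mean_map, median_map = ts.local_stats(img)
    hist = ts.build_histogram3d(img, mean_map, median_map, k=8)
    thr = ts.ThresholdSet(t=(3,), a=(4,), b=(3,), lam=2.0)
    # oracle: count pixels whose full triple lands in each diagonal box
    counts = [0, 0]
    for l, m, n in zip(img.ravel(), mean_map.ravel(), median_map.ravel()):
        if l <= 3 and m <= 4 and n <= 3:
            counts[0] += 1
        elif l > 3 and m > 4 and n > 3:
            counts[1] += 1
    expected = np.array(counts, dtype=float)
    expected /= expected.sum()
    assert ts.class_probability(hist, thr) == pytest.approx(expected)


def test_class_probabilities_sum_to_one(rng):
    img = rng.integers(0, 16, size=(12, 12))
    mean_map, median_map = ts.local_stats(img)
    hist = ts.build_histogram3d(img, mean_map, median_map, k=16)
    for t, a, b in [((3, 9), (4, 8), (2, 11)), ((1,), (7,), (13,))]:
        thr = ts.ThresholdSet(t=t, a=a, b=b, lam=1.5)
        assert ts.class_probability(hist, thr).sum() == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# entropy closed forms


def _uniform_box_histogram(n_low, n_high, k=8):
    """Counts uniform over n_low diagonal triples below 4 and n_high above."""
    counts = np.zeros((k, k, k), dtype=np.int64)
    for i in range(n_low):
        counts[i, i, i] = 6
    for i in range(n_high):
        counts[k - 1 - i, k - 1 - i, k - 1 - i] = 6
    return ts.Histogram3D(counts=counts, k=k)


def test_degenerate_class_entropy_is_zero():
    hist = _uniform_box_histogram(1, 1)
    thr = ts.ThresholdSet(t=(3,), a=(3,), b=(3,), lam=2.0)
    ev = ts.TsallisEvaluator(hist, 2.0)
    assert ev.class_entropies(thr) == pytest.approx([0.0, 0.0])


def test_uniform_class_entropy_closed_form():
    # uniform over n triples at lambda=2: S = 1 - 1/n
    hist = _uniform_box_histogram(4, 2)
    thr = ts.ThresholdSet(t=(3,), a=(3,), b=(3,), lam=2.0)
    ev = ts.TsallisEvaluator(hist, 2.0)
    assert ev.class_entropies(thr) == pytest.approx([0.75, 0.5])


def test_pseudo_additive_composition():
    # S1=0.75, S2=0.5, lambda=2 -> 1.25 + (1-2)*0.375 = 0.875
    hist = _uniform_box_histogram(4, 2)
    thr = ts.ThresholdSet(t=(3,), a=(3,), b=(3,), lam=2.0)
    assert ts.tsallis_objective(hist, thr) == pytest.approx(0.875)


def test_lambda_one_rejected():
    with pytest.raises(ValueError):
        ts.ThresholdSet(t=(3,), a=(3,), b=(3,), lam=1.0)


def test_entropy_shannon_limit(rng):
    img = rng.integers(0, 8, size=(16, 16))
    mean_map, median_map = ts.local_stats(img)
    hist = ts.build_histogram3d(img, mean_map, median_map, k=8)
    thr_kw = dict(t=(3,), a=(3,), b=(3,))
    prob = hist.prob
    shannon = []
    for (lo, hi) in ts.ThresholdSet(lam=2.0, **thr_kw).boxes(8):
        box = prob[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        mass = box.sum()
        if mass > 0:
            q = box[box > 0] / mass
            shannon.append(float(-(q * np.log(q)).sum()))
        else:
            shannon.append(0.0)
    for lam in (1.0 - 1e-4, 1.0 + 1e-4):
        ev = ts.TsallisEvaluator(hist, lam)
        got = ev.class_entropies(ts.ThresholdSet(lam=lam, **thr_kw))
        assert got == pytest.approx(shannon, abs=1e-2)


def test_entropy_nonnegative_for_lambda_above_one(rng):
    img = rng.integers(0, 8, size=(10, 10))
    mean_map, median_map = ts.local_stats(img)
    hist = ts.build_histogram3d(img, mean_map, median_map, k=8)
    for lam in (1.2, 2.0, 3.5):
        ev = ts.TsallisEvaluator(hist, lam)
        for t in [(2,), (5,)]:
            s = ev.class_entropies(ts.ThresholdSet(t=t, a=t, b=t, lam=lam))
            assert np.all(s >= 0)


def test_objective_invariant_under_interior_translation():
    img = np.full((32, 32), 100, dtype=np.int64)
    img[8:14, 8:14] = 30
    img2 = np.full((32, 32), 100, dtype=np.int64)
    img2[12:18, 12:18] = 30
    thr = ts.ThresholdSet(t=(3,), a=(3,), b=(3,), lam=1.5)
    scores = []
    for im in (img, img2):
        mean_map, median_map = ts.local_stats(im)
        q = [ts.quantize(x, 256, 8) for x in (im, mean_map, median_map)]
        hist = ts.build_histogram3d(*q, k=8)
        scores.append(ts.tsallis_objective(hist, thr))
    assert scores[0] == pytest.approx(scores[1])


# ---------------------------------------------------------------------------
# threshold search


def _quantized_hist(img, k=8):
    mean_map, median_map = ts.local_stats(img)
    q = [ts.quantize(x, 256, k) for x in (img, mean_map, median_map)]
    return ts.build_histogram3d(*q, k=k)


def test_npoa_matches_exhaustive_on_small_instance(rng):
    img = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    hist = _quantized_hist(img, k=8)
    _, s_ex = ts.search_thresholds(hist, ml=1, lam=1.5, method="exhaustive")
    _, s_np = ts.search_thresholds(hist, ml=1, lam=1.5, method="npoa", seed=0)
    assert s_np >= 0.999 * s_ex


def test_constant_image_tie_breaks_to_smallest_triple():
    img = np.full((8, 8), 5, dtype=np.int64)
    hist = ts.build_histogram3d(img, img, img, k=8)
    thr, score = ts.search_thresholds(hist, ml=1, lam=2.0, method="exhaustive")
    assert score == pytest.approx(0.0)
    assert (thr.t, thr.a, thr.b) == ((0,), (0,), (0,))


def test_exhaustive_cap_enforced():
    img = np.zeros((4, 4), dtype=np.int64)
    hist = ts.build_histogram3d(img, img, img, k=8)
    with pytest.raises(ValueError, match="cap"):
        ts.search_thresholds(hist, ml=1, method="exhaustive", exhaustive_cap=10)


# ---------------------------------------------------------------------------
# applying thresholds


def test_two_region_threshold_between_modes(speckled_two_region):
    seg = ts.segment_image(speckled_two_region, ml=1, seed=0)
    assert 40 < seg.thresholds.t[0] < 200


def test_segmentation_recovers_phantom_mass(malignant_phantom):
    img, mask = malignant_phantom
    seg = ts.segment_image(img, seed=1)
    inter = np.sum(seg.roi_mask & mask)
    dice = 2 * inter / (seg.roi_mask.sum() + mask.sum())
    assert dice >= 0.9


def test_constant_image_roi_is_full_frame():
    img = np.full((32, 32), 90, dtype=np.uint8)
    seg = ts.segment_image(img, ml=1, seed=0, refine=False)
    assert seg.roi_mask.all()


def test_polarity_flips_foreground(two_region_image):
    mean_map, median_map = ts.local_stats(two_region_image)
    thr = ts.ThresholdSet(t=(120,), a=(120,), b=(120,), lam=1.5)
    _, roi_dark = ts.apply_thresholds(
        two_region_image, mean_map, median_map, thr, polarity="dark"
    )
    _, roi_bright = ts.apply_thresholds(
        two_region_image, mean_map, median_map, thr, polarity="bright"
    )
    assert np.array_equal(roi_dark, ~roi_bright)


def test_threshold_set_validation():
    with pytest.raises(ValueError, match="ascending"):
        ts.ThresholdSet(t=(5, 3), a=(1, 2), b=(1, 2), lam=1.5)
    with pytest.raises(ValueError, match="Tsallis index"):
        ts.ThresholdSet(t=(1,), a=(1,), b=(1,), lam=-0.5)
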