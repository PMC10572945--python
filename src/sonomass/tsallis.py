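"""Mass segmentation by Tsallis-entropy multilevel thresholding of the 3D
(intensity, local-mean, local-median) histogram.

Each pixel contributes a gray-level triple (l, m, n): its own intensity, the
rounded mean of its 3x3 neighborhood, and the neighborhood median.  The joint
histogram of these triples is partitioned by per-axis threshold vectors into
ML+1 diagonal axis-aligned boxes; the thresholds maximize the pseudo-additive
Tsallis composition of the per-box entropies

    S_z = (1 - sum_box (p / P_z)^lambda) / (lambda - 1),
    score = sum_z S_z + (1 - lambda) * prod_z S_z,

with P_z the box probability mass and S_z := 0 for empty boxes.  Using the
local mean and median alongside raw intensity makes the criterion robust to
speckle while preserving edges, since noisy pixels fall off the histogram
diagonal and stop dominating the box masses.

For tractability the histogram axes may be quantized to ``k_q`` levels before
the search; selected thresholds are mapped back to the full intensity scale
at bin boundaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# local statistics and the 3D histogram


def local_stats(img: np.ndarray, g: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Rounded local mean and exact local median over a g x g window.

    Borders are handled by replicate padding.  The mean is
    ``floor(window_sum / g^2 + 0.5)`` so triples stay on the integer lattice;
    the median is the middle order statistic of the window.

    Returns ``(mean_map, median_map)``, both integer rasters of the input
    shape.
    """
    if g % 2 == 0:
        raise ValueError("window size g must be odd")
    if g > min(img.shape):
        raise ValueError("window larger than image")
    arr = np.asarray(img, dtype=np.int64)
    kernel = np.ones((g, g), dtype=np.int64)
    window_sum = ndimage.correlate(arr, kernel, mode="nearest")
    # integer floor(sum/g^2 + 0.5) without float round-off
    mean_map = (2 * window_sum + g * g) // (2 * g * g)
    median_map = ndimage.median_filter(arr, size=g, mode="nearest")
    return mean_map.astype(np.int64), median_map.astype(np.int64)


@dataclass
class Histogram3D:
    """Joint counts of (intensity, mean, median) triples.

    ``counts[l, m, n]`` is the number of pixels whose triple is (l, m, n);
    ``prob`` divides by the pixel count so the tensor sums to 1.
    """

    counts: np.ndarray
    k: int

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def prob(self) -> np.ndarray:
        return self.counts / self.n_pixels


def build_histogram3d(
    img: np.ndarray,
    mean_map: np.ndarray,
    median_map: np.ndarray,
    k: int = 256,
) -> Histogram3D:
    """Exact triple counts over a k x k x k lattice."""
    l = np.asarray(img, dtype=np.int64).ravel()
    m = np.asarray(mean_map, dtype=np.int64).ravel()
    n = np.asarray(median_map, dtype=np.int64).ravel()
    if l.shape != m.shape or l.shape != n.shape:
        raise ValueError("image and statistic maps must share a shape")
    for axis in (l, m, n):
        if axis.min() < 0 or axis.max() >= k:
            raise ValueError(f"values outside [0, {k - 1}]")
    flat = (l * k + m) * k + n
    counts = np.bincount(flat, minlength=k**3).reshape(k, k, k)
    return Histogram3D(counts=counts, k=k)


def quantize(values: np.ndarray, k_int: int, k_q: int) -> np.ndarray:
    """Map integer values in [0, k_int) onto k_q equal-width bins."""
    return (np.asarray(values, dtype=np.int64) * k_q) // k_int


def threshold_to_full_scale(t_q: int, k_int: int, k_q: int) -> int:
    """Full-scale threshold equivalent to quantized threshold ``t_q``.

    A quantized threshold separates bins <= t_q from bins > t_q; the
    equivalent full-scale cut sits at the upper boundary of bin t_q.
    """
    return (t_q + 1) * k_int // k_q - 1


# ---------------------------------------------------------------------------
# thresholds and the Tsallis objective


@dataclass(frozen=True)
class ThresholdSet:
    """Per-axis ascending thresholds plus the Tsallis index.

    ``t`` thresholds the intensity axis, ``a`` the local-mean axis, ``b`` the
    local-median axis; each is a strictly ascending tuple of integers in
    [0, k-2].  ``lam`` is the entropic index (> 0, != 1).
    """

    t: tuple[int, ...]
    a: tuple[int, ...]
    b: tuple[int, ...]
    lam: float = 1.5

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.lam == 1.0:
            raise ValueError("Tsallis index must be > 0 and != 1")
        lens = {len(self.t), len(self.a), len(self.b)}
        if len(lens) != 1:
            raise ValueError("axes must carry the same number of thresholds")
        for vec in (self.t, self.a, self.b):
            if any(v2 <= v1 for v1, v2 in zip(vec, vec[1:])):
                raise ValueError("thresholds must be strictly ascending")

    @property
    def ml(self) -> int:
        return len(self.t)

    def boxes(self, k: int) -> list[tuple[tuple[int, int, int], tuple[int, int, int]]]:
        """Inclusive (lo, hi) index corners of the ML+1 diagonal boxes."""
        et = (-1,) + self.t + (k - 1,)
        ea = (-1,) + self.a + (k - 1,)
        eb = (-1,) + self.b + (k - 1,)
        out = []
        for z in range(self.ml + 1):
            lo = (et[z] + 1, ea[z] + 1, eb[z] + 1)
            hi = (et[z + 1], ea[z + 1], eb[z + 1])
            out.append((lo, hi))
        return out


class TsallisEvaluator:
    """Cached prefix sums for O(1) evaluation of box masses and entropies."""

    def __init__(self, hist: Histogram3D, lam: float):
        if lam <= 0 or lam == 1.0:
            raise ValueError("Tsallis index must be > 0 and != 1")
        self.k = hist.k
        self.lam = lam
        prob = hist.prob
        self._cp = self._padded_cumsum(prob)
        with np.errstate(divide="ignore"):
            self._cq = self._padded_cumsum(np.where(prob > 0, prob, 0.0) ** lam)

    @staticmethod
    def _padded_cumsum(arr: np.ndarray) -> np.ndarray:
        c = arr.cumsum(0).cumsum(1).cumsum(2)
        return np.pad(c, ((1, 0), (1, 0), (1, 0)))

    def _box(self, c: np.ndarray, lo, hi) -> float:
        l0, m0, n0 = lo
        l1, m1, n1 = (hi[0] + 1, hi[1] + 1, hi[2] + 1)
        if l1 <= l0 or m1 <= m0 or n1 <= n0:
            return 0.0
        return float(
            c[l1, m1, n1]
            - c[l0, m1, n1]
            - c[l1, m0, n1]
            - c[l1, m1, n0]
            + c[l0, m0, n1]
            + c[l0, m1, n0]
            + c[l1, m0, n0]
            - c[l0, m0, n0]
        )

    def box_masses(self, thr: ThresholdSet) -> np.ndarray:
        """Raw probability mass of each diagonal class box."""
        return np.array([self._box(self._cp, lo, hi) for lo, hi in thr.boxes(self.k)])

    def class_entropies(self, thr: ThresholdSet) -> np.ndarray:
        """Per-box Tsallis entropies; empty boxes contribute 0."""
        lam = self.lam
        out = []
        for lo, hi in thr.boxes(self.k):
            p = self._box(self._cp, lo, hi)
            if p <= 0:
                out.append(0.0)
                continue
            q = self._box(self._cq, lo, hi)
            out.append((1.0 - q / p**lam) / (lam - 1.0))
        return np.array(out)

    def score(self, thr: ThresholdSet) -> float:
        s = self.class_entropies(thr)
        return float(s.sum() + (1.0 - self.lam) * s.prod())


def class_probability(hist: Histogram3D, thr: ThresholdSet) -> np.ndarray:
    """Class probabilities of the ML+1 diagonal boxes, normalized to sum 1.

    Raw box masses need not sum to 1 because speckle pushes some triples off
    the histogram diagonal; masses are renormalized by the total in-box mass
    (the entropy criterion itself uses only within-box ratios, so the score
    is unaffected).
    """
    ev = TsallisEvaluator(hist, thr.lam)
    raw = ev.box_masses(thr)
    total = raw.sum()
    if total <= 0:
        return raw
    return raw / total


def tsallis_objective(hist: Histogram3D, thr: ThresholdSet) -> float:
    """Pseudo-additive Tsallis score of one threshold set."""
    return TsallisEvaluator(hist, thr.lam).score(thr)


# ---------------------------------------------------------------------------
# threshold search


def _decode_vector(x: np.ndarray, ml: int, k: int) -> tuple[tuple[int, ...], ...]:
    """Continuous optimizer position -> strictly ascending integer thresholds."""
    axes = []
    for ax in range(3):
        vals = np.sort(np.clip(np.rint(x[ax * ml : (ax + 1) * ml]), 0, k - 2))
        vals = vals.astype(int)
        for i in range(1, ml):  # repair collisions deterministically
            if vals[i] <= vals[i - 1]:
                vals[i] = vals[i - 1] + 1
        vals = np.minimum(vals, k - 2)
        for i in range(ml - 2, -1, -1):
            if vals[i] >= vals[i + 1]:
                vals[i] = vals[i + 1] - 1
        axes.append(tuple(int(v) for v in vals))
    return tuple(axes)


def search_thresholds(
    hist: Histogram3D,
    ml: int = 2,
    lam: float = 1.5,
    method: str = "npoa",
    budget: int = 1500,
    seed: int = 0,
    exhaustive_cap: int = 2_000_000,
) -> tuple[ThresholdSet, float]:
    """Maximize the Tsallis objective over ascending threshold triples.

    ``method='exhaustive'`` enumerates every valid combination (global
    optimum, ties broken by lexicographically smallest (t, a, b));
    ``method='npoa'`` runs the nomadic-people optimizer over a continuous
    relaxation, rounding to the integer lattice.
    """
    k = hist.k
    ev = TsallisEvaluator(hist, lam)

    if method == "exhaustive":
        per_axis = list(itertools.combinations(range(k - 1), ml))
        n_cand = len(per_axis) ** 3
        if n_cand > exhaustive_cap:
            raise ValueError(
                f"exhaustive search of {n_cand} candidates exceeds cap {exhaustive_cap}"
            )
        best: ThresholdSet | None = None
        best_score = -np.inf
        for t in per_axis:
            for a in per_axis:
                for b in per_axis:
                    thr = ThresholdSet(t=t, a=a, b=b, lam=lam)
                    s = ev.score(thr)
                    if s > best_score:  # lex order of iteration => lex tie-break
                        best, best_score = thr, s
        assert best is not None
        return best, best_score

    if method == "npoa":
        from .npoa import optimize

        def objective(x: np.ndarray) -> float:
            t, a, b = _decode_vector(x, ml, k)
            return -ev.score(ThresholdSet(t=t, a=a, b=b, lam=lam))

        bounds = [(0.0, float(k - 2))] * (3 * ml)
        res = optimize(
            objective, bounds, n_clans=4, n_families=6, budget=budget, seed=seed
        )
        t, a, b = _decode_vector(res.best_position, ml, k)
        thr = ThresholdSet(t=t, a=a, b=b, lam=lam)
        return thr, ev.score(thr)

    raise ValueError(f"unknown search method: {method!r}")


# ---------------------------------------------------------------------------
# applying thresholds to an image


def apply_thresholds(
    img: np.ndarray,
    mean_map: np.ndarray,
    median_map: np.ndarray,
    thr: ThresholdSet,
    polarity: str = "dark",
    fill_holes: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Label pixels by their triple's class box and extract the ROI mask.

    Each axis value is binned by its threshold vector; on-diagonal triples
    (all three bins equal) take that class, off-diagonal triples take the
    median of the three bin indices.  The ROI is the largest connected
    component of the foreground class — class 0 when ``polarity='dark'``
    (hypoechoic masses), class ML when ``polarity='bright'`` — with interior
    holes filled.
    """
    bins_l = np.digitize(img, [v + 0.5 for v in thr.t])
    bins_m = np.digitize(mean_map, [v + 0.5 for v in thr.a])
    bins_n = np.digitize(median_map, [v + 0.5 for v in thr.b])
    label_map = np.median(np.stack([bins_l, bins_m, bins_n]), axis=0).astype(np.int64)

    # Foreground class: the one whose box contains the darker (or brighter)
    # histogram mode.  The mode search runs on the local-mean map (the
    # denoised intensity) and assumes the mass mean differs from the
    # dominant background mode by at least ~25%; classes beyond the mass
    # class toward the polarity extreme are folded in, since an
    # edge-gradient class may split the mass mode across boxes.
    hist1d = np.bincount(np.asarray(mean_map).ravel().astype(np.int64))
    smooth = ndimage.gaussian_filter1d(hist1d.astype(float), 5)
    dominant = int(np.argmax(smooth))
    def _mode_class(mode: int) -> int:
        # classify the mode triple (mode, mode, mode) exactly like a pixel
        votes = [
            int(np.digitize(mode, [v + 0.5 for v in vec]))
            for vec in (thr.t, thr.a, thr.b)
        ]
        return int(np.median(votes))

    if polarity == "dark":
        cut = int(round(0.75 * dominant))
        head = smooth[: cut + 1]
        mode = int(np.argmax(head)) if head.size and head.max() > 0 else dominant
        fg = label_map <= _mode_class(mode)
    elif polarity == "bright":
        cut = int(round(1.25 * dominant))
        tail = smooth[cut:] if cut < smooth.size else np.array([])
        mode = cut + int(np.argmax(tail)) if tail.size and tail.max() > 0 else dominant
        fg = label_map >= _mode_class(mode)
    else:
        raise ValueError(f"polarity must be 'dark' or 'bright', got {polarity!r}")

    labeled, n_comp = ndimage.label(fg)
    if n_comp == 0:
        roi = np.zeros_like(fg)
    else:
        sizes = ndimage.sum_labels(fg, labeled, index=np.arange(1, n_comp + 1))
        roi = labeled == (1 + int(np.argmax(sizes)))
        if fill_holes:
            roi = ndimage.binary_fill_holes(roi)
    return label_map, roi


def refine_roi(
    img: np.ndarray,
    roi: np.ndarray,
    mean_map: np.ndarray | None = None,
    polarity: str = "dark",
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Half-level boundary refinement of an initial ROI mask.

    The Tsallis thresholds localize the mass but the exact cut level inside
    the edge-gradient band varies with the histogram, which shifts and
    roughens the recovered boundary.  This step re-anchors the boundary at
    the half-contrast level of the local-mean map (the denoised intensity):
    the mass and background levels are estimated from the initial mask, the
    level set at their midpoint is extracted, and the component overlapping
    the initial ROI is kept, hole-filled, and smoothed at the speckle scale
    (Gaussian on the binary mask, re-threshold at 0.5).
    """
    roi = np.asarray(roi, dtype=bool)
    if mean_map is None:
        mean_map, _ = local_stats(img)

    def _smooth(mask: np.ndarray) -> np.ndarray:
        if smooth_sigma <= 0:
            return mask
        out = ndimage.gaussian_filter(mask.astype(float), smooth_sigma) > 0.5
        labeled, n = ndimage.label(out)
        if n > 1:
            sizes = ndimage.sum_labels(out, labeled, index=np.arange(1, n + 1))
            out = labeled == (1 + int(np.argmax(sizes)))
        return out

    degenerate = roi.all() or not roi.any() or roi.mean() > 0.6
    if degenerate:
        # fall back to histogram modes when the initial mask carries no
        # usable foreground/background partition
        hist1d = np.bincount(mean_map.ravel().astype(np.int64))
        smooth = ndimage.gaussian_filter1d(hist1d.astype(float), 5)
        dominant = int(np.argmax(smooth))
        if polarity == "dark":
            cut = int(round(0.75 * dominant))
            head = smooth[: cut + 1]
            mass = int(np.argmax(head)) if head.size and head.max() > 0 else dominant
        else:
            cut = int(round(1.25 * dominant))
            tail = smooth[cut:]
            mass = (
                cut + int(np.argmax(tail))
                if tail.size and tail.max() > 0
                else dominant
            )
        bg = dominant
    else:
        mass = float(mean_map[roi].mean())
        bg = float(mean_map[~roi].mean())
    half = 0.5 * (mass + bg)
    cand = mean_map <= half if polarity == "dark" else mean_map >= half
    labeled, n = ndimage.label(cand)
    if n == 0:
        return _smooth(roi)
    if degenerate:
        sizes = ndimage.sum_labels(cand, labeled, index=np.arange(1, n + 1))
        keep = 1 + int(np.argmax(sizes))
    else:
        overlaps = ndimage.sum_labels(
            roi.astype(float), labeled, index=np.arange(1, n + 1)
        )
        keep = 1 + int(np.argmax(overlaps))
    out = ndimage.binary_fill_holes(labeled == keep)
    return _smooth(out)


@dataclass
class SegmentationResult:
    """Output of :func:`segment_image`."""

    label_map: np.ndarray
    roi_mask: np.ndarray
    thresholds: ThresholdSet  # on the full intensity scale
    thresholds_q: ThresholdSet  # on the quantized scale used for the search
    score: float
    k_q: int


def segment_image(
    img: np.ndarray,
    ml: int = 2,
    lam: float = 1.5,
    k_int: int = 256,
    k_q: int = 32,
    method: str = "npoa",
    budget: int = 1500,
    seed: int = 0,
    polarity: str = "dark",
    refine: bool = True,
    smooth_sigma: float = 2.0,
) -> SegmentationResult:
    """Full segmentation of one grayscale image.

    Local statistics are computed at full bit depth, the three axes are
    quantized to ``k_q`` bins for the threshold search, and the selected
    thresholds are mapped back to the [0, k_int-1] scale.  With ``refine``
    the ROI boundary is re-anchored at the half-contrast level and smoothed
    at the speckle scale (see :func:`refine_roi`).
    """
    mean_map, median_map = local_stats(img)
    ql = quantize(img, k_int, k_q)
    qm = quantize(mean_map, k_int, k_q)
    qn = quantize(median_map, k_int, k_q)
    hist = build_histogram3d(ql, qm, qn, k=k_q)
    thr_q, score = search_thresholds(
        hist, ml=ml, lam=lam, method=method, budget=budget, seed=seed
    )
    to_full = lambda vec: tuple(threshold_to_full_scale(v, k_int, k_q) for v in vec)
    thr_full = ThresholdSet(
        t=to_full(thr_q.t), a=to_full(thr_q.a), b=to_full(thr_q.b), lam=lam
    )
    label_map, roi = apply_thresholds(
        img, mean_map, median_map, thr_full, polarity=polarity
    )
    if refine:
        roi = refine_roi(
            img, roi, mean_map=mean_map, polarity=polarity,
            smooth_sigma=smooth_sigma,
        )
    return SegmentationResult(
        label_map=label_map,
        roi_mask=roi,
        thresholds=thr_full,
        thresholds_q=thr_q,
        score=score,
        k_q=k_q,
    )
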