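"""Statistical texture features of curvelet coefficient matrices.

Eleven features are computed per coefficient matrix (on the magnitudes of
the complex wedge coefficients): marginal means and standard deviations
along both axes, a third-central-moment skewness, and the GLCM-style
contrast, energy, homogeneity, entropy, correlation, and dissimilarity.
The marginal moments and correlation use the weighted-marginal convention
(weights M / sum(M)), which keeps correlation in [-1, 1]; contrast, energy,
homogeneity, entropy and dissimilarity are evaluated directly on the matrix
as given.  At extraction time each magnitude matrix is normalized to unit
sum first (probability-matrix convention), switchable off for raw
magnitudes.
"""

from __future__ import annotations

import numpy as np

FEATURE_NAMES = (
    "mean_x",
    "mean_y",
    "sd_x",
    "sd_y",
    "skewness",
    "contrast",
    "energy",
    "homogeneity",
    "entropy",
    "correlation",
    "dissimilarity",
)


def compute_features(matrix: np.ndarray, normalized_skewness: bool = False) -> dict[str, float]:
    """The 11 texture features of one nonnegative real matrix.

    ``skewness`` is the third central moment (1/(i*j)) * sum (M - mean)^3 by
    default; ``normalized_skewness`` divides by the cube of the matrix
    standard deviation instead.  Entropy treats zero entries as contributing
    0 (0 * log 0 := 0); correlation is defined as 0 whenever either marginal
    standard deviation vanishes.
    """
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise ValueError("empty matrix")
    if m.min() < 0:
        raise ValueError("matrix must be nonnegative (use coefficient magnitudes)")
    i, j = m.shape
    a = np.arange(i, dtype=float)[:, None]
    b = np.arange(j, dtype=float)[None, :]

    total = m.sum()
    if total > 0:
        px = m.sum(axis=1) / total  # marginal over rows
        py = m.sum(axis=0) / total
        mean_x = float(np.sum(np.arange(i) * px))
        mean_y = float(np.sum(np.arange(j) * py))
        sd_x = float(np.sqrt(np.sum((np.arange(i) - mean_x) ** 2 * px)))
        sd_y = float(np.sqrt(np.sum((np.arange(j) - mean_y) ** 2 * py)))
    else:
        mean_x = mean_y = sd_x = sd_y = 0.0

    mean_all = float(m.mean())
    skew = float(np.mean((m - mean_all) ** 3))
    if normalized_skewness:
        sd_all = float(m.std())
        skew = skew / sd_all**3 if sd_all > 0 else 0.0

    contrast = float(np.sum(m * (a - b) ** 2))
    energy = float(np.sum(m**2))
    homogeneity = float(np.sum(m / (1.0 + np.abs(a - b))))
    with np.errstate(divide="ignore", invalid="ignore"):
        logm = np.where(m > 0, np.log(np.where(m > 0, m, 1.0)), 0.0)
    entropy = float(np.sum(m * logm))
    dissimilarity = float(np.sum(np.abs(a - b) * m))

    if total > 0 and sd_x > 0 and sd_y > 0:
        correlation = float(
            (np.sum(m * a * b) / total - mean_x * mean_y) / (sd_x * sd_y)
        )
    else:
        correlation = 0.0

    return {
        "mean_x": mean_x,
        "mean_y": mean_y,
        "sd_x": sd_x,
        "sd_y": sd_y,
        "skewness": skew,
        "contrast": contrast,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
        "correlation": correlation,
        "dissimilarity": dissimilarity,
    }


def extract_radiomics(
    coeffs, normalize: bool = True, normalized_skewness: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Concatenated per-wedge feature blocks in (scale, wedge) order.

    Each coefficient matrix is reduced to its magnitudes, optionally
    normalized to unit sum, and passed through :func:`compute_features`.
    Feature names follow ``s{scale}_w{wedge}_{feature}``.

    Returns ``(vector, names)`` with ``len(vector) == 11 * n_matrices``.
    """
    values: list[float] = []
    names: list[str] = []
    for scale, wedge, matrix in coeffs.matrices():
        mag = np.abs(matrix)
        if normalize:
            s = mag.sum()
            if s > 0:
                mag = mag / s
        feats = compute_features(mag, normalized_skewness=normalized_skewness)
        for fname in FEATURE_NAMES:
            values.append(feats[fname])
            names.append(f"s{scale}_w{wedge}_{fname}")
    return np.asarray(values), names


def image_features(
    img: np.ndarray,
    mask: np.ndarray | None = None,
    size: int = 128,
    n_coarse_angles: int = 16,
    normalize: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Curvelet radiomics of one (optionally ROI-masked) grayscale image.

    The masked image is resized to ``size x size`` (bilinear) before the
    wrapping curvelet decomposition, then reduced to the concatenated
    11-feature blocks.
    """
    from skimage.transform import resize

    from .curvelet import fdct_wrp_forward

    arr = np.asarray(img, dtype=float)
    if mask is not None:
        arr = arr * mask
    if arr.shape != (size, size):
        arr = resize(arr, (size, size), order=1, anti_aliasing=True,
                     preserve_range=True)
    coeffs = fdct_wrp_forward(arr, n_coarse_angles=n_coarse_angles)
    return extract_radiomics(coeffs, normalize=normalize)
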