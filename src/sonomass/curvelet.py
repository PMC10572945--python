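"""Fast discrete curvelet transform by wrapping (FDCT-WRP).

The image spectrum is partitioned with smooth Meyer-type windows into
concentric coronae (scales) and angular wedges (orientations).  The squared
windows sum to exactly 1 over the frequency grid, so the transform is a
tight frame: energy is preserved (Parseval) and the adjoint reconstructs the
input to machine precision.  Each windowed wedge is wrapped around the
origin — re-indexed modulo the dimensions of its frequency bounding box —
and inverse-transformed into a small complex coefficient matrix, which keeps
the redundancy far below one full-size band per orientation.

Scale count for an nc x ns image follows floor(log2(min(nc, ns))) - 3, so a
128 x 128 image decomposes into 4 scales.  The coarsest scale is a single
isotropic wedge; the second-coarsest carries 16 orientations by default and
the count doubles every other scale (16, 16, 32, 32, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def num_scales(nc: int, ns: int) -> int:
    """Number of decomposition scales for an nc x ns image.

    ``floor(log2(min(nc, ns))) - 3``, at least 1; images smaller than 16
    pixels on a side are rejected.
    """
    m = min(nc, ns)
    if m < 16:
        raise ValueError("image must be at least 16 pixels on its short side")
    return max(int(np.floor(np.log2(m))) - 3, 1)


def wedge_counts(n_scales: int, n_coarse_angles: int = 16) -> list[int]:
    """Orientations per scale, coarse to fine: 1 isotropic wedge, then
    ``n_coarse_angles`` doubling every other scale."""
    counts = [1]
    for s in range(2, n_scales + 1):
        counts.append(n_coarse_angles * 2 ** ((s - 2) // 2))
    return counts


def _meyer_nu(x: np.ndarray) -> np.ndarray:
    """Polynomial Meyer step: 0 at 0, 1 at 1, with nu(x) + nu(1-x) = 1."""
    x = np.clip(x, 0.0, 1.0)
    return x**4 * (35.0 - 84.0 * x + 70.0 * x**2 - 20.0 * x**3)


def _smooth_cutoff(r: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """1 below ``lo``, cosine-Meyer ramp on [lo, hi], 0 above ``hi``."""
    out = np.ones_like(r)
    ramp = (r >= lo) & (r < hi)
    out[ramp] = np.cos(0.5 * np.pi * _meyer_nu((r[ramp] - lo) / (hi - lo)))
    out[r >= hi] = 0.0
    return out


@dataclass
class _Wedge:
    scale: int  # 1-based, 1 = coarsest
    angle: int  # 0-based orientation index within the scale
    window: np.ndarray  # cropped window values (float)
    row0: int  # crop offset in the fftshifted grid
    col0: int
    wrap_rows: np.ndarray  # permutation of 0..P1-1: target rows after wrapping
    wrap_cols: np.ndarray


class CurveletSystem:
    """Precomputed window system for one image shape.

    Building the windows costs a few full-grid passes; systems are cached by
    (shape, n_scales, n_coarse_angles) via :func:`get_system`.
    """

    def __init__(self, shape: tuple[int, int], n_scales: int | None = None,
                 n_coarse_angles: int = 16):
        n1, n2 = shape
        if n_scales is None:
            n_scales = num_scales(n1, n2)
        self.shape = (n1, n2)
        self.n_scales = n_scales
        self.counts = wedge_counts(n_scales, n_coarse_angles)
        self.wedges: list[_Wedge] = []
        self._build()

    def _build(self) -> None:
        n1, n2 = self.shape
        f1 = np.fft.fftshift(np.fft.fftfreq(n1)) * n1  # centered integer freqs
        f2 = np.fft.fftshift(np.fft.fftfreq(n2)) * n2
        w1 = f1[:, None] / (n1 / 2.0)
        w2 = f2[None, :] / (n2 / 2.0)
        r = np.maximum(np.abs(w1), np.abs(w2))  # concentric-square radius
        theta = np.arctan2(np.broadcast_to(w2, r.shape),
                           np.broadcast_to(w1, r.shape))

        J = self.n_scales
        if J == 1:
            radial = [np.ones_like(r)]
        else:
            cut = [_smooth_cutoff(r, 2.0 ** -(J - k), 2.0 ** -(J - k - 1))
                   for k in range(1, J)]
            radial = [cut[0]]
            for s in range(2, J):
                radial.append(np.sqrt(np.maximum(cut[s - 1] ** 2 - cut[s - 2] ** 2, 0.0)))
            radial.append(np.sqrt(np.maximum(1.0 - cut[J - 2] ** 2, 0.0)))

        windows: list[tuple[int, int, np.ndarray]] = [(1, 0, radial[0])]
        for s in range(2, J + 1):
            n_ang = self.counts[s - 1]
            delta = 2.0 * np.pi / n_ang
            for l in range(n_ang):
                center = -np.pi + l * delta
                d = np.abs((theta - center + np.pi) % (2.0 * np.pi) - np.pi)
                ang = np.where(
                    d < delta, np.cos(0.5 * np.pi * _meyer_nu(d / delta)), 0.0
                )
                windows.append((s, l, radial[s - 1] * ang))

        # exact partition of unity: normalize the squared-window sum to 1
        total = np.zeros_like(r)
        for _, _, u in windows:
            total += u**2
        norm = np.sqrt(total)
        if np.any(norm == 0):
            raise RuntimeError("window system leaves uncovered frequencies")

        half1, half2 = n1 // 2, n2 // 2
        for s, l, u in windows:
            u = u / norm
            rows = np.flatnonzero(u.any(axis=1))
            cols = np.flatnonzero(u.any(axis=0))
            r0, r1 = int(rows[0]), int(rows[-1])
            c0, c1 = int(cols[0]), int(cols[-1])
            p1, p2 = r1 - r0 + 1, c1 - c0 + 1
            # wrap around the origin: true frequency index modulo box size;
            # the support spans exactly p1 (p2) consecutive indices, so the
            # modulo map is a bijection onto the box
            wrap_rows = (np.arange(r0, r1 + 1) - half1) % p1
            wrap_cols = (np.arange(c0, c1 + 1) - half2) % p2
            self.wedges.append(
                _Wedge(s, l, u[r0 : r1 + 1, c0 : c1 + 1], r0, c0,
                       wrap_rows, wrap_cols)
            )

    # -- transforms --------------------------------------------------------

    def forward(self, img: np.ndarray) -> "CurveletCoefficients":
        img = np.asarray(img, dtype=float)
        if img.shape != self.shape:
            raise ValueError(f"expected image of shape {self.shape}")
        spectrum = np.fft.fftshift(np.fft.fft2(img, norm="ortho"))
        per_scale: list[list[np.ndarray]] = [[] for _ in range(self.n_scales)]
        for w in self.wedges:
            p1, p2 = w.window.shape
            block = (
                spectrum[w.row0 : w.row0 + p1, w.col0 : w.col0 + p2] * w.window
            )
            wrapped = np.zeros((p1, p2), dtype=complex)
            wrapped[np.ix_(w.wrap_rows, w.wrap_cols)] = block
            per_scale[w.scale - 1].append(np.fft.ifft2(wrapped, norm="ortho"))
        return CurveletCoefficients(scales=per_scale, shape=self.shape,
                                    n_coarse_angles=self.counts[1] if self.n_scales > 1 else 16)

    def inverse(self, coeffs: "CurveletCoefficients") -> np.ndarray:
        acc = np.zeros(self.shape, dtype=complex)
        it = iter([c for scale in coeffs.scales for c in scale])
        for w in self.wedges:
            c = next(it)
            p1, p2 = w.window.shape
            if c.shape != (p1, p2):
                raise ValueError("coefficient matrix shape mismatch")
            wrapped = np.fft.fft2(c, norm="ortho")
            block = wrapped[np.ix_(w.wrap_rows, w.wrap_cols)]
            acc[w.row0 : w.row0 + p1, w.col0 : w.col0 + p2] += block * w.window
        return np.fft.ifft2(np.fft.ifftshift(acc), norm="ortho").real


@dataclass
class CurveletCoefficients:
    """Per-scale, per-wedge complex coefficient matrices."""

    scales: list[list[np.ndarray]]
    shape: tuple[int, int]
    n_coarse_angles: int = 16

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def matrices(self) -> list[tuple[int, int, np.ndarray]]:
        """Flat (scale, wedge, matrix) list in deterministic order."""
        return [
            (s + 1, w, m)
            for s, scale in enumerate(self.scales)
            for w, m in enumerate(scale)
        ]

    def energy(self) -> float:
        return float(sum(np.sum(np.abs(m) ** 2) for _, _, m in self.matrices()))

    def wedge_energies(self, scale: int) -> np.ndarray:
        """Energy per wedge at one (1-based) scale."""
        return np.array(
            [np.sum(np.abs(m) ** 2) for m in self.scales[scale - 1]]
        )


_SYSTEMS: dict[tuple, CurveletSystem] = {}


def get_system(shape: tuple[int, int], n_scales: int | None = None,
               n_coarse_angles: int = 16) -> CurveletSystem:
    """Cached window system for a given image shape."""
    key = (shape, n_scales, n_coarse_angles)
    if key not in _SYSTEMS:
        _SYSTEMS[key] = CurveletSystem(shape, n_scales, n_coarse_angles)
    return _SYSTEMS[key]


def fdct_wrp_forward(img: np.ndarray, n_scales: int | None = None,
                     n_coarse_angles: int = 16) -> CurveletCoefficients:
    """Forward wrapping curvelet transform of a 2D image."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("input must be a 2D image")
    return get_system(img.shape, n_scales, n_coarse_angles).forward(img)


def fdct_wrp_inverse(coeffs: CurveletCoefficients,
                     n_coarse_angles: int | None = None) -> np.ndarray:
    """Inverse transform (exact, tight frame)."""
    return get_system(
        coeffs.shape, coeffs.n_scales,
        n_coarse_angles if n_coarse_angles is not None else coeffs.n_coarse_angles,
    ).inverse(coeffs)
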