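"""Synthetic grayscale ultrasound phantoms with labeled pelvic-mass lesions.

Real B-mode images of adnexal masses are not publicly distributable, so this
module renders desk-scale stand-ins: a hypoechoic (darker) mass with a
class-dependent boundary irregularity on a speckled background.  The three
classes — benign, borderline, malignant — differ by the amplitude of a radial
sinusoidal perturbation of an elliptical boundary, mirroring the clinical
heuristic that irregular margins correlate with malignant potential.

Speckle is modelled as gamma-distributed multiplicative noise with mean 1,
the standard fully-developed-speckle surrogate; the shape parameter sets the
signal-to-noise ratio without simulating beam physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

CLASS_NAMES = ("benign", "borderline", "malignant")

#: default boundary-irregularity amplitude per class (fraction of radius)
IRREGULARITY = {"benign": 0.02, "borderline": 0.12, "malignant": 0.30}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom image.

    Attributes
    ----------
    class_label : str
        One of ``benign``, ``borderline``, ``malignant``.
    height, width : int
        Frame size in pixels, each >= 32.
    axes : tuple of float
        Ellipse semi-axes (pixels) of the mass before perturbation.
    irregularity : float or None
        Amplitude of the radial sinusoidal boundary perturbation as a
        fraction of the local radius.  ``None`` selects the class default.
    n_lobes : int
        Number of sinusoidal harmonics perturbing the boundary.
    mass_contrast : float
        Mean-intensity offset of the mass relative to background (gray
        levels); positive values render a hypoechoic (darker) mass.
    background_level : float
        Mean background intensity (gray levels).
    speckle_shape : float
        Gamma shape parameter of the multiplicative speckle (mean 1);
        ``inf`` disables noise. Larger values mean less speckle.
    edge_sigma : float
        Gaussian blur (pixels) applied to the clean render, emulating the
        system point-spread function.
    k_int : int
        Number of gray levels (intensities span [0, k_int - 1]).
    seed : int
        Seed for boundary phases and speckle.
    """

    class_label: str = "benign"
    height: int = 128
    width: int = 128
    axes: tuple[float, float] = (36.0, 24.0)
    irregularity: float | None = None
    n_lobes: int = 7
    mass_contrast: float = 80.0
    background_level: float = 170.0
    speckle_shape: float = 100.0
    edge_sigma: float = 1.5
    k_int: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class label: {self.class_label!r}")
        if self.height < 32 or self.width < 32:
            raise ValueError("frame must be at least 32x32 pixels")
        amp = self.amplitude
        r_max = max(self.axes) * (1.0 + amp)
        if 2 * r_max >= min(self.height, self.width) - 4:
            raise ValueError("mass does not fit fully inside the frame")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive (or inf)")

    @property
    def amplitude(self) -> float:
        """Effective boundary-irregularity amplitude."""
        if self.irregularity is not None:
            return self.irregularity
        return IRREGULARITY[self.class_label]


def _render_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize the perturbed ellipse; returns a boolean mask."""
    a, b = spec.axes
    amp = spec.amplitude
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_lobes)
    weights = rng.uniform(0.5, 1.0, size=spec.n_lobes)
    # normalize the realized bump to unit peak so `amplitude` is exactly the
    # peak radial deviation as a fraction of the local radius
    grid = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    probe = np.zeros_like(grid)
    for k in range(spec.n_lobes):
        probe += weights[k] * np.sin((k + 2) * grid + phases[k])
    peak = np.max(np.abs(probe))
    weights = weights / (peak if peak > 0 else 1.0)

    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    dy, dx = yy - cy, xx - cx
    phi = np.arctan2(dy, dx)
    # radial boundary of the unperturbed ellipse at angle phi
    r_ell = (a * b) / np.sqrt((b * np.cos(phi)) ** 2 + (a * np.sin(phi)) ** 2)
    bump = np.zeros_like(phi)
    for k in range(spec.n_lobes):
        bump += weights[k] * np.sin((k + 2) * phi + phases[k])
    r_bound = r_ell * (1.0 + amp * bump)
    r_bound = np.maximum(r_bound, 1.0)
    return np.hypot(dy, dx) <= r_bound


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom.

    Returns
    -------
    image : uint8 ndarray of shape (height, width)
    mask : bool ndarray — ground-truth mass region (True inside the mass)

    The render is deterministic for a fixed spec (including seed).  Speckle
    is applied multiplicatively (pixel = clean x noise, noise mean 1) after
    the clean render, so ``speckle_shape=inf`` returns exactly the clean
    image.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _render_mask(spec, rng)

    clean = np.full((spec.height, spec.width), spec.background_level, dtype=float)
    clean[mask] -= spec.mass_contrast
    if spec.edge_sigma > 0:
        clean = ndimage.gaussian_filter(clean, spec.edge_sigma)

    if np.isinf(spec.speckle_shape):
        noisy = clean
    else:
        k = spec.speckle_shape
        noise = rng.gamma(shape=k, scale=1.0 / k, size=clean.shape)
        noisy = clean * noise

    img = np.clip(np.rint(noisy), 0, spec.k_int - 1).astype(np.uint8)
    return img, mask


def generate_dataset(
    n_per_class: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    jitter: bool = True,
) -> list[tuple[np.ndarray, np.ndarray, str]]:
    """Generate a balanced labeled dataset of ``3 * n_per_class`` phantoms.

    Per-item seeds are spawned reproducibly from the master seed.  With
    ``jitter`` enabled, ellipse axes are varied by up to +/-20% per item so
    that size alone carries no class signal.

    Returns a list of ``(image, mask, label)`` triples, grouped by class in
    the order benign, borderline, malignant.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3 * n_per_class)
    out: list[tuple[np.ndarray, np.ndarray, str]] = []
    i = 0
    for label in CLASS_NAMES:
        for _ in range(n_per_class):
            child = children[i]
            item_seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(item_seed + 1)
            axes = base.axes
            if jitter:
                f = rng.uniform(0.8, 1.2, size=2)
                axes = (base.axes[0] * f[0], base.axes[1] * f[1])
            spec = replace(
                base, class_label=label, irregularity=None, axes=axes, seed=item_seed
            )
            img, mask = generate_phantom(spec)
            out.append((img, mask, label))
            i += 1
    return out
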