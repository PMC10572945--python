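"""Geometric augmentation: named dihedral ops plus seeded random compositions.

Each input image expands into ``multiplier`` outputs (default 63, counting
the original).  The first six slots are fixed — the original plus the five
named operations (rotate 90 deg clockwise / counterclockwise, rotate 180 deg,
horizontal and vertical flips) — and the remaining slots are filled with
seeded random compositions of 90-degree rotations, flips, and small-angle
rotations, so the expansion factor is exact and reproducible.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

NAMED_OPS = ("rot90cw", "rot90ccw", "rot180", "flip_h", "flip_v")

#: small-angle set for the random fill rotations (degrees)
SMALL_ANGLES = (-15.0, -10.0, -5.0, 5.0, 10.0, 15.0)


def apply_named(img: np.ndarray, op: str) -> np.ndarray:
    """Apply one named op: an exact, lossless pixel permutation."""
    if op == "rot90cw":
        return np.rot90(img, k=-1)
    if op == "rot90ccw":
        return np.rot90(img, k=1)
    if op == "rot180":
        return np.rot90(img, k=2)
    if op == "flip_h":
        return np.fliplr(img)
    if op == "flip_v":
        return np.flipud(img)
    raise ValueError(f"unknown op name: {op!r}")


def _random_composition(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One seeded random composition used to fill augmentation slots 7+.

    Composes a 90-degree rotation multiple, optional flips, and optionally a
    small-angle rotation (nearest-neighbor, reflective padding) so the 8-bit
    intensity range stays closed.
    """
    out = np.rot90(img, k=int(rng.integers(0, 4)))
    if rng.random() < 0.5:
        out = np.fliplr(out)
    if rng.random() < 0.5:
        out = np.flipud(out)
    if rng.random() < 0.75:
        angle = SMALL_ANGLES[int(rng.integers(0, len(SMALL_ANGLES)))]
        out = ndimage.rotate(
            out, angle, reshape=False, order=0, mode="reflect", prefilter=False
        )
    return out


def augment_image(
    img: np.ndarray, multiplier: int = 63, seed: int = 0
) -> list[np.ndarray]:
    """Expand one image into exactly ``multiplier`` images.

    Slots 1-6 are {original, rot90cw, rot90ccw, rot180, flip_h, flip_v}
    when ``multiplier >= 6``; further slots are seeded random compositions.
    For smaller multipliers the fixed sequence is truncated.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    fixed = [img.copy()] + [apply_named(img, op) for op in NAMED_OPS]
    out = fixed[:multiplier]
    rng = np.random.default_rng(seed)
    while len(out) < multiplier:
        out.append(_random_composition(img, rng))
    return out


def dihedral_orbit(img: np.ndarray) -> list[np.ndarray]:
    """The 8-element symmetry orbit of a square image (dihedral group D4):
    four rotations, both axis flips, and both diagonal transpositions."""
    return [
        img.copy(),
        np.rot90(img, 1),
        np.rot90(img, 2),
        np.rot90(img, 3),
        np.fliplr(img),
        np.flipud(img),
        img.T.copy(),
        np.rot90(img, 2).T.copy(),
    ]


def augment_batch(
    images: list[np.ndarray], multiplier: int = 63, seed: int = 0
) -> list[tuple[int, np.ndarray]]:
    """Augment a batch; returns (source index, image) pairs.

    Output count is exactly ``multiplier * len(images)``; per-image seeds are
    derived from the master seed so batches are order-stable.
    """
    ss = np.random.SeedSequence(seed)
    out: list[tuple[int, np.ndarray]] = []
    for i, (img, child) in enumerate(zip(images, ss.spawn(len(images)))):
        sub = int(child.generate_state(1)[0] % (2**31))
        out.extend((i, aug) for aug in augment_image(img, multiplier, seed=sub))
    return out
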