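"""Hand-landmark sets and their skeleton rasterization.

A detected hand is represented by 21 articulated joints (wrist, then four
joints per digit) with normalized image coordinates.  For the skeleton
dataset variant the joints are rendered as filled discs and the 20
wrist-rooted bone segments as lines, white on black, which strips
appearance (skin tone, lighting, background) and keeps only pose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
from skimage.draw import disk as _sk_disk

__all__ = [
    "N_LANDMARKS",
    "HAND_BONES",
    "HandLandmarkSet",
    "LandmarkDetector",
    "StaticDetector",
    "line_pixels",
    "rasterize_landmarks",
]

N_LANDMARKS = 21

# Five digit chains rooted at the wrist (joint 0): thumb 1-4, index 5-8,
# middle 9-12, ring 13-16, pinky 17-20.  20 bones in total.
HAND_BONES: tuple[tuple[int, int], ...] = tuple(
    (0, base) for base in (1, 5, 9, 13, 17)
) + tuple(
    (base + i, base + i + 1) for base in (1, 5, 9, 13, 17) for i in range(3)
)


@dataclass(frozen=True)
class HandLandmarkSet:
    """21 joint coordinates of one hand.

    ``points`` has shape (21, 3): x, y in normalized image coordinates
    (x rightward, y downward) and an unconstrained depth z.  x and y are
    clamped to [0, 1] on construction.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 3):
            raise ValueError(
                f"a hand landmark set has exactly {N_LANDMARKS} (x, y, z) "
                f"points, got array of shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError("landmark coordinates must be finite")
        pts = pts.copy()
        pts[:, :2] = np.clip(pts[:, :2], 0.0, 1.0)
        object.__setattr__(self, "points", pts)

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]


@runtime_checkable
class LandmarkDetector(Protocol):
    """Anything that maps an image to a hand landmark set (or None on miss)."""

    def detect(self, image: np.ndarray) -> HandLandmarkSet | None: ...


class StaticDetector:
    """Detector stub returning a fixed landmark set for every image.

    ``landmarks=None`` makes it miss everything.  Useful in tests and as the
    simplest pluggable replacement for a real detector.
    """

    def __init__(self, landmarks: HandLandmarkSet | None):
        self.landmarks = landmarks

    def detect(self, image: np.ndarray) -> HandLandmarkSet | None:
        return self.landmarks


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def line_pixels(r0: int, c0: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-pixel line by DDA: n = max(|dr|, |dc|) steps, minor coordinate
    rounded half-up at each step.  Fully specified so an independent
    enumeration can reproduce the exact pixel set."""
    n = max(abs(r1 - r0), abs(c1 - c0))
    if n == 0:
        return np.array([r0]), np.array([c0])
    t = np.arange(n + 1) / n
    return _round_half_up(r0 + t * (r1 - r0)), _round_half_up(c0 + t * (c1 - c0))


def _draw_disc(canvas: np.ndarray, cy: int, cx: int, radius: float, value: float) -> None:
    rr, cc = _sk_disk((cy, cx), radius, shape=canvas.shape)
    canvas[rr, cc] = value


def rasterize_landmarks(
    lm: HandLandmarkSet | None,
    size: tuple[int, int],
    radius: float = 2.0,
    thickness: float = 1.0,
    vmax: float = 255.0,
) -> np.ndarray:
    """Render a hand skeleton as a white-on-black grayscale image.

    Joints become filled discs of the given radius (pixels at Euclidean
    distance < radius from the joint centre); bones become lines of the
    given thickness (thickness 1 is the single-pixel DDA line of
    :func:`line_pixels`, larger thicknesses stamp discs of radius
    thickness/2 along that line).  Joint
    coordinates map to 0-based pixel centres: x=0 -> column 0,
    x=1 -> column width-1.  Deterministic for fixed inputs; ``lm=None``
    (detector miss) yields an all-zero canvas.
    """
    h, w = size
    canvas = np.zeros((h, w), dtype=float)
    if lm is None:
        return canvas
    if not isinstance(lm, HandLandmarkSet):
        lm = HandLandmarkSet(np.asarray(lm, dtype=float))
    cols = _round_half_up(lm.points[:, 0] * (w - 1))
    rows = _round_half_up(lm.points[:, 1] * (h - 1))
    for a, b in HAND_BONES:
        rr, cc = line_pixels(rows[a], cols[a], rows[b], cols[b])
        if thickness <= 1.0:
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            canvas[rr[keep], cc[keep]] = vmax
        else:
            for r, c in zip(rr, cc):
                _draw_disc(canvas, r, c, thickness / 2.0, vmax)
    for r, c in zip(rows, cols):
        _draw_disc(canvas, r, c, radius, vmax)
    return canvas
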