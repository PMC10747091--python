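"""Seeded synthetic fixtures: dark scenes, gesture glyphs, hand landmarks.

Everything the pipeline needs can be generated deterministically, with no
downloads:

* :func:`gen_dark_scene` — an underexposed colour scene whose histogram
  mass sits near intensities 0-30, with embedded mid-gray shapes that the
  retinal enhancement should make recoverable (the regime where contrast
  self-regulation earns its keep);
* :func:`gen_gesture_dataset` — a 29-class stand-in for a static
  sign-alphabet image set: each class is a distinct deterministic stroke
  glyph at 200x200, jittered in position/rotation/brightness per sample.
  The ``NOTHING`` class is a near-blank dark frame (no hand in view);
* :func:`gen_landmarks` — a plausible 21-joint hand pose, jittered around a
  fixed open-hand template;
* :func:`darken` — dark-corruption of a bright image (intensity ceiling
  ~30 plus sensor noise, 8-bit quantized), used to compare training on raw
  versus enhanced inputs;
* :class:`SyntheticLandmarkDetector` — a deterministic detector stub that
  gates on peak brightness (so blank frames yield no hand) and derives a
  hand pose from the bright-pixel moments of the image.

All generators are pure functions of their seed via
``numpy.random.default_rng`` (PCG64); fixed seeds give byte-identical
outputs across machines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import disk as _sk_disk
from skimage.draw import line as _sk_line

from .datasets import ASL_CLASSES
from .landmarks import HandLandmarkSet

__all__ = [
    "FixtureSpec",
    "gen_dark_scene",
    "gen_landmarks",
    "gen_gesture_image",
    "gen_gesture_arrays",
    "gen_gesture_dataset",
    "darken",
    "SyntheticLandmarkDetector",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic generators.

    ``dark_bias`` is the minimum fraction of pixels a dark scene places in
    the intensity band [0, 30].
    """

    seed: int = 0
    n_classes: int = 29
    samples_per_class: int = 20
    image_size: tuple[int, int] = (200, 200)
    dark_bias: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.dark_bias <= 1.0):
            raise ValueError("dark_bias must lie in [0, 1]")
        if not (1 <= self.n_classes <= len(ASL_CLASSES)):
            raise ValueError(f"n_classes must lie in [1, {len(ASL_CLASSES)}]")

    @property
    def classes(self) -> tuple[str, ...]:
        return ASL_CLASSES[: self.n_classes]


# -- dark scenes ----------------------------------------------------------


def gen_dark_scene(spec: FixtureSpec) -> np.ndarray:
    """Underexposed RGB scene (uint8) with >= ``dark_bias`` of its pixels in
    [0, 30] and a few mid-gray discs occupying the remaining budget."""
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    background = np.clip(rng.exponential(8.0, size=(h, w)), 0, 28)
    canvas = background.copy()
    budget = int((1.0 - spec.dark_bias) * h * w)
    bright = np.zeros((h, w), dtype=bool)
    for _ in range(4):
        if budget <= 0:
            break
        radius = max(2.0, np.sqrt(budget / (4 * np.pi)) * rng.uniform(0.6, 1.0))
        cy = rng.uniform(radius, h - radius)
        cx = rng.uniform(radius, w - radius)
        rr, cc = _sk_disk((cy, cx), radius, shape=(h, w))
        new = ~bright[rr, cc]
        if new.sum() > budget:
            continue
        canvas[rr, cc] = rng.uniform(60.0, 120.0)
        bright[rr, cc] = True
        budget -= int(new.sum())
    return np.repeat(np.floor(canvas + 0.5)[..., None], 3, axis=2).astype(np.uint8)


# -- hand landmarks -------------------------------------------------------

# Open-hand template in normalized coordinates: wrist at bottom centre,
# thumb leaning left, four fingers fanning upward.
_HAND_TEMPLATE = np.array([
    (0.50, 0.88),                                            # wrist
    (0.38, 0.78), (0.30, 0.68), (0.24, 0.60), (0.20, 0.53),  # thumb
    (0.42, 0.62), (0.40, 0.48), (0.39, 0.38), (0.38, 0.30),  # index
    (0.50, 0.60), (0.50, 0.44), (0.50, 0.33), (0.50, 0.24),  # middle
    (0.58, 0.62), (0.59, 0.47), (0.60, 0.37), (0.61, 0.29),  # ring
    (0.66, 0.66), (0.68, 0.55), (0.70, 0.47), (0.71, 0.40),  # pinky
])


def gen_landmarks(seed: int = 0) -> HandLandmarkSet:
    """A jittered open-hand pose: 21 points on the standard topology."""
    rng = np.random.default_rng(seed)
    xy = _HAND_TEMPLATE + rng.normal(0.0, 0.02, _HAND_TEMPLATE.shape)
    xy += rng.uniform(-0.05, 0.05, size=(1, 2))
    z = rng.normal(0.0, 0.05, size=(21, 1))
    return HandLandmarkSet(np.hstack([xy, z]))


# -- gesture glyphs -------------------------------------------------------


def _stamp_line(canvas, r0, c0, r1, c1, half_width, value) -> None:
    rr, cc = _sk_line(r0, c0, r1, c1)
    for r, c in zip(rr, cc):
        dd, cc2 = _sk_disk((r, c), half_width, shape=canvas.shape)
        canvas[dd, cc2] = value


def _class_geometry(spec: FixtureSpec, class_idx: int):
    """Per-class stroke/disc layout, independent of the sample index."""
    rng = np.random.default_rng([spec.seed, 7, class_idx])
    h, w = spec.image_size
    m = 0.18  # keep glyphs away from the border so jitter cannot clip them
    strokes = rng.uniform([m * h, m * w], [(1 - m) * h, (1 - m) * w], size=(4, 2, 2))
    discs = rng.uniform([0.25 * h, 0.25 * w], [0.75 * h, 0.75 * w], size=(2, 2))
    disc_radii = rng.uniform(0.04 * h, 0.08 * h, size=2)
    return strokes, discs, disc_radii


def gen_gesture_image(spec: FixtureSpec, class_idx: int, sample_idx: int) -> np.ndarray:
    """One 8-bit grayscale glyph sample (class-specific geometry, per-sample
    jitter in position, rotation and brightness)."""
    h, w = spec.image_size
    rng = np.random.default_rng([spec.seed, 11, class_idx, sample_idx])
    canvas = np.clip(rng.normal(10.0, 3.0, size=(h, w)), 0, 25)
    label = spec.classes[class_idx]
    if label != "NOTHING":
        strokes, discs, disc_radii = _class_geometry(spec, class_idx)
        shift = rng.uniform(-0.04 * h, 0.04 * h, size=2)
        angle = rng.uniform(-0.12, 0.12)
        value = rng.uniform(200.0, 245.0)
        centre = np.array([h / 2.0, w / 2.0])
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])

        def _tf(p):
            return (p - centre) @ rot.T + centre + shift

        for (p0, p1) in strokes:
            (r0, c0), (r1, c1) = _tf(p0), _tf(p1)
            _stamp_line(canvas, int(round(r0)), int(round(c0)),
                        int(round(r1)), int(round(c1)),
                        half_width=0.018 * h, value=value)
        for centre_pt, radius in zip(discs, disc_radii):
            r, c = _tf(centre_pt)
            rr, cc = _sk_disk((r, c), radius, shape=(h, w))
            canvas[rr, cc] = value
    return np.floor(canvas + 0.5).astype(np.uint8)


def gen_gesture_arrays(spec: FixtureSpec) -> tuple[list[np.ndarray], list[str]]:
    """All samples as in-memory arrays with their class labels."""
    images, labels = [], []
    for k, label in enumerate(spec.classes):
        for i in range(spec.samples_per_class):
            images.append(gen_gesture_image(spec, k, i))
            labels.append(label)
    return images, labels


def gen_gesture_dataset(spec: FixtureSpec, out_dir) -> Path:
    """Write the glyph dataset as a ``out/<CLASS>/<CLASS>_<i>.png`` tree."""
    out_dir = Path(out_dir)
    for k, label in enumerate(spec.classes):
        cdir = out_dir / label
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(spec.samples_per_class):
            iio.imwrite(cdir / f"{label}_{i:04d}.png",
                        gen_gesture_image(spec, k, i))
    return out_dir


def darken(image: np.ndarray, seed: int = 0, ceiling: float = 30.0,
           noise_sigma: float = 2.0) -> np.ndarray:
    """Dark-corrupt an 8-bit image: compress intensities into [0, ceiling],
    add Gaussian sensor noise and requantize.  Emulates severe underexposure
    of the same scene."""
    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=float) * (ceiling / 255.0)
    out += rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


# -- detector stub --------------------------------------------------------


class SyntheticLandmarkDetector:
    """Deterministic landmark-detector stand-in (synthetic; not a real
    hand detector).

    Declares a miss when no structure stands out from the background: the
    peak brightness must exceed ``min_peak`` and rise at least
    ``min_contrast`` above the median (a blank frame — dark or globally
    brightened by the enhancement — fails the contrast gate).  Otherwise it
    derives a hand pose from the bright-pixel moments of the image —
    centroid, extent — so that visually similar images yield similar
    skeletons, and seeds the residual jitter from those quantized moments,
    keeping detection a pure function of the image.
    """

    def __init__(self, min_peak: float = 60.0, min_contrast: float = 60.0,
                 seed: int = 0):
        self.min_peak = min_peak
        self.min_contrast = min_contrast
        self.seed = seed

    def detect(self, image: np.ndarray) -> HandLandmarkSet | None:
        gray = np.asarray(image, dtype=float)
        if gray.ndim == 3:
            gray = gray.mean(axis=2)
        peak = float(gray.max(initial=0.0))
        if peak < self.min_peak or peak - float(np.median(gray)) < self.min_contrast:
            return None
        h, w = gray.shape
        mask = gray > 0.5 * peak
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean() / h, xs.mean() / w
        span = max(np.ptp(ys) / h, np.ptp(xs) / w, 0.2)
        key = [self.seed, int(cy * 32), int(cx * 32), int(span * 32),
               int(mask.sum() % 1024)]
        rng = np.random.default_rng(key)
        xy = _HAND_TEMPLATE - _HAND_TEMPLATE.mean(axis=0)
        xy = xy * span + np.array([cx, cy])
        xy = xy + rng.normal(0.0, 0.01, xy.shape)
        z = rng.normal(0.0, 0.05, size=(21, 1))
        return HandLandmarkSet(np.hstack([np.clip(xy, 0.0, 1.0), z]))
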