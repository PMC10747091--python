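"""Dataset variants for the gesture classifier.

From one directory-per-class image tree, three training sets are derived:

* **V1** — raw images, grayscaled and resized to the classifier's 50x50 input;
* **V2** — images passed through the retinal enhancement
  (:func:`retinasign.adaptation.enhance`) first;
* **V3** — enhanced images run through a hand-landmark detector and replaced
  by their white-on-black skeleton rendering; images where the detector
  finds no hand are dropped (so a "NOTHING" class typically disappears).

Grayscale conversion is the channel mean; resizing is area-averaging
(Pillow BOX).  Skeletons are rendered at the source resolution (disc radius
and line thickness scale with it) and then resized.  Building is
deterministic given a deterministic detector.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

from .adaptation import AdaptationParams, enhance, to_uint8
from .landmarks import LandmarkDetector, rasterize_landmarks
from .retina import PhotoreceptorParams

__all__ = [
    "ASL_CLASSES",
    "DatasetVariant",
    "resize_area",
    "build_variant",
    "build_variant_from_arrays",
    "save_variant",
    "load_class_tree",
]

logger = logging.getLogger(__name__)

#: The 29 static-gesture classes: the letters A-Z plus three control signs.
ASL_CLASSES: tuple[str, ...] = tuple(string.ascii_uppercase) + (
    "SPACE", "DELETE", "NOTHING",
)

VARIANT_TAGS = ("V1", "V2", "V3")


@dataclass
class DatasetVariant:
    """One built dataset: 50x50 grayscale images with labels.

    ``dropped`` lists identifiers of images removed because the landmark
    detector returned no hand (V3 only).
    """

    tag: str
    images: list[np.ndarray] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label in self.labels:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.stack(self.images), np.asarray(self.labels)


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    return image.mean(axis=2) if image.ndim == 3 else image


def resize_area(image: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Area-averaging resize of a 2-D float image to (height, width)."""
    h, w = size
    pil = Image.fromarray(np.asarray(image, dtype=np.float32), mode="F")
    return np.asarray(pil.resize((w, h), Image.Resampling.BOX), dtype=float)


def _process_one(
    image: np.ndarray,
    tag: str,
    detector: LandmarkDetector | None,
    ph: PhotoreceptorParams,
    ad: AdaptationParams,
    size: tuple[int, int],
    radius: float,
    thickness: float,
) -> np.ndarray | None:
    """One image through the variant pipeline; None means dropped (V3 miss)."""
    if tag == "V1":
        return resize_area(_to_gray(image), size)
    enhanced = enhance(np.asarray(image, dtype=float), ph, ad)
    if tag == "V2":
        return resize_area(_to_gray(enhanced), size)
    # V3: detector on the enhanced image, skeleton at source resolution
    if detector is None:
        raise ValueError("building V3 requires a landmark detector")
    lm = detector.detect(enhanced)
    if lm is None:
        return None
    src_shape = enhanced.shape[:2]
    scale = src_shape[0] / 200.0
    skeleton = rasterize_landmarks(
        lm, src_shape, radius=max(radius * scale, 1.0),
        thickness=max(thickness * scale, 1.0), vmax=ad.vmax,
    )
    return resize_area(skeleton, size)


def build_variant_from_arrays(
    images,
    labels,
    tag: str,
    detector: LandmarkDetector | None = None,
    ph: PhotoreceptorParams | None = None,
    ad: AdaptationParams | None = None,
    size: tuple[int, int] = (50, 50),
    radius: float = 2.0,
    thickness: float = 1.0,
    ids=None,
) -> DatasetVariant:
    """Build a variant from in-memory images (see module docstring)."""
    if tag not in VARIANT_TAGS:
        raise ValueError(f"unknown variant tag {tag!r}; expected one of {VARIANT_TAGS}")
    ph = ph or PhotoreceptorParams()
    ad = ad or AdaptationParams()
    if ids is None:
        ids = [f"{label}/{i}" for i, label in enumerate(labels)]
    variant = DatasetVariant(tag=tag)
    for image, label, ident in zip(images, labels, ids):
        out = _process_one(image, tag, detector, ph, ad, size, radius, thickness)
        if out is None:
            variant.dropped.append(ident)
        else:
            variant.images.append(out)
            variant.labels.append(label)
    if variant.dropped:
        logger.info("%s: dropped %d image(s) with no detected hand",
                    tag, len(variant.dropped))
    empty = set(labels) - set(variant.labels)
    if empty:
        logger.warning("%s: classes emptied by filtering: %s", tag, sorted(empty))
    return variant


def load_class_tree(root) -> tuple[list[np.ndarray], list[str], list[str]]:
    """Read a ``root/<CLASS>/<image>.png|jpg`` tree; unreadable files are
    logged and skipped."""
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class directories under {root}")
    images, labels, paths = [], [], []
    for cdir in class_dirs:
        for f in sorted(cdir.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            try:
                images.append(np.asarray(iio.imread(f), dtype=float))
            except Exception:  # unreadable image: skip, keep going
                logger.warning("skipping unreadable image %s", f)
                continue
            labels.append(cdir.name)
            paths.append(str(f.relative_to(root)))
    if not images:
        raise FileNotFoundError(f"no readable images under {root}")
    return images, labels, paths


def build_variant(
    src_root,
    tag: str,
    detector: LandmarkDetector | None = None,
    ph: PhotoreceptorParams | None = None,
    ad: AdaptationParams | None = None,
    **kwargs,
) -> DatasetVariant:
    """Build a variant from a directory-per-class tree on disk."""
    images, labels, paths = load_class_tree(src_root)
    return build_variant_from_arrays(
        images, labels, tag, detector=detector, ph=ph, ad=ad, ids=paths, **kwargs
    )


def save_variant(variant: DatasetVariant, out_root, vmax: float = 255.0) -> Path:
    """Write the variant as a mirrored class tree plus a manifest CSV.

    Returns the manifest path.  Images are quantized to 8-bit PNG.
    """
    out_root = Path(out_root)
    rows = []
    counters: dict[str, int] = {}
    for image, label in zip(variant.images, variant.labels):
        counters[label] = counters.get(label, 0) + 1
        cdir = out_root / label
        cdir.mkdir(parents=True, exist_ok=True)
        rel = f"{label}/{label}_{counters[label]:04d}.png"
        iio.imwrite(out_root / rel, to_uint8(image, vmax))
        rows.append({"path": rel, "class": label, "variant": variant.tag,
                     "status": "kept"})
    for ident in variant.dropped:
        rows.append({"path": ident, "class": ident.split("/")[0],
                     "variant": variant.tag, "status": "dropped"})
    manifest = out_root / "manifest.csv"
    out_root.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
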