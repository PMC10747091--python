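"""Michaelis-Menten light adaptation (contrast self-regulation).

Photoreceptors adjust their sensitivity to the light level in their
vicinity.  Per pixel, the adapted response is

    C(m, n) = R(m, n) * (Vmax + R0(m, n)) / (R(m, n) + R0(m, n))

with the compression map

    R0(m, n) = V0 * L(m, n) + Vmax * (1 - V0)

where R is the raw intensity, L is the local-luminance map (the
photoreceptor-filtered image from :mod:`retinasign.retina`), V0 in [0, 1]
controls how strongly local luminance shifts the operating point and Vmax is
the maximum representable intensity (255 for 8-bit).  The map amplifies dark
regions while leaving bright ones nearly unchanged — dark pixels surrounded
by darkness see a small R0 and hence a large gain (Vmax + R0)/(R + R0),
while C(Vmax) = Vmax whenever R0 = Vmax.  Applied to a dark-biased scene it
redistributes a histogram concentrated near 0-30 into a more homogeneous
one, which is what downstream detection and classification benefit from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .retina import PhotoreceptorParams, apply_photoreceptor_filter

__all__ = [
    "AdaptationParams",
    "compression_parameter",
    "adapt",
    "luminance",
    "enhance",
    "response_curve",
    "RetinalEnhancer",
]


@dataclass(frozen=True)
class AdaptationParams:
    """Light-regulation constants: compression parameter ``v0`` in [0, 1]
    and maximum pixel value ``vmax`` (> 0, 255 for 8-bit images)."""

    v0: float = 0.7
    vmax: float = 255.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.v0 <= 1.0):
            raise ValueError(f"v0 must lie in [0, 1], got {self.v0!r}")
        if not (np.isfinite(self.vmax) and self.vmax > 0):
            raise ValueError(f"vmax must be positive and finite, got {self.vmax!r}")


def compression_parameter(
    L: np.ndarray, params: AdaptationParams | None = None
) -> np.ndarray:
    """Compression map R0 = V0 * L + Vmax * (1 - V0), elementwise.

    At V0 = 0 the map is constant Vmax (no local adaptation); at V0 = 1 it
    equals the local luminance exactly.
    """
    if params is None:
        params = AdaptationParams()
    L = np.asarray(L, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("local luminance contains non-finite values")
    return params.v0 * L + params.vmax * (1.0 - params.v0)


def adapt(
    R: np.ndarray,
    R0: np.ndarray,
    params: AdaptationParams | None = None,
) -> np.ndarray:
    """Adapted response C = R * (Vmax + R0) / (R + R0), clipped to [0, Vmax].

    Pixels where R + R0 = 0 are assigned C = 0, the continuous limit from
    R -> 0.  Negative raw intensities are rejected.
    """
    if params is None:
        params = AdaptationParams()
    R = np.asarray(R, dtype=float)
    R0 = np.asarray(R0, dtype=float)
    if R.shape != R0.shape:
        raise ValueError(f"shape mismatch: R {R.shape} vs R0 {R0.shape}")
    if np.any(R < 0):
        raise ValueError("raw intensities must be non-negative")
    denom = R + R0
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom == 0.0, 0.0, R * (params.vmax + R0) / np.where(denom == 0.0, 1.0, denom))
    return np.clip(C, 0.0, params.vmax)


def luminance(image: np.ndarray) -> np.ndarray:
    """Luminance channel: the image itself if 2-D, the channel mean if H x W x C."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3:
        return image.mean(axis=2)
    raise ValueError(f"expected 2-D or 3-D image, got ndim={image.ndim}")


def enhance(
    image: np.ndarray,
    ph: PhotoreceptorParams | None = None,
    ad: AdaptationParams | None = None,
    per_channel: bool = False,
) -> np.ndarray:
    """Full contrast self-regulation: OPL filter then light adaptation.

    The local-luminance map L is the photoreceptor-filtered luminance of the
    input (one shared map for all colour channels, preserving hue relations;
    ``per_channel=True`` computes an independent L per channel instead).
    Output is floating point, same shape as the input, clipped to
    [0, vmax]; quantization to integers happens only on file write.
    """
    if ph is None:
        ph = PhotoreceptorParams()
    if ad is None:
        ad = AdaptationParams()
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        L = apply_photoreceptor_filter(image, ph)
        return adapt(image, compression_parameter(L, ad), ad)
    if image.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D image, got ndim={image.ndim}")
    if per_channel:
        channels = [
            adapt(
                image[..., c],
                compression_parameter(apply_photoreceptor_filter(image[..., c], ph), ad),
                ad,
            )
            for c in range(image.shape[2])
        ]
    else:
        L = apply_photoreceptor_filter(luminance(image), ph)
        R0 = compression_parameter(L, ad)
        channels = [adapt(image[..., c], R0, ad) for c in range(image.shape[2])]
    return np.stack(channels, axis=2)


def response_curve(
    params: AdaptationParams | None = None,
    L_level: float = 0.0,
    n_points: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated response C(R) for R in [0, Vmax] under a uniform vicinity.

    Returns ``(R, C)`` arrays; used for plotting the family of curves over
    V0 and for monotonicity checks.  The curve is strictly increasing in R
    and lies on or above the identity whenever R0 <= Vmax.
    """
    if params is None:
        params = AdaptationParams()
    R = np.linspace(0.0, params.vmax, n_points)
    R0 = compression_parameter(np.full_like(R, float(L_level)), params)
    return R, adapt(R, R0, params)


def to_uint8(image: np.ndarray, vmax: float = 255.0) -> np.ndarray:
    """Quantize a float image on [0, vmax] to uint8 (round half up)."""
    scaled = np.clip(np.asarray(image, dtype=float), 0.0, vmax) * (255.0 / vmax)
    return np.floor(scaled + 0.5).astype(np.uint8)


class RetinalEnhancer(TransformerMixin, BaseEstimator):
    """Transformer applying the full retinal enhancement to image arrays.

    Parameters mirror the filter and adaptation constants; defaults are the
    heuristically tuned values of the reference configuration (beta_ph=0,
    alpha_ph=1, tau_ph=1, v0=0.7, vmax=255).  ``transform`` accepts a single
    image (2-D or H x W x 3) or a stack with a leading batch axis.
    """

    def __init__(self, beta_ph: float = 0.0, alpha_ph: float = 1.0,
                 tau_ph: float = 1.0, v0: float = 0.7, vmax: float = 255.0,
                 per_channel: bool = False):
        self.beta_ph = beta_ph
        self.alpha_ph = alpha_ph
        self.tau_ph = tau_ph
        self.v0 = v0
        self.vmax = vmax
        self.per_channel = per_channel

    def _param_objects(self) -> tuple[PhotoreceptorParams, AdaptationParams]:
        return (
            PhotoreceptorParams(self.beta_ph, self.alpha_ph, self.tau_ph),
            AdaptationParams(self.v0, self.vmax),
        )

    def fit(self, X, y=None):
        self.n_images_seen_ = 1 if np.asarray(X).ndim <= 3 else len(X)
        return self

    def transform(self, X):
        ph, ad = self._param_objects()
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 or (X.ndim == 3 and X.shape[-1] in (3, 4)):
            return enhance(X, ph, ad, per_channel=self.per_channel)
        return np.stack([enhance(img, ph, ad, per_channel=self.per_channel) for img in X])
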