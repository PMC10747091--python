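"""Photoreceptor (outer-plexiform-layer) low-pass filtering.

The first stage of the retina is modelled as a spatio-temporal low-pass
filter acting on the incoming light image.  In the frequency domain the
photoreceptor transfer function is

    F_ph(fx, fy, ft) = 1 / (1 + beta_ph
                              + 2 * alpha_ph * (2 - cos 2*pi*fx - cos 2*pi*fy)
                              + j * 2*pi * tau_ph * ft)

where ``beta_ph`` is a gain-control constant (DC gain is 1/(1+beta_ph)),
``alpha_ph`` sets the spatial cut-off, and ``tau_ph`` damps temporal noise
across frames.  The separable-cosine spatial term is the discrete-Laplacian
coupling standard in OPL retina models; it makes the filter exactly
equivalent to a circular spatial convolution, which the test-suite exploits
as an oracle.

Spatial frequencies are in cycles/pixel on [-0.5, 0.5), laid out in standard
(unshifted) DFT order so that DC sits at index (0, 0); no ``fftshift`` is
applied anywhere in this module.

The filtered image is the *local luminance* map L(m, n) consumed by
:mod:`retinasign.adaptation`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PhotoreceptorParams",
    "opl_frequency_response",
    "apply_photoreceptor_filter",
    "temporal_filter_step",
    "PhotoreceptorFilter",
]


@dataclass(frozen=True)
class PhotoreceptorParams:
    """Constants of the photoreceptor filter F_ph.

    Attributes
    ----------
    beta_ph : float
        Dimensionless gain-control constant, >= 0.  DC gain is
        ``1 / (1 + beta_ph)``.
    alpha_ph : float
        Dimensionless spatial filtering constant, >= 0; larger values push
        the spatial cut-off towards lower frequencies.
    tau_ph : float
        Temporal filtering constant in frame-time units, >= 0.
    """

    beta_ph: float = 0.0
    alpha_ph: float = 1.0
    tau_ph: float = 1.0

    def __post_init__(self) -> None:
        for name in ("beta_ph", "alpha_ph", "tau_ph"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"{name} must be finite and non-negative, got {value!r}"
                )


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={image.ndim}")
    if image.size == 0:
        raise ValueError("image is empty")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def opl_frequency_response(
    shape: tuple[int, int],
    params: PhotoreceptorParams | None = None,
    ft: float = 0.0,
) -> np.ndarray:
    """Complex gain grid of F_ph for an image of the given shape.

    Parameters
    ----------
    shape : (height, width)
        Size of the DFT grid.
    params : PhotoreceptorParams
        Filter constants; defaults if None.
    ft : float
        Scalar temporal frequency; 0 for static images, in which case the
        response is real and Hermitian-symmetric.

    Returns
    -------
    ndarray of complex, shape ``shape``
        Gains in unshifted DFT order (DC at [0, 0]).
    """
    if params is None:
        params = PhotoreceptorParams()
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError(f"shape must be at least 1x1, got {shape}")
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    spatial = 2.0 * params.alpha_ph * (
        2.0 - np.cos(2.0 * np.pi * fx) - np.cos(2.0 * np.pi * fy)
    )
    denom = 1.0 + params.beta_ph + spatial + 1j * 2.0 * np.pi * params.tau_ph * ft
    return 1.0 / denom


def apply_photoreceptor_filter(
    image: np.ndarray, params: PhotoreceptorParams | None = None
) -> np.ndarray:
    """Filter a grayscale image through F_ph in the frequency domain.

    The image is transformed with the 2-D DFT, multiplied by the filter
    response and transformed back; boundary handling is therefore periodic.
    The real part of the inverse transform is returned (the imaginary
    residue is numerical noise since the response is Hermitian at ft=0).
    The output is the local-luminance map L and is *not* clipped: it may
    exceed the input range slightly near sharp edges.
    """
    image = _validate_image(image)
    if params is None:
        params = PhotoreceptorParams()
    response = opl_frequency_response(image.shape, params, ft=0.0)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * response))


def temporal_filter_step(
    current: np.ndarray,
    previous_output: np.ndarray | None = None,
    params: PhotoreceptorParams | None = None,
) -> np.ndarray:
    """One step of the temporal branch of F_ph on an image sequence.

    Discretizes the first-order low-pass 1/(1 + j*2*pi*tau_ph*ft) as the
    exponential-smoothing recursion

        y[t] = (x[t] + tau_ph * y[t-1]) / (1 + tau_ph)

    which has unity DC gain.  With no previous output the filter is
    initialized at the current frame and returns it unchanged.
    """
    current = _validate_image(current)
    if params is None:
        params = PhotoreceptorParams()
    if previous_output is None:
        return current.copy()
    previous_output = np.asarray(previous_output, dtype=float)
    if previous_output.shape != current.shape:
        raise ValueError(
            f"shape mismatch: current {current.shape} vs "
            f"previous {previous_output.shape}"
        )
    tau = params.tau_ph
    return (current + tau * previous_output) / (1.0 + tau)


class PhotoreceptorFilter(TransformerMixin, BaseEstimator):
    """Stateless transformer applying the OPL low-pass filter per image.

    Accepts a single 2-D image or a stack of shape ``(n_images, h, w)``.
    ``fit`` only records the image shape; ``transform`` returns arrays of
    the same shape as the input.
    """

    def __init__(self, beta_ph: float = 0.0, alpha_ph: float = 1.0,
                 tau_ph: float = 1.0):
        self.beta_ph = beta_ph
        self.alpha_ph = alpha_ph
        self.tau_ph = tau_ph

    def _params(self) -> PhotoreceptorParams:
        return PhotoreceptorParams(self.beta_ph, self.alpha_ph, self.tau_ph)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.image_shape_ = X.shape[-2:]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        params = self._params()
        if X.ndim == 2:
            return apply_photoreceptor_filter(X, params)
        if X.ndim == 3:
            return np.stack([apply_photoreceptor_filter(img, params) for img in X])
        raise ValueError(f"expected 2-D image or 3-D stack, got ndim={X.ndim}")
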