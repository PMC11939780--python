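"""Frequency-domain and filtering primitives.

All functions operate on ``H x W x C`` arrays (spatial maps are real,
spectra are complex) and are pure: no parameters, no state.  The FFT
convention is orthonormal (``norm="ortho"``) in both directions, so
Parseval's identity holds symmetrically and a gate applied in the
frequency domain has an energy interpretation.  2-D transforms are taken
per channel over the two spatial axes.

Filtering primitives (Sobel gradient magnitude, Gaussian smoothing) use
reflect padding to avoid border ringing on small feature maps.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve as _nd_convolve

__all__ = [
    "forward_fft",
    "inverse_fft",
    "split_amplitude_phase",
    "sobel_edge_map",
    "min_max_norm",
    "gaussian_smooth",
    "gaussian_kernel",
    "SOBEL_GX",
    "SOBEL_GY",
]

#: Standard 3x3 Sobel kernel responding to horizontal gradients (d/dx,
#: where x is the column index).
SOBEL_GX = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])

#: Transpose of :data:`SOBEL_GX`; responds to vertical gradients.
SOBEL_GY = SOBEL_GX.T.copy()


def _require_hwc(x: np.ndarray, name: str = "input") -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 3:
        raise ValueError(f"{name} must be a 3-D H x W x C array, got shape {x.shape}")
    if x.shape[0] < 1 or x.shape[1] < 1 or x.shape[2] < 1:
        raise ValueError(f"{name} must have positive dimensions, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def forward_fft(x: np.ndarray) -> np.ndarray:
    """Per-channel orthonormal 2-D DFT of a real spatial feature map.

    Parameters
    ----------
    x
        Real ``H x W x C`` array; all entries must be finite.

    Returns
    -------
    numpy.ndarray
        Complex ``H x W x C`` spectrum.  Under the orthonormal convention
        the total squared magnitude equals that of ``x`` (Parseval).
    """
    x = _require_hwc(x, "spatial map")
    return np.fft.fft2(x, axes=(0, 1), norm="ortho")


def inverse_fft(X: np.ndarray, return_imag_fraction: bool = False):
    """Per-channel orthonormal inverse 2-D DFT, returning the real part.

    Refined spectra are generally no longer Hermitian-symmetric, so the
    exact inverse transform has a nonzero imaginary component.  The real
    part is returned; with ``return_imag_fraction=True`` the fraction of
    the output energy carried by the discarded imaginary part is reported
    alongside as a diagnostic.
    """
    X = _require_hwc(X, "spectrum")
    z = np.fft.ifft2(X, axes=(0, 1), norm="ortho")
    real = np.ascontiguousarray(z.real)
    if not return_imag_fraction:
        return real
    total = float(np.sum(z.real**2) + np.sum(z.imag**2))
    frac = float(np.sum(z.imag**2) / total) if total > 0 else 0.0
    return real, frac


def split_amplitude_phase(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a complex spectrum into (amplitude, phase).

    Amplitude is the per-entry modulus (non-negative); phase is the
    argument in ``(-pi, pi]``, with the phase of an exactly-zero entry
    defined as 0 so that ``amplitude * exp(i*phase)`` reconstructs the
    spectrum exactly.
    """
    X = _require_hwc(X, "spectrum")
    amplitude = np.abs(X)
    phase = np.arctan2(X.imag, X.real)  # atan2(0, 0) == 0 by definition
    return amplitude, phase


def sobel_edge_map(x: np.ndarray) -> np.ndarray:
    """Per-channel Sobel gradient magnitude ``sqrt(Gx^2 + Gy^2)``.

    Uses the standard 3x3 kernels with reflect padding.  Input must have
    spatial extent of at least 3 in both directions.
    """
    x = _require_hwc(x, "input")
    if x.shape[0] < 3 or x.shape[1] < 3:
        raise ValueError(
            f"sobel_edge_map needs spatial dims >= 3, got {x.shape[:2]}"
        )
    out = np.empty_like(x, dtype=np.float64)
    for c in range(x.shape[2]):
        gx = _nd_convolve(x[:, :, c].astype(np.float64), SOBEL_GX, mode="mirror")
        gy = _nd_convolve(x[:, :, c].astype(np.float64), SOBEL_GY, mode="mirror")
        out[:, :, c] = np.hypot(gx, gy)
    return out


def min_max_norm(x: np.ndarray) -> np.ndarray:
    """Per-channel min-max normalization to [0, 1].

    A spatially constant channel maps to all zeros (a featureless channel
    should receive zero edge attention) rather than NaN.
    """
    x = _require_hwc(x, "input")
    x = x.astype(np.float64, copy=False)
    lo = x.min(axis=(0, 1), keepdims=True)
    hi = x.max(axis=(0, 1), keepdims=True)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (x - lo) / safe
    return np.where(span > 0, out, 0.0)


def gaussian_kernel(sigma: float, ksize: int) -> np.ndarray:
    """Isotropic 2-D Gaussian kernel of odd size ``ksize``, normalized to sum 1."""
    if ksize % 2 == 0 or ksize < 1:
        raise ValueError(f"ksize must be a positive odd integer, got {ksize}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    r = ksize // 2
    ax = np.arange(-r, r + 1, dtype=np.float64)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_smooth(x: np.ndarray, sigma: float = 1.0, ksize: int = 3) -> np.ndarray:
    """Per-channel Gaussian convolution with reflect padding.

    The kernel sums to one, so a constant map is left unchanged.
    """
    x = _require_hwc(x, "input")
    k = gaussian_kernel(sigma, ksize)
    out = np.empty_like(x, dtype=np.float64)
    for c in range(x.shape[2]):
        out[:, :, c] = _nd_convolve(x[:, :, c].astype(np.float64), k, mode="mirror")
    return out
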