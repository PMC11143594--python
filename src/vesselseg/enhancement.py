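"""Intensity calibration and unsharp-style vessel enhancement.

Calibration windows the raw intensities around the vessel statistics: with
``mu``/``sigma`` the mean and (population) standard deviation of intensities
under the vessel mask, values are clipped to ``[mu - 3 sigma, mu + 3 sigma]``
and mapped affinely to display gray levels::

    f'(x, y) = alpha * (clip(f) - mu) / sigma + c

The defaults ``alpha = 255/6`` and ``c = 127.5`` map the clip window exactly
onto [0, 255].  Enhancement then subtracts a scaled low-pass copy::

    f'(x, y) = f(x, y) - lam * (f ⊛ k)(x, y)

applied slice by slice; a unit-sum low-pass kernel ``k`` leaves thin bright
tubes almost untouched while cancelling the smooth organ background, so
vessel-to-liver contrast increases for ``lam`` in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io_volumes import BinaryMask, VolumeImage

__all__ = [
    "CalibrationParams",
    "EnhancementParams",
    "CalibrationError",
    "estimate_calibration",
    "clip_and_normalize",
    "enhance_vessels",
    "gaussian_lowpass_kernel",
]

DEFAULT_ALPHA = 255.0 / 6.0
DEFAULT_C = 127.5


class CalibrationError(ValueError):
    """Raised when vessel statistics cannot define a window."""


@dataclass
class CalibrationParams:
    """Window statistics (vessel mean/std) and the gray-scale affine map."""

    mu: float
    sigma: float
    alpha: float = DEFAULT_ALPHA
    c: float = DEFAULT_C

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise CalibrationError(f"sigma must be > 0, got {self.sigma}")
        lo = self.c - 3.0 * self.alpha
        hi = self.c + 3.0 * self.alpha
        if lo < -1e-9 or hi > 255.0 + 1e-9:
            raise ValueError(
                f"alpha/c map the clip window to [{lo:.3f}, {hi:.3f}], outside [0, 255]"
            )

    def to_dict(self) -> dict:
        return {"mu": self.mu, "sigma": self.sigma, "alpha": self.alpha, "c": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationParams":
        return cls(mu=float(d["mu"]), sigma=float(d["sigma"]),
                   alpha=float(d["alpha"]), c=float(d["c"]))


@dataclass
class EnhancementParams:
    """Subtraction magnitude ``lam`` and the normalized low-pass kernel."""

    lam: float = 0.5
    kernel: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.kernel is None:
            self.kernel = gaussian_lowpass_kernel()
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.ndim != 2 or any(s % 2 == 0 for s in self.kernel.shape):
            raise ValueError("kernel must be 2D with odd side lengths")
        if np.any(self.kernel < 0) or not np.isclose(self.kernel.sum(), 1.0):
            raise ValueError("kernel entries must be >= 0 and sum to 1")


def gaussian_lowpass_kernel(sigma: float = 5.0, truncate: float = 2.0) -> np.ndarray:
    """2D Gaussian kernel, unit sum, truncated at ``truncate`` sigmas."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = max(1, int(truncate * sigma + 0.5))
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    k = np.outer(g, g)
    return k / k.sum()


def estimate_calibration(
    volume: VolumeImage,
    vessel_mask: BinaryMask,
    alpha: float = DEFAULT_ALPHA,
    c: float = DEFAULT_C,
) -> CalibrationParams:
    """Estimate mu/sigma from the intensities under the vessel mask.

    Uses the population (divide-by-N) standard deviation.  Raises
    :class:`CalibrationError` for masks with fewer than two voxels or
    constant masked intensities (sigma would be 0).
    """
    vessel_mask.check_companion(volume)
    vals = volume.data[vessel_mask.data.astype(bool)]
    if vals.size < 2:
        raise CalibrationError(
            f"vessel mask must cover >= 2 voxels, got {vals.size}"
        )
    mu = float(np.mean(vals))
    sigma = float(np.std(vals))  # population std (ddof=0)
    if sigma == 0.0:
        raise CalibrationError("masked intensities are constant; sigma is 0")
    return CalibrationParams(mu=mu, sigma=sigma, alpha=alpha, c=c)


def clip_and_normalize(volume: VolumeImage, params: CalibrationParams) -> VolumeImage:
    """Clip to [mu-3sigma, mu+3sigma] and map affinely onto gray levels."""
    f = np.asarray(volume.data, dtype=float)
    clipped = np.clip(f, params.mu - 3.0 * params.sigma, params.mu + 3.0 * params.sigma)
    out = params.alpha * (clipped - params.mu) / params.sigma + params.c
    return VolumeImage(data=out, spacing=volume.spacing)


def enhance_vessels(volume: VolumeImage, params: EnhancementParams) -> VolumeImage:
    """Subtract ``lam`` times the low-pass-filtered image, slice by slice.

    Convolution uses reflect padding to avoid dark rims at the borders.
    """
    data = np.asarray(volume.data, dtype=float)
    out = np.empty_like(data)
    for k in range(data.shape[0]):
        low = ndi.convolve(data[k], params.kernel, mode="reflect")
        out[k] = data[k] - params.lam * low
    return VolumeImage(data=out, spacing=volume.spacing)
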