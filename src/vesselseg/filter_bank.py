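"""The 22-operator 2D filter bank and per-slice feature stacks.

Each slice of the (enhanced) volume is transformed by 12 named operators
(CLAHE, Gabor, gamma correction, Gaussian, Hessian, Laplacian, median, mean,
minimum, bilateral, Sobel, Canny) and the ten classic fixed convolution
kernels historically shipped with the Pillow ImageFilter module (blur,
contour, detail, edge-enhance, edge-enhance-more, emboss, find-edges,
sharpen, smooth, smooth-more), frozen here as in-repo constants.  Together
with the untouched input ("origin", channel 0) this yields a d = 23 channel
FeatureStack per volume.

All operators are 2D and applied slice by slice; 3D information enters only
through the h-hop context neighborhoods of :mod:`vesselseg.context`.
Intensities are assumed to be on the 0-255 gray scale produced by
calibration; operators that need a [0, 1] domain (CLAHE, gamma, bilateral)
clip and rescale internally and return 0-255 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from functools import lru_cache

import numpy as np
from scipy import ndimage as ndi, signal
from skimage import exposure, feature, filters, restoration

from .io_volumes import VolumeImage

__all__ = [
    "FilterSpec",
    "FeatureStack",
    "PILLOW_KERNELS",
    "pillow_kernel",
    "apply_filter",
    "hessian_response",
    "default_registry",
    "build_feature_stack",
]

# The ten predefined Pillow ImageFilter kernels, frozen as constants:
# name -> (kernel rows, scale, offset).  Output = correlate(I, K) / scale + offset.
PILLOW_KERNELS: dict[str, tuple[tuple[tuple[int, ...], ...], float, float]] = {
    "pl_blur": (
        ((1, 1, 1, 1, 1),
         (1, 0, 0, 0, 1),
         (1, 0, 0, 0, 1),
         (1, 0, 0, 0, 1),
         (1, 1, 1, 1, 1)), 16.0, 0.0),
    "pl_contour": (((-1, -1, -1), (-1, 8, -1), (-1, -1, -1)), 1.0, 255.0),
    "pl_detail": (((0, -1, 0), (-1, 10, -1), (0, -1, 0)), 6.0, 0.0),
    "pl_edge_enhance": (((-1, -1, -1), (-1, 10, -1), (-1, -1, -1)), 2.0, 0.0),
    "pl_edge_enhance_more": (((-1, -1, -1), (-1, 9, -1), (-1, -1, -1)), 1.0, 0.0),
    "pl_emboss": (((-1, 0, 0), (0, 1, 0), (0, 0, 0)), 1.0, 128.0),
    "pl_find_edges": (((-1, -1, -1), (-1, 8, -1), (-1, -1, -1)), 1.0, 0.0),
    "pl_sharpen": (((-2, -2, -2), (-2, 32, -2), (-2, -2, -2)), 16.0, 0.0),
    "pl_smooth": (((1, 1, 1), (1, 5, 1), (1, 1, 1)), 13.0, 0.0),
    "pl_smooth_more": (
        ((1, 1, 1, 1, 1),
         (1, 5, 5, 5, 1),
         (1, 5, 44, 5, 1),
         (1, 5, 5, 5, 1),
         (1, 1, 1, 1, 1)), 100.0, 0.0),
}

_NAMED = (
    "clahe", "gabor", "gamma", "gaussian", "hessian", "laplacian",
    "median", "mean", "minimum", "bilateral", "sobel", "canny",
)

KNOWN_FILTERS = _NAMED + tuple(PILLOW_KERNELS)


@dataclass
class FilterSpec:
    """One registry entry: operator name plus its parameters."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in KNOWN_FILTERS:
            raise KeyError(f"unknown filter {self.name!r}; known: {KNOWN_FILTERS}")


@dataclass
class FeatureStack:
    """Per-voxel d-channel responses, channel-last array ``(k, i, j, d)``.

    Channel 0 ("origin") is the untouched input volume.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"feature stack must be 4D, got {self.data.shape}")
        if self.data.shape[3] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        if self.channel_names[0] != "origin":
            raise ValueError("channel 0 must be 'origin'")
        self.channel_names = tuple(self.channel_names)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @property
    def d(self) -> int:
        return self.data.shape[3]


def pillow_kernel(name: str) -> tuple[np.ndarray, float, float]:
    """Return the frozen (kernel, scale, offset) of a predefined filter."""
    key = name if name.startswith("pl_") else f"pl_{name.lower()}"
    if key not in PILLOW_KERNELS:
        raise KeyError(f"unknown predefined filter {name!r}")
    rows, scale, offset = PILLOW_KERNELS[key]
    return np.array(rows, dtype=float), scale, offset


def _to_unit(im: np.ndarray) -> np.ndarray:
    return np.clip(im, 0.0, 255.0) / 255.0


def _clahe(im, params):
    clip = float(params.get("clip_limit", 2.0))  # OpenCV-style; /100 -> skimage scale
    tiles = params.get("tile_grid", (8, 8))
    ks = (max(1, im.shape[0] // tiles[0]), max(1, im.shape[1] // tiles[1]))
    out = exposure.equalize_adapthist(_to_unit(im), kernel_size=ks, clip_limit=clip / 100.0)
    return out * 255.0


@lru_cache(maxsize=32)
def _gabor_kernels(gamma, sigma, lam, psi, thetas):
    return tuple(
        filters.gabor_kernel(
            frequency=1.0 / lam, theta=th,
            sigma_x=sigma, sigma_y=sigma / gamma, offset=psi,
        )
        for th in thetas
    )


def _gabor(im, params):
    """Max magnitude over an orientation bank; FFT convolution, reflect pad."""
    gamma = float(params.get("gamma", 0.5))
    sigma = float(params.get("sigma", 2.0))
    lam = float(params.get("lam", 8.0))
    psi = float(params.get("psi", 0.0))
    thetas = tuple(params.get("thetas", (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)))
    best = None
    for kernel in _gabor_kernels(gamma, sigma, lam, psi, thetas):
        kh, kw = kernel.shape[0] // 2, kernel.shape[1] // 2
        padded = np.pad(im, ((kh, kh), (kw, kw)), mode="reflect")
        resp = signal.fftconvolve(padded, kernel, mode="valid")
        mag = np.abs(resp)
        best = mag if best is None else np.maximum(best, mag)
    return best


def _gamma(im, params):
    lam = float(params.get("lam", 1.0))
    gamma = float(params.get("gamma", 0.5))
    return 255.0 * lam * _to_unit(im) ** gamma


def _gaussian(im, params):
    return ndi.gaussian_filter(im, sigma=float(params.get("sigma", 1.0)), mode="reflect")


def _laplacian(im, params):
    return ndi.laplace(im, mode="reflect")


def _median(im, params):
    return ndi.median_filter(im, size=tuple(params.get("size", (3, 3))), mode="reflect")


def _mean(im, params):
    return ndi.uniform_filter(im, size=tuple(params.get("size", (3, 3))), mode="reflect")


def _minimum(im, params):
    return ndi.minimum_filter(im, size=tuple(params.get("size", (3, 3))), mode="reflect")


def _bilateral(im, params):
    sigma_s = float(params.get("sigma_spatial", 3.0))
    sigma_r = float(params.get("sigma_color", 25.0))  # gray levels on 0-255
    # spatial window truncated at 2 sigma, as for the Gaussian kernels
    win = int(params.get("win_size", 2 * int(np.ceil(2 * sigma_s)) + 1))
    out = restoration.denoise_bilateral(
        _to_unit(im), sigma_color=sigma_r / 255.0, sigma_spatial=sigma_s, win_size=win
    )
    return out * 255.0


def _sobel(im, params):
    gx = ndi.sobel(im, axis=0, mode="reflect")
    gy = ndi.sobel(im, axis=1, mode="reflect")
    return np.hypot(gx, gy)


def _canny(im, params):
    sigma = float(params.get("sigma", 1.0))
    low = float(params.get("low", 10.0))
    high = float(params.get("high", 30.0))
    edges = feature.canny(np.ascontiguousarray(im, dtype=float), sigma=sigma,
                          low_threshold=low, high_threshold=high)
    return edges.astype(float)


def hessian_response(slice2d: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Scale-normalized bright-ridge response from the 2x2 image Hessian.

    At each pixel the Hessian of the sigma-smoothed slice is formed from
    Gaussian second derivatives; the response is minus the eigenvalue of
    larger magnitude, scaled by sigma^2, so thin bright lines give a large
    positive ridge, flat regions give 0, and wide blobs give a comparatively
    small interior response.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    im = np.asarray(slice2d, dtype=float)
    hxx = ndi.gaussian_filter(im, sigma, order=(2, 0), mode="reflect")
    hyy = ndi.gaussian_filter(im, sigma, order=(0, 2), mode="reflect")
    hxy = ndi.gaussian_filter(im, sigma, order=(1, 1), mode="reflect")
    # the truncated discrete 2nd-derivative kernel has a tiny nonzero DC
    # gain; remove it so constant images give an exactly flat response
    dc = float(ndi.gaussian_filter(np.ones((1, 1)), sigma, order=(2, 0), mode="reflect")[0, 0])
    hxx = hxx - dc * im
    hyy = hyy - dc * im
    tr_half = 0.5 * (hxx + hyy)
    disc = np.sqrt(np.maximum((0.5 * (hxx - hyy)) ** 2 + hxy**2, 0.0))
    lam1 = tr_half + disc
    lam2 = tr_half - disc
    # eigenvalue of larger magnitude
    big = np.where(np.abs(lam1) >= np.abs(lam2), lam1, lam2)
    return -(sigma**2) * big


def _hessian(im, params):
    return hessian_response(im, sigma=float(params.get("sigma", 2.0)))


def _pillow(im, name, params):
    kernel, scale, offset = pillow_kernel(name)
    return ndi.correlate(im, kernel, mode="reflect") / scale + offset


_DISPATCH = {
    "clahe": _clahe,
    "gabor": _gabor,
    "gamma": _gamma,
    "gaussian": _gaussian,
    "hessian": _hessian,
    "laplacian": _laplacian,
    "median": _median,
    "mean": _mean,
    "minimum": _minimum,
    "bilateral": _bilateral,
    "sobel": _sobel,
    "canny": _canny,
}


def apply_filter(slice2d: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Apply one operator to a 2D slice; deterministic for a fixed spec."""
    im = np.asarray(slice2d, dtype=float)
    if im.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {im.shape}")
    if not np.all(np.isfinite(im)):
        raise ValueError("slice contains non-finite values")
    if spec.name in _DISPATCH:
        return np.asarray(_DISPATCH[spec.name](im, spec.params), dtype=float)
    if spec.name in PILLOW_KERNELS:
        return np.asarray(_pillow(im, spec.name, spec.params), dtype=float)
    raise KeyError(f"unknown filter {spec.name!r}")


def default_registry() -> list[FilterSpec]:
    """The default 22-operator registry (d = 23 with the origin channel)."""
    return [FilterSpec(name) for name in _NAMED] + [
        FilterSpec(name) for name in PILLOW_KERNELS
    ]


def build_feature_stack(
    volume: VolumeImage,
    registry: list[FilterSpec] | None = None,
    dtype=np.float32,
) -> FeatureStack:
    """Run every registry operator on every slice and stack the responses.

    Channel 0 is the input volume itself; channels 1..d-1 follow registry
    order.
    """
    if registry is None:
        registry = default_registry()
    data = np.asarray(volume.data, dtype=float)
    d = 1 + len(registry)
    out = np.empty(data.shape + (d,), dtype=dtype)
    out[..., 0] = data
    for k in range(data.shape[0]):
        sl = data[k]
        for c, spec in enumerate(registry, start=1):
            out[k, :, :, c] = apply_filter(sl, spec)
    names = ("origin",) + tuple(s.name for s in registry)
    return FeatureStack(data=out, channel_names=names)
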