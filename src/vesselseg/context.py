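"""h-hop context neighborhoods and flattened n x d voxel feature vectors.

A voxel at ``(k', i', j')`` is an h-hop neighbor of the center ``(k, i, j)``
when ``max(|k - k'|, |i - i'|, |j - j'|) <= h``, giving a cube of side
``2h + 1`` per axis (``(2h+1)^3`` voxels in 3D; ``(2h+1)^2`` within the
slice in 2D mode).  Each neighbor contributes its full d-channel filter
response, so a center voxel is described by a flat vector of length ``n*d``
in a fixed position-major order: neighborhood positions in raster scan
(dk outer, then di, then dj), the d channels contiguous per position.
Out-of-bounds positions are filled by reflect padding.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .filter_bank import FeatureStack
from .io_volumes import BinaryMask

__all__ = [
    "ContextSpec",
    "VoxelSample",
    "neighborhood_indices",
    "neighborhood_offsets",
    "extract_features",
    "extract_features_batch",
    "build_training_arrays",
    "build_training_set",
    "export_training_set",
    "TrainingSetError",
]


class TrainingSetError(ValueError):
    """Raised when no positive voxels are available for training."""


@dataclass(frozen=True)
class ContextSpec:
    """Hop radius ``h`` and dimensionality mode ('2d' within-slice, '3d')."""

    h: int = 1
    mode: str = "3d"

    def __post_init__(self) -> None:
        if self.h not in (0, 1, 2, 3, 4):
            raise ValueError(f"h must be in 0..4, got {self.h}")
        if self.mode not in ("2d", "3d"):
            raise ValueError(f"mode must be '2d' or '3d', got {self.mode!r}")

    @property
    def n_neighbors(self) -> int:
        side = 2 * self.h + 1
        return side**3 if self.mode == "3d" else side**2

    def offsets(self) -> np.ndarray:
        return neighborhood_offsets(self)


def neighborhood_offsets(spec: ContextSpec) -> np.ndarray:
    """All (dk, di, dj) offsets of the neighborhood in raster order."""
    h = spec.h
    rng = range(-h, h + 1)
    ks = rng if spec.mode == "3d" else (0,)
    return np.array([(dk, di, dj) for dk in ks for di in rng for dj in rng], dtype=int)


def neighborhood_indices(
    center: tuple[int, int, int],
    spec: ContextSpec,
    shape: tuple[int, int, int],
) -> list[tuple[tuple[int, int, int], bool]]:
    """Neighbor indices in raster order with an in-bounds flag each.

    Out-of-bounds positions keep their raw (possibly negative) indices and
    are flagged ``False`` so callers can substitute padded values.
    """
    k, i, j = center
    if not (0 <= k < shape[0] and 0 <= i < shape[1] and 0 <= j < shape[2]):
        raise IndexError(f"center {center} outside volume of shape {shape}")
    out = []
    for dk, di, dj in neighborhood_offsets(spec):
        kk, ii, jj = k + dk, i + di, j + dj
        inside = 0 <= kk < shape[0] and 0 <= ii < shape[1] and 0 <= jj < shape[2]
        out.append(((kk, ii, jj), inside))
    return out


def _pad_stack(stack: FeatureStack, h: int) -> np.ndarray:
    if h == 0:
        return stack.data
    return np.pad(stack.data, ((h, h), (h, h), (h, h), (0, 0)), mode="reflect")


def extract_features_batch(
    stack: FeatureStack,
    centers: np.ndarray,
    spec: ContextSpec,
    dtype=np.float32,
) -> np.ndarray:
    """Flat n*d context vectors for many centers at once.

    ``centers`` is an (N, 3) integer array of (k, i, j) indices.  Returns an
    (N, n*d) array in the canonical position-major order.
    """
    centers = np.asarray(centers, dtype=np.intp)
    if centers.ndim != 2 or centers.shape[1] != 3:
        raise ValueError("centers must be (N, 3)")
    shape = stack.shape
    if centers.size and (
        centers.min() < 0
        or np.any(centers >= np.array(shape, dtype=np.intp))
    ):
        raise IndexError("a center lies outside the volume")
    h = spec.h
    padded = _pad_stack(stack, h)
    offs = neighborhood_offsets(spec)
    n, d = len(offs), stack.d
    out = np.empty((len(centers), n * d), dtype=dtype)
    ck, ci, cj = centers[:, 0] + h, centers[:, 1] + h, centers[:, 2] + h
    for p, (dk, di, dj) in enumerate(offs):
        out[:, p * d:(p + 1) * d] = padded[ck + dk, ci + di, cj + dj, :]
    return out


def extract_features(
    stack: FeatureStack,
    center: tuple[int, int, int],
    spec: ContextSpec,
) -> np.ndarray:
    """Flat context vector of length n*d for one center voxel."""
    return extract_features_batch(stack, np.array([center]), spec)[0]


@dataclass
class VoxelSample:
    """One training sample: center index, flat n*d features, binary label."""

    center: tuple[int, int, int]
    features: np.ndarray
    label: int


def _sample_centers(
    vessel: np.ndarray,
    roi: np.ndarray | None,
    neg_ratio: float,
    rng: np.random.Generator,
    max_positives: int | None,
) -> tuple[np.ndarray, np.ndarray]:
    inside = np.ones_like(vessel, dtype=bool) if roi is None else roi.astype(bool)
    pos = np.argwhere(vessel.astype(bool) & inside)
    if len(pos) == 0:
        raise TrainingSetError("no positive (vessel) voxels inside the ROI")
    if max_positives is not None and len(pos) > max_positives:
        sel = rng.choice(len(pos), size=max_positives, replace=False)
        pos = pos[np.sort(sel)]
    neg_pool = np.argwhere(inside & ~vessel.astype(bool))
    n_neg = int(round(neg_ratio * len(pos)))
    n_neg = min(n_neg, len(neg_pool))
    if n_neg > 0:
        sel = rng.choice(len(neg_pool), size=n_neg, replace=False)
        neg = neg_pool[np.sort(sel)]
    else:
        neg = neg_pool[:0]
    return pos, neg


def build_training_arrays(
    stack: FeatureStack,
    vessel_mask: BinaryMask,
    roi_mask: BinaryMask | None,
    spec: ContextSpec,
    neg_ratio: float = 5.0,
    seed: int = 0,
    max_positives: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized training-set construction: (X, y, centers).

    Every positive voxel inside the ROI is included (optionally capped at
    ``max_positives``, sampled without replacement); negatives are drawn
    uniformly at random inside the ROI at ``neg_ratio`` negatives per
    positive.  Deterministic for a fixed seed.
    """
    if vessel_mask.shape != stack.shape:
        raise ValueError("vessel mask shape does not match stack")
    if roi_mask is not None and roi_mask.shape != stack.shape:
        raise ValueError("roi mask shape does not match stack")
    rng = np.random.default_rng(seed)
    roi = None if roi_mask is None else roi_mask.data
    pos, neg = _sample_centers(vessel_mask.data, roi, neg_ratio, rng, max_positives)
    centers = np.vstack([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=np.int8), np.zeros(len(neg), dtype=np.int8)])
    X = extract_features_batch(stack, centers, spec)
    return X, y, centers


def export_training_set(samples: list["VoxelSample"], path: str) -> None:
    """Write samples as TSV: one row per sample, feature columns + label."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        n_feat = len(samples[0].features) if samples else 0
        writer.writerow(["k", "i", "j", *(f"f{i}" for i in range(n_feat)), "label"])
        for s in samples:
            writer.writerow([*s.center, *(repr(float(x)) for x in s.features), s.label])


def build_training_set(
    stack: FeatureStack,
    vessel_mask: BinaryMask,
    roi_mask: BinaryMask | None,
    spec: ContextSpec,
    neg_ratio: float = 5.0,
    seed: int = 0,
    max_positives: int | None = None,
) -> list[VoxelSample]:
    """As :func:`build_training_arrays`, returned as VoxelSample records."""
    X, y, centers = build_training_arrays(
        stack, vessel_mask, roi_mask, spec,
        neg_ratio=neg_ratio, seed=seed, max_positives=max_positives,
    )
    return [
        VoxelSample(center=tuple(int(v) for v in c), features=x, label=int(lab))
        for c, x, lab in zip(centers, X, y)
    ]
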