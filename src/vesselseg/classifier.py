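"""Gradient-boosted voxel classification and per-filter importance.

A boosted-tree ensemble (XGBoost, binary logistic) is trained on flattened
n x d context vectors and applied voxel-wise to produce a posterior
probability map.  Because every neighborhood position of every filter
channel is a separate input column, the ensemble performs implicit feature
selection; :func:`filter_importance` aggregates the per-column gain back to
the source filter (and, in 3D mode, to the slice offset it came from),
mirroring how one inspects which operators the model actually uses.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .context import ContextSpec, VoxelSample, extract_features_batch, neighborhood_offsets
from .enhancement import CalibrationParams
from .filter_bank import FeatureStack
from .io_volumes import BinaryMask

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "FeatureLayout",
    "TrainedModel",
    "ProbabilityMap",
    "train",
    "predict_volume",
    "threshold_map",
    "filter_importance",
    "save_model",
    "load_model",
]

# Defaults sized for single-CPU training on tens of thousands of voxels with
# hundreds-to-thousands of columns; column subsampling doubles as implicit
# regularization for the highly redundant neighborhood features.
DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 40,
    "max_depth": 4,
    "learning_rate": 0.2,
    "subsample": 0.8,
    "colsample_bytree": 0.2,
    "max_bin": 64,
}


@dataclass(frozen=True)
class FeatureLayout:
    """The context spec and channel order a model was trained with."""

    spec: ContextSpec
    channel_names: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.spec.n_neighbors * len(self.channel_names)


@dataclass
class TrainedModel:
    """Boosted ensemble plus everything needed to reproduce its inputs."""

    booster: xgb.Booster
    layout: FeatureLayout
    calibration: CalibrationParams | None = None
    threshold: float = 0.5
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Vessel posterior for rows of flattened context features."""
        return self.booster.inplace_predict(
            np.asarray(X, dtype=np.float32), validate_features=False
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(np.int8)


@dataclass
class ProbabilityMap:
    """Per-voxel vessel posterior in [0, 1]; voxels outside the ROI are 0."""

    data: np.ndarray
    roi: BinaryMask | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("probability map must be 3D")
        if np.any((self.data < 0) | (self.data > 1)):
            raise ValueError("posteriors must lie in [0, 1]")
        if self.roi is not None:
            if self.roi.shape != self.data.shape:
                raise ValueError("roi shape mismatch")
            if np.any(self.data[~self.roi.data.astype(bool)] != 0):
                raise ValueError("posteriors outside the ROI must be 0")


def _samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        return np.asarray(samples[0]), np.asarray(samples[1])
    X = np.stack([s.features for s in samples])
    y = np.array([s.label for s in samples], dtype=np.int8)
    return X, y


def train(
    samples: list[VoxelSample] | tuple[np.ndarray, np.ndarray],
    layout: FeatureLayout,
    hyperparams: dict | None = None,
    seed: int = 0,
    calibration: CalibrationParams | None = None,
    threshold: float = 0.5,
) -> TrainedModel:
    """Fit the boosted-tree voxel classifier.

    Deterministic for a fixed seed (single-thread, histogram method).
    Raises on single-class input.
    """
    X, y = _samples_to_arrays(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if X.shape[1] != layout.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} != layout n*d = {layout.n_features}"
        )
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    params = {
        "objective": "binary:logistic",
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(seed),
        "max_depth": int(hp["max_depth"]),
        "eta": float(hp["learning_rate"]),
        "subsample": float(hp["subsample"]),
        "colsample_bytree": float(hp["colsample_bytree"]),
        "max_bin": int(hp.get("max_bin", 256)),
    }
    dtrain = xgb.DMatrix(np.asarray(X, dtype=np.float32), label=y)
    booster = xgb.train(params, dtrain, num_boost_round=int(hp["n_estimators"]))
    return TrainedModel(
        booster=booster, layout=layout, calibration=calibration,
        threshold=threshold, hyperparams=hp,
    )


def predict_volume(
    model: TrainedModel,
    stack: FeatureStack,
    roi: BinaryMask | None = None,
    batch: int = 32768,
) -> ProbabilityMap:
    """Posterior for every ROI voxel (whole volume when no ROI); 0 outside."""
    if stack.channel_names != model.layout.channel_names:
        raise ValueError(
            "stack channels do not match the model's feature layout: "
            f"{stack.channel_names} vs {model.layout.channel_names}"
        )
    out = np.zeros(stack.shape, dtype=float)
    if roi is not None:
        if roi.shape != stack.shape:
            raise ValueError("roi shape mismatch")
        centers = np.argwhere(roi.data.astype(bool))
    else:
        centers = np.argwhere(np.ones(stack.shape, dtype=bool))
    for start in range(0, len(centers), batch):
        chunk = centers[start:start + batch]
        X = extract_features_batch(stack, chunk, model.layout.spec)
        p = model.predict_proba(X)
        out[chunk[:, 0], chunk[:, 1], chunk[:, 2]] = p
    np.clip(out, 0.0, 1.0, out=out)
    return ProbabilityMap(data=out, roi=roi)


def threshold_map(pmap: ProbabilityMap, t: float = 0.5) -> BinaryMask:
    """Binary mask of voxels with posterior >= t."""
    if not 0 < t < 1:
        raise ValueError("threshold must be in (0, 1)")
    return BinaryMask((pmap.data >= t).astype(np.uint8))


def filter_importance(model: TrainedModel) -> pd.DataFrame:
    """Total-gain importance aggregated per filter channel and slice offset.

    Rows are the filter channels in stack order; in 3D mode there is one
    column per slice offset dk in [-h, h] plus a 'total'; 2D mode has a
    single offset column '0'.  Filters whose aggregate gain is 0 are marked
    unselected.
    """
    gains = model.booster.get_score(importance_type="total_gain")
    d = len(model.layout.channel_names)
    offs = neighborhood_offsets(model.layout.spec)
    h = model.layout.spec.h
    dks = list(range(-h, h + 1)) if model.layout.spec.mode == "3d" else [0]
    table = pd.DataFrame(
        0.0, index=list(model.layout.channel_names), columns=[str(dk) for dk in dks]
    )
    for fname, gain in gains.items():
        idx = int(fname[1:])  # 'f123' -> 123
        pos, chan = divmod(idx, d)
        dk = int(offs[pos][0])
        table.iloc[chan, dks.index(dk)] += gain
    table["total"] = table.sum(axis=1)
    table["selected"] = table["total"] > 0
    return table


def save_model(model: TrainedModel, path: str) -> None:
    """Persist the ensemble plus its preprocessing manifest to a directory."""
    os.makedirs(path, exist_ok=True)
    model.booster.save_model(os.path.join(path, "booster.json"))
    manifest = {
        "h": model.layout.spec.h,
        "mode": model.layout.spec.mode,
        "channel_names": list(model.layout.channel_names),
        "threshold": model.threshold,
        "hyperparams": model.hyperparams,
        "calibration": model.calibration.to_dict() if model.calibration else None,
    }
    with open(os.path.join(path, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_model(path: str) -> TrainedModel:
    with open(os.path.join(path, "manifest.json")) as fh:
        manifest = json.load(fh)
    clf = xgb.Booster(model_file=os.path.join(path, "booster.json"))
    layout = FeatureLayout(
        spec=ContextSpec(h=manifest["h"], mode=manifest["mode"]),
        channel_names=tuple(manifest["channel_names"]),
    )
    calib = manifest.get("calibration")
    return TrainedModel(
        booster=clf,
        layout=layout,
        calibration=CalibrationParams.from_dict(calib) if calib else None,
        threshold=manifest["threshold"],
        hyperparams=manifest.get("hyperparams", {}),
    )
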