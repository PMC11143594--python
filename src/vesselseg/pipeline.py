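"""End-to-end segmentation estimator and the experimental protocols.

:class:`VesselSegmenter` is a scikit-learn-style estimator covering the full
chain: vessel-statistics calibration -> unsharp enhancement -> 23-channel
filter stack -> h-hop context features -> boosted-tree voxel classifier ->
optional Lorentzian-MRF refinement -> thresholded mask.  ``fit`` consumes
lists of volumes with vessel masks (and optional liver ROI masks);
prediction returns posterior maps and binary masks per volume.

The module-level protocol functions reproduce the evaluation designs used
for this kind of segmenter: scan-level k-fold cross-validation (folds
partition whole volumes, never slices), the context-size ablation over
(mode, h) cells with shared folds, and the paired MRF on/off comparison
where both arms consume identical classifier outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone

from . import classifier as clf_mod
from .classifier import FeatureLayout, ProbabilityMap, TrainedModel, predict_volume, threshold_map
from .context import ContextSpec, build_training_arrays
from .enhancement import (
    DEFAULT_ALPHA,
    DEFAULT_C,
    CalibrationParams,
    EnhancementParams,
    clip_and_normalize,
    enhance_vessels,
    gaussian_lowpass_kernel,
)
from .filter_bank import FeatureStack, build_feature_stack, default_registry
from .io_volumes import BinaryMask, VolumeImage
from .metrics import compute_metrics, confusion, report_table
from .mrf import MRFParams, refine, refine_mask

__all__ = [
    "VesselSegmenter",
    "CVResult",
    "assign_folds",
    "crossvalidate",
    "run_protocol",
    "ablate_context",
    "compare_mrf",
]


def _child_seed(seed: int, *keys) -> int:
    payload = json.dumps([int(seed), *map(str, keys)]).encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "little") % (2**31)


class VesselSegmenter(BaseEstimator):
    """Full liver-vessel segmentation pipeline as one estimator.

    Parameters
    ----------
    alpha, c : float
        Gray-scale gain/offset of the calibration map; defaults fill
        [0, 255] exactly from the +-3 sigma window.
    enhance_lam, kernel_sigma : float
        Unsharp subtraction magnitude and the Gaussian low-pass width (px).
    filters : "bank22" or list
        Filter registry; the default 22-operator bank gives d = 23.
    hop, mode : int, str
        Context radius h and '2d'/'3d' neighborhood mode.
    neg_ratio : float
        Negatives sampled per positive during training.
    max_positives : int or None
        Per-volume cap on positive training voxels (sampled without
        replacement); None keeps all.
    n_estimators, max_depth, learning_rate, subsample, colsample_bytree
        Boosted-tree hyperparameters.
    threshold : float
        Posterior cutoff for binary masks.
    refine : bool
        Apply Lorentzian-MRF refinement before thresholding.
    mrf_lam, mrf_sigma_i, mrf_sigma_g, mrf_neighborhood, mrf_max_iter
        Refinement energy parameters.
    random_state : int
        Seeds negative sampling and the tree ensemble.
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        c: float = DEFAULT_C,
        enhance_lam: float = 0.5,
        kernel_sigma: float = 5.0,
        filters="bank22",
        hop: int = 1,
        mode: str = "3d",
        neg_ratio: float = 5.0,
        max_positives: int | None = 600,
        n_estimators: int = 40,
        max_depth: int = 4,
        learning_rate: float = 0.2,
        subsample: float = 0.8,
        colsample_bytree: float = 0.2,
        threshold: float = 0.5,
        refine: bool = True,
        mrf_lam: float = 0.3,
        mrf_sigma_i: float = 0.3,
        mrf_sigma_g: float = 0.3,
        mrf_neighborhood: str = "3d-6",
        mrf_max_iter: int = 20,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.c = c
        self.enhance_lam = enhance_lam
        self.kernel_sigma = kernel_sigma
        self.filters = filters
        self.hop = hop
        self.mode = mode
        self.neg_ratio = neg_ratio
        self.max_positives = max_positives
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.threshold = threshold
        self.refine = refine
        self.mrf_lam = mrf_lam
        self.mrf_sigma_i = mrf_sigma_i
        self.mrf_sigma_g = mrf_sigma_g
        self.mrf_neighborhood = mrf_neighborhood
        self.mrf_max_iter = mrf_max_iter
        self.random_state = random_state

    # -- building blocks -------------------------------------------------

    def _registry(self):
        if isinstance(self.filters, str):
            if self.filters != "bank22":
                raise ValueError(f"unknown filter preset {self.filters!r}")
            return default_registry()
        return list(self.filters)

    def _context_spec(self) -> ContextSpec:
        return ContextSpec(h=self.hop, mode=self.mode)

    def mrf_params(self) -> MRFParams:
        return MRFParams(
            lam=self.mrf_lam, sigma_i=self.mrf_sigma_i, sigma_g=self.mrf_sigma_g,
            neighborhood=self.mrf_neighborhood, max_iter=self.mrf_max_iter,
        )

    def estimate_calibration(
        self, volumes: list[VolumeImage], vessel_masks: list[BinaryMask]
    ) -> CalibrationParams:
        """Pooled vessel-intensity statistics over the training volumes."""
        vals = np.concatenate([
            vol.data[m.data.astype(bool)] for vol, m in zip(volumes, vessel_masks)
        ])
        if vals.size < 2:
            raise ValueError("need >= 2 vessel voxels across the training volumes")
        sigma = float(np.std(vals))
        if sigma == 0:
            raise ValueError("vessel intensities are constant; cannot calibrate")
        return CalibrationParams(mu=float(np.mean(vals)), sigma=sigma,
                                 alpha=self.alpha, c=self.c)

    def build_stack(self, volume: VolumeImage, calibration: CalibrationParams) -> FeatureStack:
        """Calibrate, enhance and run the filter bank on one volume."""
        enh_params = EnhancementParams(
            lam=self.enhance_lam, kernel=gaussian_lowpass_kernel(self.kernel_sigma)
        )
        calibrated = clip_and_normalize(volume, calibration)
        enhanced = enhance_vessels(calibrated, enh_params)
        return build_feature_stack(enhanced, self._registry())

    # -- estimator API ---------------------------------------------------

    def fit(
        self,
        volumes: list[VolumeImage],
        vessel_masks: list[BinaryMask],
        roi_masks: list[BinaryMask] | None = None,
    ) -> "VesselSegmenter":
        if len(volumes) != len(vessel_masks):
            raise ValueError("volumes and vessel_masks must have equal length")
        if roi_masks is not None and len(roi_masks) != len(volumes):
            raise ValueError("roi_masks length mismatch")
        calibration = self.estimate_calibration(volumes, vessel_masks)
        stacks = [self.build_stack(v, calibration) for v in volumes]
        self.fit_from_stacks(stacks, vessel_masks, roi_masks, calibration)
        return self

    def fit_from_stacks(
        self,
        stacks: list[FeatureStack],
        vessel_masks: list[BinaryMask],
        roi_masks: list[BinaryMask] | None,
        calibration: CalibrationParams,
    ) -> "VesselSegmenter":
        """Train the voxel classifier from precomputed feature stacks."""
        spec = self._context_spec()
        Xs, ys = [], []
        for i, (stack, vmask) in enumerate(zip(stacks, vessel_masks)):
            roi = roi_masks[i] if roi_masks is not None else None
            X, y, _ = build_training_arrays(
                stack, vmask, roi, spec,
                neg_ratio=self.neg_ratio,
                seed=_child_seed(self.random_state, "sample", i),
                max_positives=self.max_positives,
            )
            Xs.append(X)
            ys.append(y)
        X = np.vstack(Xs)
        y = np.concatenate(ys)
        layout = FeatureLayout(spec=spec, channel_names=stacks[0].channel_names)
        self.model_ = clf_mod.train(
            (X, y), layout,
            hyperparams={
                "n_estimators": self.n_estimators,
                "max_depth": self.max_depth,
                "learning_rate": self.learning_rate,
                "subsample": self.subsample,
                "colsample_bytree": self.colsample_bytree,
            },
            seed=_child_seed(self.random_state, "xgb"),
            calibration=calibration,
            threshold=self.threshold,
        )
        self.calibration_ = calibration
        self.layout_ = layout
        return self

    def _check_fitted(self) -> TrainedModel:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
        return self.model_

    def predict_proba_volume(
        self, volume: VolumeImage, roi: BinaryMask | None = None
    ) -> ProbabilityMap:
        model = self._check_fitted()
        stack = self.build_stack(volume, self.calibration_)
        return predict_volume(model, stack, roi=roi)

    def predict_from_stack(
        self, stack: FeatureStack, roi: BinaryMask | None = None
    ) -> ProbabilityMap:
        return predict_volume(self._check_fitted(), stack, roi=roi)

    def predict_volume(
        self, volume: VolumeImage, roi: BinaryMask | None = None
    ) -> BinaryMask:
        pmap = self.predict_proba_volume(volume, roi=roi)
        if self.refine:
            return refine_mask(pmap, self.mrf_params(), t=self.threshold)
        return threshold_map(pmap, self.threshold)

    def filter_importance(self) -> pd.DataFrame:
        return clf_mod.filter_importance(self._check_fitted())

    def save(self, path: str) -> None:
        """Persist the fitted model, calibration and estimator parameters."""
        import os

        model = self._check_fitted()
        if not isinstance(self.filters, str):
            raise ValueError("only preset filter registries can be persisted")
        clf_mod.save_model(model, path)
        with open(os.path.join(path, "estimator.json"), "w") as fh:
            json.dump(self.get_params(), fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "VesselSegmenter":
        import os

        with open(os.path.join(path, "estimator.json")) as fh:
            est = cls(**json.load(fh))
        est.model_ = clf_mod.load_model(path)
        est.calibration_ = est.model_.calibration
        est.layout_ = est.model_.layout
        return est


# -- experimental protocols ----------------------------------------------


@dataclass
class CVResult:
    """Cross-validation output: metric table, fold map, run manifest."""

    report: pd.DataFrame
    fold_of_volume: np.ndarray
    manifest: dict = field(default_factory=dict)


def assign_folds(n_volumes: int, folds: int, seed: int = 0) -> np.ndarray:
    """Deterministic scan-level fold assignment (a partition of volumes)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n_volumes < folds:
        raise ValueError(f"need >= {folds} volumes for {folds}-fold CV, got {n_volumes}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_volumes)
    assignment = np.empty(n_volumes, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        assignment[chunk] = f
    return assignment


def _dataset_parts(dataset):
    volumes = [t[0] for t in dataset]
    vessels = [t[1] for t in dataset]
    rois = [t[2] if len(t) > 2 else None for t in dataset]
    if any(r is None for r in rois):
        rois = None
    return volumes, vessels, rois


def crossvalidate(
    dataset,
    estimator: VesselSegmenter | None = None,
    folds: int = 5,
    seed: int = 0,
    return_masks: bool = False,
):
    """Scan-level k-fold CV; every volume is tested exactly once.

    ``dataset`` is a list of (volume, vessel_mask[, roi_mask]) tuples.
    Calibration is estimated per fold from training vessels only.
    """
    estimator = estimator if estimator is not None else VesselSegmenter()
    volumes, vessels, rois = _dataset_parts(dataset)
    assignment = assign_folds(len(volumes), folds, seed)
    pairs, names, masks = [], [], {}
    for f in range(folds):
        train_idx = np.flatnonzero(assignment != f)
        test_idx = np.flatnonzero(assignment == f)
        est = clone(estimator)
        est.random_state = _child_seed(seed, "fold", f, estimator.random_state)
        est.fit(
            [volumes[i] for i in train_idx],
            [vessels[i] for i in train_idx],
            [rois[i] for i in train_idx] if rois is not None else None,
        )
        for i in test_idx:
            roi = rois[i] if rois is not None else None
            pred = est.predict_volume(volumes[i], roi=roi)
            pairs.append((pred, vessels[i], roi))
            names.append(f"vol{i}")
            if return_masks:
                masks[i] = pred
    report = report_table(pairs, names)
    manifest = {
        "folds": folds, "seed": seed, "n_volumes": len(volumes),
        "fold_of_volume": assignment.tolist(),
        "estimator": {k: repr(v) for k, v in estimator.get_params().items()},
    }
    result = CVResult(report=report, fold_of_volume=assignment, manifest=manifest)
    return (result, masks) if return_masks else result


def run_protocol(
    dataset,
    cells: list[tuple[str, int]] = (("3d", 1), ("3d", 2)),
    estimator: VesselSegmenter | None = None,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Shared-fold CV over (mode, h) context cells with paired MRF arms.

    Per fold, calibration and the per-volume feature stacks are computed
    once and reused across cells; only the context spec (hence training
    arrays and the classifier) differs per cell.  Both the raw thresholded
    mask and the MRF-refined mask are evaluated from the same posterior
    map.  Returns one row per (cell, test volume) with Sen/Spe/Acc/DSC for
    both arms.
    """
    estimator = estimator if estimator is not None else VesselSegmenter()
    volumes, vessels, rois = _dataset_parts(dataset)
    assignment = assign_folds(len(volumes), folds, seed)
    rows = []
    for f in range(folds):
        train_idx = np.flatnonzero(assignment != f)
        test_idx = np.flatnonzero(assignment == f)
        base = clone(estimator)
        base.random_state = _child_seed(seed, "fold", f, estimator.random_state)
        calibration = base.estimate_calibration(
            [volumes[i] for i in train_idx], [vessels[i] for i in train_idx]
        )
        stacks = {i: base.build_stack(volumes[i], calibration)
                  for i in np.concatenate([train_idx, test_idx])}
        for mode, h in cells:
            est = clone(base)
            est.mode, est.hop = mode, h
            est.fit_from_stacks(
                [stacks[i] for i in train_idx],
                [vessels[i] for i in train_idx],
                [rois[i] for i in train_idx] if rois is not None else None,
                calibration,
            )
            for i in test_idx:
                roi = rois[i] if rois is not None else None
                pmap = est.predict_from_stack(stacks[i], roi=roi)
                raw = threshold_map(pmap, est.threshold)
                ref = refine_mask(pmap, est.mrf_params(), t=est.threshold)
                m_raw = compute_metrics(confusion(raw, vessels[i], roi))
                m_ref = compute_metrics(confusion(ref, vessels[i], roi))
                rows.append({
                    "mode": mode, "h": h, "volume": f"vol{i}", "fold": f,
                    "dsc_raw": m_raw.dsc, "dsc_refined": m_ref.dsc,
                    "sen_raw": m_raw.sen, "sen_refined": m_ref.sen,
                    "spe_raw": m_raw.spe, "spe_refined": m_ref.spe,
                    "acc_raw": m_raw.acc, "acc_refined": m_ref.acc,
                })
    return pd.DataFrame(rows)


def ablate_context(
    dataset,
    cells: list[tuple[str, int]] = (("2d", 1), ("3d", 1), ("3d", 2)),
    estimator: VesselSegmenter | None = None,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Context-size ablation: one CV per (mode, h) cell, shared folds.

    Returns a table with one row per cell ('1x3x3' style labels: leading 1
    for 2D, 2h+1 for 3D) and the Sen/Spe/Acc/DSC averaged over test
    volumes, using the refined arm when the estimator refines (raw
    otherwise).
    """
    estimator = estimator if estimator is not None else VesselSegmenter()
    long = run_protocol(dataset, cells=cells, estimator=estimator, folds=folds, seed=seed)
    arm = "refined" if estimator.refine else "raw"
    rows = []
    for mode, h in cells:
        side = 2 * h + 1
        label = f"1x{side}x{side}" if mode == "2d" else f"{side}x{side}x{side}"
        sub = long[(long["mode"] == mode) & (long["h"] == h)]
        rows.append({
            "voxel": label, "mode": mode, "h": h,
            "acc": sub[f"acc_{arm}"].mean(), "sen": sub[f"sen_{arm}"].mean(),
            "spe": sub[f"spe_{arm}"].mean(), "dsc": sub[f"dsc_{arm}"].mean(),
        })
    return pd.DataFrame(rows).set_index("voxel")


def compare_mrf(
    dataset,
    estimator: VesselSegmenter | None = None,
    folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired MRF on/off comparison; both arms share the classifier output.

    Returns one row per test volume with dsc/sen for the raw thresholded
    masks and the refined masks, plus a 'mean' summary row; the paired mean
    DSC difference is ``df.loc['mean', 'dsc_refined'] - df.loc['mean',
    'dsc_raw']``.
    """
    estimator = estimator if estimator is not None else VesselSegmenter()
    long = run_protocol(
        dataset, cells=[(estimator.mode, estimator.hop)],
        estimator=estimator, folds=folds, seed=seed,
    )
    df = long.set_index("volume")[
        ["fold", "dsc_raw", "dsc_refined", "sen_raw", "sen_refined"]
    ]
    df.loc["mean"] = df.mean(numeric_only=True)
    return df
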