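"""Segmentation evaluation: Sen, Spe, Acc and Dice from mask pairs.

Sen = TP/(TP+FN), Spe = TN/(TN+FP), Acc = (TP+TN)/total and
DSC = 2*TP/(FP+FN+2*TP).  Counts can be restricted to a region of interest
(the liver mask); metrics with a zero denominator are flagged undefined and
reported as NaN rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_volumes import BinaryMask

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "compute_metrics", "report_table"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The four metrics; undefined entries are NaN with a False flag."""

    sen: float
    spe: float
    acc: float
    dsc: float

    @property
    def defined(self) -> dict[str, bool]:
        return {m: not math.isnan(getattr(self, m)) for m in ("sen", "spe", "acc", "dsc")}


def confusion(
    pred: BinaryMask,
    truth: BinaryMask,
    roi: BinaryMask | None = None,
) -> ConfusionCounts:
    """Voxel confusion counts, restricted to the ROI when given."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred.data.astype(bool)
    t = truth.data.astype(bool)
    if roi is not None:
        if roi.shape != pred.shape:
            raise ValueError("roi shape mismatch")
        sel = roi.data.astype(bool)
        p, t = p[sel], t[sel]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Closed-form metrics from confusion counts."""
    return MetricReport(
        sen=_ratio(c.tp, c.tp + c.fn),
        spe=_ratio(c.tn, c.tn + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
        dsc=_ratio(2 * c.tp, c.fp + c.fn + 2 * c.tp),
    )


def report_table(
    pairs: list[tuple[BinaryMask, BinaryMask, BinaryMask | None]],
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-volume metric rows plus 'mean' (across volumes) and 'pooled' rows.

    'mean' averages the per-volume metrics (NaN-aware); 'pooled' sums the
    confusion counts over all volumes first.
    """
    if names is None:
        names = [f"vol{i}" for i in range(len(pairs))]
    rows, counts = [], []
    for (pred, truth, roi), name in zip(pairs, names):
        c = confusion(pred, truth, roi)
        m = compute_metrics(c)
        counts.append(c)
        rows.append({"volume": name, "sen": m.sen, "spe": m.spe, "acc": m.acc,
                     "dsc": m.dsc, "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn})
    df = pd.DataFrame(rows).set_index("volume")
    mean = df[["sen", "spe", "acc", "dsc"]].mean()
    pooled_counts = ConfusionCounts(
        tp=int(df["tp"].sum()), fp=int(df["fp"].sum()),
        tn=int(df["tn"].sum()), fn=int(df["fn"].sum()),
    )
    pm = compute_metrics(pooled_counts)
    df.loc["mean", ["sen", "spe", "acc", "dsc"]] = mean
    df.loc["pooled", ["sen", "spe", "acc", "dsc"]] = [pm.sen, pm.spe, pm.acc, pm.dsc]
    return df
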