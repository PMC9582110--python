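"""Segmentation quality metrics: Dice coefficient, Jaccard index, grouping.

Conventions:

- ``dice(a, b) = 2|A∩B| / (|A| + |B|)``, ``iou(a, b) = |A∩B| / |A∪B|``.
- Two empty masks score 1.0 (a healthy cube predicted empty is a perfect
  segmentation and must not drag a group average down).
- Per-group aggregation pools the voxel counts (TP, FP, FN) over all cubes
  of the group — robust to empty-mask cubes — and additionally reports the
  per-cube mean of both metrics for transparency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np


def _as_bool(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int]:
    """(TP, FP, FN) voxel counts between a predicted and a truth mask."""
    pred, truth = _as_bool(pred, truth)
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    return tp, fp, fn


def _dice_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2.0 * tp / denom


def _iou_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = tp + fp + fn
    return 1.0 if denom == 0 else tp / denom


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient in [0, 1]; 1.0 when both masks are empty."""
    return _dice_from_counts(*confusion_counts(a, b))


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index in [0, 1]; 1.0 when both masks are empty."""
    return _iou_from_counts(*confusion_counts(a, b))


@dataclass(frozen=True)
class CubeMetrics:
    cube_id: str
    group: str
    dice: float
    iou: float
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class GroupMetrics:
    group: str
    n_cubes: int
    dice_pooled: float
    iou_pooled: float
    dice_mean: float
    iou_mean: float
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class MetricsReport:
    per_cube: tuple[CubeMetrics, ...]
    per_group: Mapping[str, GroupMetrics]

    def to_dict(self) -> dict:
        return {
            "per_cube": [vars(c) for c in self.per_cube],
            "per_group": {g: vars(m) for g, m in self.per_group.items()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_table(self) -> str:
        """Human-readable per-group table (metric rows, group columns)."""
        groups = sorted(self.per_group)
        header = "Metric".ljust(14) + "".join(g.rjust(12) for g in groups)
        rows = [header]
        for label, attr in (("DSC", "dice_pooled"), ("IoU", "iou_pooled"),
                            ("DSC (mean)", "dice_mean"), ("IoU (mean)", "iou_mean")):
            vals = "".join(f"{getattr(self.per_group[g], attr):12.4f}" for g in groups)
            rows.append(label.ljust(14) + vals)
        return "\n".join(rows)


def evaluate_groups(
    pred_cubes: Sequence[np.ndarray],
    gt_cubes: Sequence[np.ndarray],
    group_of: Callable[[int], str] | Sequence[str],
    cube_ids: Sequence[str] | None = None,
) -> MetricsReport:
    """Per-cube and per-group (voxel-pooled) Dice/IoU over aligned mask lists.

    ``group_of`` labels each cube (callable on the cube index, or a sequence
    of labels), e.g. by acquisition geometry.  Healthy cubes with empty
    prediction and empty truth score 1.0 and contribute zero counts to the
    pooled group metric.
    """
    if len(pred_cubes) != len(gt_cubes):
        raise ValueError("pred_cubes and gt_cubes must have equal length")
    labels = ([group_of(i) for i in range(len(pred_cubes))]
              if callable(group_of) else list(group_of))
    ids = list(cube_ids) if cube_ids is not None else [f"cube_{i:03d}" for i in
                                                      range(len(pred_cubes))]
    per_cube = []
    for cid, lab, pred, gt in zip(ids, labels, pred_cubes, gt_cubes):
        tp, fp, fn = confusion_counts(pred, gt)
        per_cube.append(CubeMetrics(cid, lab, _dice_from_counts(tp, fp, fn),
                                    _iou_from_counts(tp, fp, fn), tp, fp, fn))
    per_group = {}
    for lab in sorted(set(labels)):
        members = [c for c in per_cube if c.group == lab]
        tp = sum(c.tp for c in members)
        fp = sum(c.fp for c in members)
        fn = sum(c.fn for c in members)
        per_group[lab] = GroupMetrics(
            group=lab, n_cubes=len(members),
            dice_pooled=_dice_from_counts(tp, fp, fn),
            iou_pooled=_iou_from_counts(tp, fp, fn),
            dice_mean=float(np.mean([c.dice for c in members])),
            iou_mean=float(np.mean([c.iou for c in members])),
            tp=tp, fp=fp, fn=fn)
    return MetricsReport(tuple(per_cube), per_group)
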