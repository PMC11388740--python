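"""PCKh evaluation: percentage of correct keypoints and curve AUC.

PCKh@t counts a predicted keypoint as correct when its Euclidean error is at
most t * l, where l is the ground-truth head-top to neck distance of that
image.  The headline scalar is the normalized area under the PCKh(t) curve
over t in [0, 0.5]:

    AUC(pckh) = (1 / 0.5) * integral_0^0.5 pckh(t) dt,   AUC% = 100 * AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Pose

__all__ = ["PCKhCurve", "pckh_at", "pckh_curve", "auc_pckh", "auc_percent",
           "DEFAULT_THRESHOLDS", "evaluate_poses"]

DEFAULT_THRESHOLDS = np.round(np.linspace(0.0, 0.5, 51), 4)


@dataclass
class PCKhCurve:
    thresholds: np.ndarray
    values: np.ndarray  # percentages in [0, 100]

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.thresholds.size != self.values.size or self.thresholds.size < 2:
            raise ValueError("curve needs >= 2 aligned samples")


def _errors_and_scales(predictions, ground_truth):
    if len(predictions) != len(ground_truth) or not predictions:
        raise ValueError("prediction and ground-truth lists must align and "
                         "be non-empty")
    errs, tols, vis = [], [], []
    for pred, gt in zip(predictions, ground_truth):
        l = gt.head_neck_length()
        if l <= 0:
            raise ValueError("ground-truth head-neck length is zero")
        e = np.linalg.norm(pred.keypoints - gt.keypoints, axis=1)
        v = gt.visible
        e = np.where(np.isnan(e), np.inf, e)  # invisible predictions miss
        errs.append(e)
        tols.append(np.full_like(e, l))
        vis.append(v)
    return np.asarray(errs), np.asarray(tols), np.asarray(vis)


def pckh_at(predictions, ground_truth, t: float,
            per_image: bool = False) -> float:
    """PCKh@t as a percentage over all visible ground-truth keypoints.

    By default all keypoints are pooled across images; ``per_image=True``
    averages the per-image percentages instead.
    """
    errs, tols, vis = _errors_and_scales(predictions, ground_truth)
    correct = (errs <= t * tols) & vis
    if per_image:
        per = 100.0 * correct.sum(axis=1) / np.maximum(vis.sum(axis=1), 1)
        return float(per.mean())
    return float(100.0 * correct.sum() / vis.sum())


def pckh_curve(predictions, ground_truth,
               thresholds=DEFAULT_THRESHOLDS) -> PCKhCurve:
    errs, tols, vis = _errors_and_scales(predictions, ground_truth)
    n = vis.sum()
    values = [100.0 * float(((errs <= t * tols) & vis).sum()) / n
              for t in thresholds]
    return PCKhCurve(np.asarray(thresholds), np.asarray(values))


def auc_pckh(curve: PCKhCurve) -> float:
    """Normalized area under the PCKh curve, in [0, 1]."""
    t = curve.thresholds
    if np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    area = np.trapezoid(curve.values / 100.0, t)
    return float(area / (t[-1] - t[0]))


def auc_percent(curve: PCKhCurve) -> float:
    return 100.0 * auc_pckh(curve)


def evaluate_poses(predictions, ground_truth) -> dict:
    """The standard report: PCKh@0.5, PCKh@0.2 and AUC%."""
    curve = pckh_curve(predictions, ground_truth)
    return {
        "PCKh@0.5": pckh_at(predictions, ground_truth, 0.5),
        "PCKh@0.2": pckh_at(predictions, ground_truth, 0.2),
        "AUC%": auc_percent(curve),
    }
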