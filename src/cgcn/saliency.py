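"""Single-ROI occlusion saliency.

One ROI's input column is zeroed at a time and the trained model is
re-evaluated; the accuracy degradation relative to baseline is taken as
that ROI's contribution to the classification.  Occlusion acts on the
model's actual input representation (i.e. after per-record z-scoring, so
"zero" is the ROI's mean level) and never touches the graph or weights.
A full scan over N ROIs costs exactly N + 1 evaluation passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fc_graph import RoiTimeSeries, zscore_record
from .nn import CgcnModel

__all__ = ["SaliencyMap", "occlude_roi", "occlusion_map", "average_saliency"]


@dataclass
class SaliencyMap:
    """Per-ROI accuracy drops from single-ROI occlusion."""

    baseline_accuracy: float
    per_roi_drop: np.ndarray
    n_records: int

    def __post_init__(self) -> None:
        self.per_roi_drop = np.asarray(self.per_roi_drop, dtype=float)
        if np.any(self.per_roi_drop > self.baseline_accuracy + 1e-12):
            raise ValueError("an accuracy drop cannot exceed the baseline accuracy")
        if np.any(self.per_roi_drop < -1 - 1e-12):
            raise ValueError("accuracy drops cannot be below -1")

    @property
    def n_rois(self) -> int:
        return len(self.per_roi_drop)


def occlude_roi(clip: np.ndarray, roi: int) -> np.ndarray:
    """Copy of ``clip`` with column ``roi`` zeroed for all frames."""
    clip = np.asarray(clip)
    if not (0 <= roi < clip.shape[1]):
        raise IndexError(f"roi index {roi} out of range for {clip.shape[1]} ROIs")
    out = clip.copy()
    out[:, roi] = 0.0
    return out


def occlusion_map(model: CgcnModel, records: Sequence[RoiTimeSeries],
                  n_frames: int, classes: Sequence,
                  normalize: bool = True) -> SaliencyMap:
    """Saliency by occluding each ROI in turn over the whole test set.

    ``per_roi_drop[r]`` is baseline accuracy minus the accuracy obtained
    with ROI r zeroed in every test clip; positive values mark ROIs the
    model relies on.
    """
    index = {c: i for i, c in enumerate(classes)}
    clips, truth = [], []
    for r in records:
        if r.n_frames < n_frames:
            raise ValueError(
                f"record {r.subject_id}/{r.session_id} shorter than {n_frames} frames"
            )
        rec = zscore_record(r) if normalize else r
        clips.append(rec.signals[:n_frames])
        truth.append(index[r.class_label])
    truth = np.asarray(truth)
    n_rois = clips[0].shape[1]

    def acc(cs: list[np.ndarray]) -> float:
        probs = model.predict_proba(cs)
        return float(np.mean(probs.argmax(axis=1) == truth))

    baseline = acc(clips)
    drops = np.empty(n_rois)
    for roi in range(n_rois):
        occluded = [occlude_roi(c, roi) for c in clips]
        drops[roi] = baseline - acc(occluded)
    return SaliencyMap(baseline_accuracy=baseline, per_roi_drop=drops,
                       n_records=len(records))


def average_saliency(maps: Sequence[SaliencyMap]) -> SaliencyMap:
    """Entrywise mean of saliency maps (e.g. across CV folds)."""
    if not maps:
        raise ValueError("need at least one saliency map")
    n = maps[0].n_rois
    for m in maps:
        if m.n_rois != n:
            raise ValueError("saliency maps disagree on the number of ROIs")
    drops = np.mean([m.per_roi_drop for m in maps], axis=0)
    baseline = float(np.mean([m.baseline_accuracy for m in maps]))
    return SaliencyMap(baseline_accuracy=baseline, per_roi_drop=drops,
                       n_records=sum(m.n_records for m in maps))
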