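"""Ready-made desk-scale experiments on synthetic cohorts.

These functions reproduce, at laptop scale and on simulated data, the
qualitative findings the architecture was built around: individual
identification from connectome fingerprints, the advantage of
connectivity-defined over random graph neighborhoods, the benefit of more
test frames, and occlusion saliency recovering planted informative ROIs.
They are used by the acceptance suite and the command line, and are the
easiest entry point for exploring the package.

Problem sizes (20 subjects x 2 sessions, 60 ROIs, 300 frames, five conv
layers of widths 8-16, ~15 epochs) are chosen so each experiment runs in
a few minutes on one CPU core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .evaluation import compare_graphs, evaluate
from .fc_graph import (RoiTimeSeries, build_knn_graph, compute_fc, group_fc,
                       zscore_record)
from .nn import CgcnConfig, CgcnModel
from .saliency import occlusion_map
from .synthetic import CohortSpec, generate_cohort
from .training import TrainConfig, make_clips, train_model

__all__ = [
    "identification_cohort_spec",
    "default_model_config",
    "default_train_config",
    "run_identification",
    "run_graph_comparison",
    "run_occlusion",
]


def identification_cohort_spec(seed: int) -> CohortSpec:
    """The standard identification cohort: 20 subjects, 2 sessions, 60 ROIs,
    4 networks, strong fingerprints, no group or site effects."""
    return CohortSpec(seed=seed)


def default_model_config(n_classes: int, l2_lambda: float = 0.0) -> CgcnConfig:
    """Five EdgeConv layers at desk-scale widths, flatten + temporal average."""
    return CgcnConfig(
        n_classes=n_classes,
        n_conv_layers=5,
        features_per_layer=(8, 8, 8, 8, 16),
        temporal_head="average_pool",
        node_pool="flatten",
        l2_lambda=l2_lambda,
    )


def default_train_config(seed: int, max_epochs: int = 15) -> TrainConfig:
    """Adam at 0.01 with small batches (many updates per epoch at this scale)."""
    return TrainConfig(
        clip_length=100,
        batch_size=2,
        max_epochs=max_epochs,
        initial_lr=0.01,
        seed=seed,
    )


def _sessions(records):
    s1 = [r for r in records if r.session_id == "ses00"]
    s2 = [r for r in records if r.session_id == "ses01"]
    return s1, s2


def run_identification(seed: int, k: int = 5,
                       eval_frames: tuple[int, ...] = (1, 5, 10, 30, 100),
                       max_epochs: int = 15) -> dict:
    """Train on session-1 clips, identify subjects from session-2 scans.

    The k-NN graph is built from session-1 (training) records only; each
    record contributes two 100-frame training clips and one validation
    clip.  Returns per-frame-count test accuracies plus the best
    validation accuracy.
    """
    spec = identification_cohort_spec(seed)
    records, _ = generate_cohort(spec)
    for r in records:
        r.class_label = r.subject_id  # identification: the subject is the class
    s1, s2 = _sessions(records)
    s1 = [zscore_record(r) for r in s1]

    graph = build_knn_graph(group_fc([compute_fc(r) for r in s1]), k)
    train_clips, val_clips = [], []
    for r in s1:
        clips = make_clips(r, 100)
        train_clips += clips[:2]
        val_clips += clips[2:]

    model = CgcnModel.initialize(default_model_config(spec.n_subjects), graph,
                                 seed=seed)
    result = train_model(model, train_clips, val_clips,
                         default_train_config(seed, max_epochs))
    accuracies = {}
    for nf in eval_frames:
        report = evaluate(result.best_model, s2, nf, result.classes)
        accuracies[nf] = report.accuracy
    return {"accuracy_by_frames": accuracies,
            "best_val_accuracy": result.best_val_accuracy,
            "classes": result.classes,
            "model": result.best_model}


def run_graph_comparison(seed: int, k: int = 3, n_seeds: int = 3,
                         n_frames: int = 10, max_epochs: int = 15) -> pd.DataFrame:
    """Connectivity vs random graphs on the identification cohort.

    Matched models differ only in the neighborhood graph.  Accuracy is
    measured at a small frame count, where the published comparison shows
    the largest separation between the two graph families.
    """
    spec = identification_cohort_spec(seed)
    records, _ = generate_cohort(spec)
    for r in records:
        r.class_label = r.subject_id
    s1, s2 = _sessions(records)

    def factory(graph, s):
        return CgcnModel.initialize(default_model_config(spec.n_subjects), graph,
                                    seed=s)

    cfg = default_train_config(seed, max_epochs)
    return compare_graphs(s1, s2, factory, cfg, k_values=[k],
                          seeds=[seed + i for i in range(n_seeds)],
                          n_frames=n_frames)


def occlusion_cohort_spec(seed: int) -> CohortSpec:
    """A two-class cohort with a planted diagnostic connectivity difference.

    The class effect perturbs between-network coupling among the
    informative ROIs (the first half of the networks); fingerprints are
    kept mild so the class signal dominates subject idiosyncrasy.
    """
    return CohortSpec(
        n_subjects=24,
        n_sessions_per_subject=2,
        n_rois=40,
        n_networks=4,
        n_frames=300,
        fingerprint_strength=0.2,
        group_effect=0.5,
        n_classes=2,
        seed=seed,
    )


def run_occlusion(seed: int, k: int = 5, n_frames: int = 30,
                  max_epochs: int = 12) -> dict:
    """Occlusion saliency on the two-class cohort.

    Trains on session 1, computes the per-ROI accuracy-drop map on session
    2, and summarizes how well the map recovers the planted informative
    ROIs (median drop contrast and Spearman rank correlation with the
    planted indicator).
    """
    spec = occlusion_cohort_spec(seed)
    records, truth = generate_cohort(spec)
    s1, s2 = _sessions(records)
    s1 = [zscore_record(r) for r in s1]

    graph = build_knn_graph(group_fc([compute_fc(r) for r in s1]), k)
    train_clips, val_clips = [], []
    for r in s1:
        clips = make_clips(r, 100)
        train_clips += clips[:2]
        val_clips += clips[2:]
    model = CgcnModel.initialize(default_model_config(2), graph, seed=seed)
    result = train_model(model, train_clips, val_clips,
                         default_train_config(seed, max_epochs))

    # score occlusion over every n_frames window of the test sessions so the
    # accuracy-drop resolution is fine enough to rank individual ROIs
    windows = []
    for r in s2:
        z = zscore_record(r)
        for start in range(0, r.n_frames - n_frames + 1, n_frames):
            windows.append(RoiTimeSeries(
                subject_id=r.subject_id, session_id=f"{r.session_id}+{start}",
                class_label=r.class_label, site_label=r.site_label,
                signals=z.signals[start:start + n_frames]))
    saliency = occlusion_map(result.best_model, windows, n_frames,
                             result.classes, normalize=False)
    informative = np.zeros(spec.n_rois, dtype=bool)
    informative[truth.informative_rois] = True
    drops = saliency.per_roi_drop
    rho, _ = spearmanr(drops, informative.astype(float))
    return {
        "baseline_accuracy": saliency.baseline_accuracy,
        "median_drop_informative": float(np.median(drops[informative])),
        "median_drop_uninformative": float(np.median(drops[~informative])),
        "spearman_vs_planted": float(rho),
        "saliency": saliency,
        "informative_rois": truth.informative_rois,
    }
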