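"""Test-time evaluation and cross-validation harnesses.

Evaluation mirrors the published protocol: a trained model is scored on
held-out records using the *first* ``n_frames`` frames of each record as a
single clip (from full scans down to a single frame), so accuracy-vs-frames
curves can be traced.  Two cross-validation schemes are provided:

* leave-one-site-out — every acquisition site is held out once; the group
  FC matrix, the k-NN graph and all weights for a fold are derived from the
  other sites' records only, testing cross-site generalization;
* stratified k-fold — subjects (never individual clips, to avoid twin-clip
  leakage) are partitioned with site x class proportions preserved.

``compare_graphs`` trains matched models that differ only in the graph
(connectivity-derived vs random) — the control showing that connectomic
neighborhoods, not graph convolution per se, carry the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fc_graph import (
    KnnGraph,
    RoiTimeSeries,
    build_knn_graph,
    build_random_graph,
    compute_fc,
    group_fc,
    zscore_record,
)
from .nn import CgcnModel
from .training import Clip, TrainConfig, TrainResult, make_clips, train_model

__all__ = [
    "EvalReport",
    "CvReport",
    "evaluate",
    "fit_fold",
    "leave_one_site_out",
    "stratified_kfold",
    "compare_graphs",
]


@dataclass
class EvalReport:
    n_frames_used: int
    accuracy: float
    per_class_accuracy: dict
    n_records: int


@dataclass
class CvReport:
    scheme: str
    per_fold: dict
    mean_accuracy: float
    min_accuracy: float
    max_accuracy: float

    @classmethod
    def from_folds(cls, scheme: str, per_fold: dict) -> "CvReport":
        accs = [r.accuracy for r in per_fold.values()]
        return cls(scheme=scheme, per_fold=per_fold,
                   mean_accuracy=float(np.mean(accs)),
                   min_accuracy=float(np.min(accs)),
                   max_accuracy=float(np.max(accs)))


def evaluate(model: CgcnModel, records: Sequence[RoiTimeSeries], n_frames: int,
             classes: Sequence, normalize: bool = True) -> EvalReport:
    """Accuracy over records, each scored on its first ``n_frames`` frames.

    ``classes`` gives the label order used at training time (class c maps
    to output index i).  Records are z-scored per record by default, the
    same normalization the model saw in training.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be positive")
    index = {c: i for i, c in enumerate(classes)}
    clips, truth = [], []
    for r in records:
        if r.n_frames < n_frames:
            raise ValueError(
                f"record {r.subject_id}/{r.session_id} has {r.n_frames} frames, "
                f"fewer than requested {n_frames}"
            )
        rec = zscore_record(r) if normalize else r
        clips.append(rec.signals[:n_frames])
        truth.append(index[r.class_label])
    probs = model.predict_proba(clips)
    pred = probs.argmax(axis=1)
    truth = np.asarray(truth)
    correct = pred == truth
    per_class = {}
    for c, i in index.items():
        mask = truth == i
        if mask.any():
            per_class[c] = float(np.mean(correct[mask]))
    return EvalReport(n_frames_used=n_frames, accuracy=float(np.mean(correct)),
                      per_class_accuracy=per_class, n_records=len(records))


def _split_train_val(clips: list[Clip], seed: int, val_fraction: float = 0.25
                     ) -> tuple[list[Clip], list[Clip]]:
    """Label-stratified clip-level validation split.

    Every class keeps at least one training clip; classes with a single
    clip stay in training only.
    """
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for i, c in enumerate(clips):
        by_label.setdefault(c.label, []).append(i)
    val_idx: set[int] = set()
    for label in sorted(by_label, key=repr):
        idxs = by_label[label]
        if len(idxs) < 2:
            continue
        order = rng.permutation(len(idxs))
        n_val = max(1, int(round(val_fraction * len(idxs))))
        n_val = min(n_val, len(idxs) - 1)
        val_idx.update(idxs[j] for j in order[:n_val])
    if not val_idx:
        raise ValueError("cannot build a validation split: every class has one clip")
    train = [c for i, c in enumerate(clips) if i not in val_idx]
    val = [c for i, c in enumerate(clips) if i in val_idx]
    return train, val


def fit_fold(train_records: Sequence[RoiTimeSeries],
             model_factory: Callable[[KnnGraph, int], CgcnModel],
             train_cfg: TrainConfig, k: int,
             graph: KnnGraph | None = None,
             normalize: bool = True) -> tuple[TrainResult, KnnGraph]:
    """Train one fold: graph from training records only, then fit the model.

    The group FC matrix and the k-NN graph are rebuilt from
    ``train_records`` exclusively — held-out records can never influence
    the fold's graph or weights.  Pass ``graph`` to reuse a fixed graph
    (e.g. a random control graph).
    """
    recs = [zscore_record(r) for r in train_records] if normalize else list(train_records)
    if graph is None:
        gfc = group_fc([compute_fc(r) for r in recs])
        graph = build_knn_graph(gfc, k)
    clips: list[Clip] = []
    for r in recs:
        clips.extend(make_clips(r, train_cfg.clip_length))
    train_clips, val_clips = _split_train_val(clips, train_cfg.seed)
    model = model_factory(graph, train_cfg.seed)
    result = train_model(model, train_clips, val_clips, train_cfg)
    return result, graph


def leave_one_site_out(records: Sequence[RoiTimeSeries],
                       model_factory: Callable[[KnnGraph, int], CgcnModel],
                       train_cfg: TrainConfig, k: int,
                       n_frames: int | None = None) -> CvReport:
    """One fold per acquisition site; each site is tested on a model trained
    on all other sites' records."""
    sites = sorted({r.site_label for r in records})
    if len(sites) < 2:
        raise ValueError("leave-one-site-out needs at least 2 sites")
    per_fold = {}
    for site in sites:
        train_recs = [r for r in records if r.site_label != site]
        test_recs = [r for r in records if r.site_label == site]
        train_classes = {r.class_label for r in train_recs}
        if len(train_classes) < 2:
            raise ValueError(f"training subset for site {site} has <2 classes")
        if not {r.class_label for r in test_recs} <= train_classes:
            raise ValueError(f"site {site} contains a class absent from training")
        result, _ = fit_fold(train_recs, model_factory, train_cfg, k)
        nf = n_frames or min(r.n_frames for r in test_recs)
        per_fold[site] = evaluate(result.best_model, test_recs, nf, result.classes)
    return CvReport.from_folds("leave_one_site_out", per_fold)


def _stratified_subject_folds(records: Sequence[RoiTimeSeries], n_folds: int,
                              seed: int) -> list[set[str]]:
    """Partition subjects into folds preserving (site x class) proportions."""
    strata: dict[tuple, list[str]] = {}
    seen = set()
    for r in records:
        if r.subject_id not in seen:
            seen.add(r.subject_id)
            strata.setdefault((r.site_label, r.class_label), []).append(r.subject_id)
    smallest = min(len(v) for v in strata.values())
    if n_folds > smallest:
        raise ValueError(
            f"n_folds={n_folds} exceeds the smallest stratum size {smallest}"
        )
    rng = np.random.default_rng(seed)
    folds: list[set[str]] = [set() for _ in range(n_folds)]
    for key in sorted(strata, key=repr):
        members = sorted(strata[key])
        rng.shuffle(members)
        for i, subject in enumerate(members):
            folds[i % n_folds].add(subject)
    return folds


def stratified_kfold(records: Sequence[RoiTimeSeries], n_folds: int,
                     model_factory: Callable[[KnnGraph, int], CgcnModel],
                     train_cfg: TrainConfig, k: int, seed: int,
                     n_frames: int | None = None) -> CvReport:
    """Subject-level stratified k-fold cross-validation.

    All sessions of a subject stay in one fold, and fold (site x class)
    proportions match the cohort's as closely as integer counts allow.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    folds = _stratified_subject_folds(records, n_folds, seed)
    per_fold = {}
    for f, subjects in enumerate(folds):
        test_recs = [r for r in records if r.subject_id in subjects]
        train_recs = [r for r in records if r.subject_id not in subjects]
        result, _ = fit_fold(train_recs, model_factory, train_cfg, k)
        nf = n_frames or min(r.n_frames for r in test_recs)
        per_fold[f"fold{f}"] = evaluate(result.best_model, test_recs, nf, result.classes)
    return CvReport.from_folds("stratified_kfold", per_fold)


def compare_graphs(train_records: Sequence[RoiTimeSeries],
                   test_records: Sequence[RoiTimeSeries],
                   model_factory: Callable[[KnnGraph, int], CgcnModel],
                   train_cfg: TrainConfig,
                   k_values: Sequence[int],
                   seeds: Sequence[int],
                   graph_kinds: Sequence[str] = ("connectivity", "random"),
                   n_frames: int = 100) -> pd.DataFrame:
    """Train matched models differing only in graph construction.

    Returns a tidy table with one row per (graph_kind, k, seed) holding the
    held-out accuracy, mirroring the connectivity-vs-random-graph control.
    """
    rows = []
    for kind in graph_kinds:
        if kind not in ("connectivity", "random"):
            raise ValueError(f"unknown graph kind {kind!r}")
        for k in k_values:
            for seed in seeds:
                cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
                graph = None
                if kind == "random":
                    n = train_records[0].n_rois
                    graph = build_random_graph(n, k, seed=seed)
                result, _ = fit_fold(train_records, model_factory, cfg, k, graph=graph)
                report = evaluate(result.best_model, test_records, n_frames,
                                  result.classes)
                rows.append({"graph_kind": kind, "k": k, "seed": seed,
                             "accuracy": report.accuracy})
    return pd.DataFrame(rows)
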