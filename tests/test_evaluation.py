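import numpy as np
import pytest

from cgcn.evaluation import (
    _stratified_subject_folds,
    compare_graphs,
    evaluate,
    leave_one_site_out,
    stratified_kfold,
)
from cgcn.fc_graph import RoiTimeSeries
from cgcn.nn import CgcnConfig, CgcnModel
from cgcn.training import TrainConfig


class StubModel:
    """Deterministic fake classifier for harness tests."""

    def __init__(self, n_classes, mode="oracle", class_of=None):
        self.n_classes = n_classes
        self.mode = mode
        self.class_of = class_of or {}
        self.calls = 0

    def predict_proba(self, clips):
        self.calls += 1
        out = np.full((len(clips), self.n_classes), 1.0 / self.n_classes)
        if self.mode == "oracle":
            for i, c in enumerate(clips):
                out[i] = 0.0
                out[i, self.class_of[id(c)]] = 1.0
        return out


def _records(rng, n_subjects=6, n_sessions=2, n_frames=60, n_rois=8,
             n_classes=2, n_sites=2):
    records = []
    for s in range(n_subjects):
        for sess in range(n_sessions):
            records.append(RoiTimeSeries(
                subject_id=f"sub{s}", session_id=f"ses{sess}",
                class_label=s % n_classes,
                site_label=f"site{(s // n_classes) % n_sites}",
                signals=rng.standard_normal((n_frames, n_rois))))
    return records


class TestEvaluate:
    def test_oracle_stub_scores_one(self, rng):
        records = _records(rng)
        labels = [r.class_label for r in records]

        class Oracle(StubModel):
            def predict_proba(self, clips):  # clips arrive in record order
                out = np.zeros((len(clips), 2))
                out[np.arange(len(clips)), labels] = 1.0
                return out

        report = evaluate(Oracle(2), records, 30, classes=[0, 1])
        assert report.accuracy == 1.0
        assert all(v == 1.0 for v in report.per_class_accuracy.values())

    def test_uniform_stub_scores_class_zero_prevalence(self, rng):
        records = _records(rng)
        labels = [r.class_label for r in records]
        report = evaluate(StubModel(2, "uniform"), records, 30, classes=[0, 1])
        # uniform probabilities argmax to index 0
        assert report.accuracy == pytest.approx(labels.count(0) / len(labels))
        assert report.n_frames_used == 30
        assert report.per_class_accuracy[0] == pytest.approx(1.0)
        assert report.per_class_accuracy[1] == pytest.approx(0.0)

    def test_single_frame_is_legal(self, rng):
        records = _records(rng)
        report = evaluate(StubModel(2, "uniform"), records, 1, classes=[0, 1])
        assert report.n_frames_used == 1

    def test_record_shorter_than_requested_raises(self, rng):
        records = _records(rng, n_frames=20)
        with pytest.raises(ValueError, match="fewer"):
            evaluate(StubModel(2, "uniform"), records, 30, classes=[0, 1])


def _factory(graph, seed):
    cfg = CgcnConfig(n_classes=2, n_conv_layers=2, features_per_layer=(3, 4))
    return CgcnModel.initialize(cfg, graph, seed=seed)


_FAST = dict(clip_length=30, batch_size=4, max_epochs=2, initial_lr=0.01)


class TestLeaveOneSiteOut:
    def test_two_sites_give_two_folds(self, tiny_cohort):
        _, records, _ = tiny_cohort
        report = leave_one_site_out(records, _factory,
                                    TrainConfig(**_FAST, seed=0), k=3,
                                    n_frames=30)
        assert report.scheme == "leave_one_site_out"
        assert set(report.per_fold) == {"site00", "site01"}
        accs = [r.accuracy for r in report.per_fold.values()]
        assert report.mean_accuracy == pytest.approx(np.mean(accs))
        assert report.min_accuracy == min(accs)
        assert report.max_accuracy == max(accs)

    def test_mutating_held_out_records_leaves_trained_weights_unchanged(self, tiny_cohort):
        _, records, _ = tiny_cohort
        site0_train = [r for r in records if r.site_label != "site00"]

        captured = []

        def capturing_factory(graph, seed):
            m = _factory(graph, seed)
            captured.append(m)
            return m

        def run(mutate):
            recs = [RoiTimeSeries(r.subject_id, r.session_id, r.class_label,
                                  r.site_label, r.signals.copy())
                    for r in records]
            if mutate:
                for r in recs:
                    if r.site_label == "site00":
                        r.signals += 99.0  # corrupt the held-out site only
            captured.clear()
            leave_one_site_out(recs, capturing_factory,
                               TrainConfig(**_FAST, seed=0), k=3, n_frames=30)
            # first fold holds out site00, trained on the rest
            return {k: v.copy() for k, v in captured[0].params.items()}

        w_clean = run(mutate=False)
        w_dirty = run(mutate=True)
        assert all(np.array_equal(w_clean[k], w_dirty[k]) for k in w_clean)

    def test_single_site_is_rejected(self, rng):
        records = _records(rng, n_sites=1)
        with pytest.raises(ValueError, match="2 sites"):
            leave_one_site_out(records, _factory, TrainConfig(**_FAST, seed=0),
                               k=3)


class TestStratifiedKfold:
    def test_folds_partition_subjects_evenly(self, rng):
        records = _records(rng, n_subjects=20, n_classes=1, n_sites=1)
        folds = _stratified_subject_folds(records, 10, seed=0)
        assert all(len(f) == 2 for f in folds)
        union = set().union(*folds)
        assert union == {f"sub{i}" for i in range(20)}

    def test_fold_proportions_match_strata(self, rng):
        records = _records(rng, n_subjects=12, n_classes=2, n_sites=2)
        folds = _stratified_subject_folds(records, 3, seed=1)
        strata = {}
        for r in records:
            strata.setdefault(r.subject_id, (r.site_label, r.class_label))
        for fold in folds:
            per = {}
            for s in fold:
                per[strata[s]] = per.get(strata[s], 0) + 1
            assert all(v == 1 for v in per.values())  # 12 subjects, 4 strata, 3 folds

    def test_no_subject_straddles_folds_across_seeds(self, rng):
        records = _records(rng, n_subjects=9, n_classes=1, n_sites=1)
        for seed in range(20):
            folds = _stratified_subject_folds(records, 3, seed=seed)
            assert sum(len(f) for f in folds) == len(set().union(*folds))

    def test_partition_is_reproducible_from_seed(self, rng):
        records = _records(rng, n_subjects=10)
        a = _stratified_subject_folds(records, 2, seed=3)
        b = _stratified_subject_folds(records, 2, seed=3)
        assert a == b

    def test_too_many_folds_raise(self, rng):
        records = _records(rng, n_subjects=4, n_classes=2, n_sites=2)
        with pytest.raises(ValueError, match="stratum"):
            _stratified_subject_folds(records, 3, seed=0)

    def test_end_to_end_kfold_report(self, tiny_cohort):
        _, records, _ = tiny_cohort
        report = stratified_kfold(records, 2, _factory,
                                  TrainConfig(**_FAST, seed=0), k=3, seed=0,
                                  n_frames=30)
        assert len(report.per_fold) == 2
        tested = [r.n_records for r in report.per_fold.values()]
        assert sum(tested) == len(records)


class TestCompareGraphs:
    def test_table_shape_and_determinism(self, tiny_cohort):
        _, records, _ = tiny_cohort
        s1 = [r for r in records if r.session_id == "ses00"]
        s2 = [r for r in records if r.session_id == "ses01"]
        cfg = TrainConfig(**_FAST, seed=0)
        table = compare_graphs(s1, s2, _factory, cfg, k_values=[2, 3],
                               seeds=[0], n_frames=30)
        assert len(table) == 4  # 2 kinds x 2 k x 1 seed
        assert set(table["graph_kind"]) == {"connectivity", "random"}
        again = compare_graphs(s1, s2, _factory, cfg, k_values=[2, 3],
                               seeds=[0], n_frames=30)
        assert np.allclose(table["accuracy"], again["accuracy"])
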