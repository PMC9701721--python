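"""Loss, metrics, fold construction and the training loop."""

import numpy as np
import pytest

from preictal.models import ModelSpec, build_model

from preictal.traineval import (METRIC_NAMES, Standardizer, TrainConfig,
                                compute_metrics, cross_entropy,
                                make_loo_folds, predict_scores, prepare_views,
                                roc_auc, train)


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        assert cross_entropy(1, 1.0) == pytest.approx(0.0, abs=1e-6)
        assert cross_entropy(0, 0.0) == pytest.approx(0.0, abs=1e-6)

    def test_half_confidence_is_ln2(self):
        assert cross_entropy(0, 0.5) == pytest.approx(np.log(2), rel=1e-9)
        assert cross_entropy(1, 0.5) == pytest.approx(np.log(2), rel=1e-9)

    def test_confident_error_clipped_to_minus_ln_eps(self):
        assert cross_entropy(1, 0.0) == pytest.approx(-np.log(1e-7), rel=1e-6)

    def test_matches_formula_pointwise(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 50)
        p = rng.uniform(0.01, 0.99, 50)
        got = cross_entropy(y, p, reduce=False)
        want = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        np.testing.assert_allclose(got, want, rtol=1e-12)


class TestComputeMetrics:
    def test_worked_confusion_table(self):
        # TP=3, FP=1, FN=1, TN=5 at threshold 0.5
        labels = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.1, 0.2, 0.3, 0.4]
        r = compute_metrics(labels, scores)
        assert (r.tp, r.fp, r.fn, r.tn) == (3, 1, 1, 5)
        assert r.acc == pytest.approx(0.8)
        assert r.sen == pytest.approx(0.75)
        assert r.spe == pytest.approx(5 / 6)
        assert r.precision == pytest.approx(0.75)
        assert r.f1 == pytest.approx(0.75)

    def test_tie_at_threshold_counts_positive(self):
        r = compute_metrics([1, 0], [0.5, 0.5])
        assert (r.tp, r.fp) == (1, 1)

    def test_perfect_separation(self):
        labels = [0] * 5 + [1] * 5
        scores = [0.1, 0.2, 0.1, 0.3, 0.2, 0.8, 0.9, 0.7, 0.95, 0.85]
        r = compute_metrics(labels, scores)
        assert r.auc == pytest.approx(1.0)
        assert r.acc == r.sen == r.spe == 1.0

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(42)
        labels = rng.integers(0, 2, 4000)
        scores = rng.uniform(size=4000)
        r = compute_metrics(labels, scores)
        assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_degenerate_denominator_flagged_zero(self):
        r = compute_metrics([0, 0], [0.1, 0.2])  # no positives at all
        assert r.sen == 0.0 and r.precision == 0.0 and r.f1 == 0.0
        assert r.degenerate

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])

    def test_counts_partition_test_set(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 257)
        scores = rng.uniform(size=257)
        r = compute_metrics(labels, scores)
        assert r.tp + r.tn + r.fp + r.fn == 257

    def test_auc_matches_sklearn_and_is_rank_invariant(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(2)
        for _ in range(20):
            labels = rng.integers(0, 2, 100)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.uniform(size=100), 1)  # force ties
            ours = roc_auc(labels, scores)
            assert ours == pytest.approx(roc_auc_score(labels, scores),
                                         abs=1e-12)
            assert roc_auc(labels, np.exp(3 * scores)) == pytest.approx(
                ours, abs=1e-12)


class TestFolds:
    def test_each_preictal_block_tested_once(self, small_segments):
        folds = make_loo_folds(small_segments, seed=0)
        assert len(folds) == 4
        tested = []
        for f in folds:
            blocks = np.unique(
                small_segments.block_id[f.test_idx][
                    small_segments.y[f.test_idx] == 1])
            assert len(blocks) == 1
            tested.append(blocks[0])
        assert sorted(tested) == [1, 2, 3, 4]

    def test_no_leakage(self, small_segments):
        for f in make_loo_folds(small_segments, seed=0):
            trval = np.concatenate([f.train_idx, f.val_idx])
            assert np.intersect1d(f.test_idx, trval).size == 0
            assert np.intersect1d(f.train_idx, f.val_idx).size == 0
            union = np.union1d(np.union1d(f.train_idx, f.val_idx), f.test_idx)
            assert union.size == len(small_segments)

    def test_val_fraction_within_one_segment(self, small_segments):
        for f in make_loo_folds(small_segments, seed=0):
            n_rest = len(f.train_idx) + len(f.val_idx)
            assert abs(len(f.val_idx) - 0.2 * n_rest) <= 1.0

    def test_val_split_stratified(self, small_segments):
        for f in make_loo_folds(small_segments, seed=0):
            y_val = small_segments.y[f.val_idx]
            y_rest = small_segments.y[np.concatenate([f.train_idx,
                                                      f.val_idx])]
            assert abs(y_val.mean() - y_rest.mean()) < 0.05

    def test_fewer_than_three_blocks_rejected(self, small_segments):
        crippled = small_segments.subset(
            (small_segments.y == 0)
            | (small_segments.block_id <= 2))
        with pytest.raises(ValueError, match="three seizures"):
            make_loo_folds(crippled, seed=0)


def _blob_views(n=120, n_ch=4, m=16, sep=3.0, seed=0):
    """Two Gaussian blobs rendered as segment views: class 1 gets a mean
    offset in both the raw and the tensor view."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    raw = rng.standard_normal((n, m, n_ch)).astype(np.float32)
    tensor = rng.standard_normal((n, 2, n_ch, n_ch)).astype(np.float32)
    raw[y == 1] += sep / 2
    tensor[y == 1] += sep / 2
    order = rng.permutation(n)
    return {"raw": raw[order], "tensor": tensor[order], "y": y[order]}


def _tiny_spec(kind="multiframe"):
    return ModelSpec(kind=kind, n_channels=4, seq_len=16,
                     conv_filters=(4, 8, 8), lstm_units=8)


class TestTrain:
    def test_separable_blobs_learned(self):
        tr = _blob_views(seed=0)
        va = _blob_views(n=60, seed=1)
        model = build_model(_tiny_spec(), seed=0)
        cfg = TrainConfig(batch_size=32, learning_rate=3e-3, max_epochs=12,
                          patience=12, seed=0)
        hist = train(model, tr, va, cfg)
        assert hist["train_loss"][4] < hist["train_loss"][0]
        scores = predict_scores(model, va)
        acc = ((scores >= 0.5).astype(int) == va["y"]).mean()
        assert acc > 0.95

    def test_zero_learning_rate_leaves_parameters(self):
        tr = _blob_views(seed=2)
        model = build_model(_tiny_spec(), seed=0)
        before = [p.copy() for l, n in model.param_handles()
                  for p in [l.params[n]]]
        cfg = TrainConfig(batch_size=32, learning_rate=0.0, max_epochs=1,
                          patience=1, seed=0)
        train(model, tr, _blob_views(n=40, seed=3), cfg)
        after = [l.params[n] for l, n in model.param_handles()]
        for b, a in zip(before, after):
            assert np.array_equal(b, a)

    def test_training_deterministic_under_seed(self):
        tr = _blob_views(seed=4)
        va = _blob_views(n=40, seed=5)
        cfg = TrainConfig(batch_size=32, learning_rate=1e-3, max_epochs=3,
                          patience=3, seed=7)
        weights = []
        for _ in range(2):
            model = build_model(_tiny_spec(), seed=1)
            train(model, tr, va, cfg)
            weights.append([l.params[n].copy()
                            for l, n in model.param_handles()])
        for a, b in zip(*weights):
            assert np.array_equal(a, b)

    def test_single_class_training_rejected(self):
        tr = _blob_views(seed=6)
        tr["y"][:] = 1
        model = build_model(_tiny_spec(), seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(model, tr, tr, TrainConfig(seed=0))


class TestStandardizer:
    def test_train_statistics_applied(self):
        views = _blob_views(seed=8)
        sc = Standardizer.fit(views)
        out = sc.apply(views)
        assert np.allclose(out["raw"].mean(axis=(0, 1)), 0, atol=1e-4)
        assert np.allclose(out["raw"].std(axis=(0, 1)), 1, atol=1e-3)
        assert np.allclose(out["tensor"].mean(axis=(0, 2, 3)), 0, atol=1e-4)

    def test_prepare_views_time_major(self, small_segments):
        views = prepare_views(small_segments)
        s, n, m = small_segments.raw.shape
        assert views["raw"].shape == (s, m, n)
        assert np.allclose(views["raw"][0, :, 2],
                           small_segments.raw[0, 2, :], atol=1e-6)


@pytest.fixture(scope="module")
def tiny_segments():
    from preictal.pipeline import build_segments, config_for_synth
    from preictal.synthio import SynthSpec, generate_subject
    spec = SynthSpec(n_channels=4, fs=32, n_seizures=3,
                     interictal_minutes_per_block=2, preictal_minutes=0.5,
                     effect_size=1.0, seed=21)
    return build_segments(generate_subject(spec),
                          config_for_synth(spec, balance_seed=2))


@pytest.fixture(scope="module")
def tiny_cfg():
    return TrainConfig(batch_size=32, learning_rate=1e-3, max_epochs=2,
                       patience=2, seed=5)


class TestLooEvaluate:
    def test_means_are_arithmetic_fold_means(self, tiny_segments, tiny_cfg):
        from preictal.traineval import loo_evaluate
        spec = ModelSpec(kind="cnn", n_channels=4, seq_len=32,
                         conv_filters=(2, 4, 4), lstm_units=8)
        report = loo_evaluate(tiny_segments, spec, tiny_cfg)
        assert len(report.folds) == 3
        for m in METRIC_NAMES:
            vals = [getattr(f, m) for f in report.folds]
            assert report.means()[m] == pytest.approx(np.mean(vals))
        frame = report.to_frame()
        assert list(frame["fold_id"]) == [1, 2, 3, "mean"]

    def test_rerun_reproduces_report(self, tiny_segments, tiny_cfg):
        from preictal.traineval import loo_evaluate
        spec = ModelSpec(kind="lstm", n_channels=4, seq_len=32,
                         lstm_units=8)
        a = loo_evaluate(tiny_segments, spec, tiny_cfg)
        b = loo_evaluate(tiny_segments, spec, tiny_cfg)
        assert a.means() == b.means()


class TestRunAblation:
    def test_table_structure_and_deltas(self, tiny_segments, tiny_cfg):
        from preictal.traineval import run_ablation
        specs = {k: ModelSpec(kind=k, n_channels=4, seq_len=32,
                              conv_filters=(2, 4, 4), lstm_units=8)
                 for k in ("cnn", "multiframe")}
        result = run_ablation(tiny_segments, specs, tiny_cfg, n_seeds=2)
        assert len(result.runs) == 4  # 2 models x 2 seeds
        assert set(result.runs["model"]) == {"cnn", "multiframe"}
        assert set(result.runs["seed"]) == {5, 6}
        assert result.summary.shape == (4, len(METRIC_NAMES))
        deltas = result.deltas("multiframe")
        mf = result.runs[result.runs.model == "multiframe"]["auc"].mean()
        cnn = result.runs[result.runs.model == "cnn"]["auc"].mean()
        assert deltas.loc["cnn", "auc"] == pytest.approx(mf - cnn)

    def test_mismatched_shapes_rejected(self, tiny_segments, tiny_cfg):
        from preictal.traineval import run_ablation
        specs = {"cnn": ModelSpec(kind="cnn", n_channels=4, seq_len=32,
                                  conv_filters=(2, 4, 4)),
                 "lstm": ModelSpec(kind="lstm", n_channels=8, seq_len=32)}
        with pytest.raises(ValueError, match="share"):
            run_ablation(tiny_segments, specs, tiny_cfg)
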