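"""Training, leave-one-seizure-out evaluation, metrics, and the ablation.

The evaluation protocol is patient-specific leave-one-seizure-out
cross-validation: with K pre-ictal blocks (one per seizure), fold k holds
out all segments of pre-ictal block k together with the inter-ictal block
paired with it; the remaining segments are split 80%/20% into training and
validation sets, stratified by class.  Per-fold confusion counts yield
accuracy, sensitivity (recall), specificity, precision and F1, plus the
trapezoidal ROC AUC; the subject-level result is the arithmetic mean over
folds.

The paper-setting optimizer is Adam with batch size 512 and learning rate
3e-4; both are configurable, and the batch size is automatically capped at
the training-set size for small runs.  Early stopping watches validation
loss with a patience window and restores the best checkpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import ModelSpec, SegmentClassifier, build_model
from .nn import softmax_cross_entropy
from .preprocess import SegmentSet

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "FoldReport", "SubjectReport", "Fold", "AblationResult",
    "cross_entropy", "prepare_views", "Standardizer", "train",
    "make_loo_folds", "compute_metrics", "loo_evaluate", "run_ablation",
    "METRIC_NAMES",
]

METRIC_NAMES = ("acc", "sen", "spe", "precision", "f1", "auc")


@dataclass
class TrainConfig:
    """Optimizer settings; defaults are the reference training setting."""
    batch_size: int = 512
    learning_rate: float = 3e-4
    optimizer: str = "adam"
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


def cross_entropy(y_true, p_hat, eps: float = 1e-7, reduce: bool = True):
    """Binary cross-entropy  l(y, p) = -[y log p + (1-y) log(1-p)].

    ``p_hat`` is the predicted probability of the positive (pre-ictal)
    class, clipped to [eps, 1-eps] so the loss stays finite.  With
    ``reduce`` the mean over samples is returned.
    """
    y = np.asarray(y_true, dtype=float)
    p = np.clip(np.asarray(p_hat, dtype=float), eps, 1.0 - eps)
    losses = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(losses.mean()) if reduce else losses


# ---------------------------------------------------------------------------
# Data views and standardization
# ---------------------------------------------------------------------------

def prepare_views(segs: SegmentSet, dtype=np.float32) -> dict[str, np.ndarray]:
    """Both model inputs for a segment set.

    ``"tensor"`` is the (S, 2, N, N) instance view; ``"raw"`` is the
    (S, M, N) sequence view — the segment matrix transposed so its columns
    are consumed in time order.
    """
    return {
        "tensor": segs.tensor.astype(dtype),
        "raw": segs.raw.transpose(0, 2, 1).astype(dtype),
        "y": segs.y.copy(),
    }


@dataclass
class Standardizer:
    """Input scaling fitted on the training split only.

    The raw view gets per-channel standardization (EEG amplitudes are on an
    arbitrary microvolt scale); each tensor plane gets a scalar
    standardization (the correlation plane is already bounded, the PCA-score
    plane scales with signal amplitude).  Fitting on the training split and
    applying everywhere keeps folds leakage-free.
    """
    raw_mean: np.ndarray = field(default=None)
    raw_sd: np.ndarray = field(default=None)
    plane_mean: np.ndarray = field(default=None)
    plane_sd: np.ndarray = field(default=None)

    @classmethod
    def fit(cls, views: dict[str, np.ndarray]) -> "Standardizer":
        raw, tensor = views["raw"], views["tensor"]
        raw_sd = raw.std(axis=(0, 1))
        plane_sd = tensor.std(axis=(0, 2, 3))
        return cls(
            raw_mean=raw.mean(axis=(0, 1)),
            raw_sd=np.where(raw_sd > 0, raw_sd, 1.0),
            plane_mean=tensor.mean(axis=(0, 2, 3)),
            plane_sd=np.where(plane_sd > 0, plane_sd, 1.0))

    def apply(self, views: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = dict(views)
        out["raw"] = (views["raw"] - self.raw_mean) / self.raw_sd
        out["tensor"] = ((views["tensor"]
                          - self.plane_mean[None, :, None, None])
                         / self.plane_sd[None, :, None, None])
        return out


def _take(views: dict[str, np.ndarray], idx: np.ndarray) -> dict[str, np.ndarray]:
    return {k: v[idx] for k, v in views.items()}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _batched_logits(model: SegmentClassifier, views: dict[str, np.ndarray],
                    batch: int = 256) -> np.ndarray:
    n = len(views["y"])
    out = np.empty((n, 2), dtype=np.float64)
    for a in range(0, n, batch):
        sl = slice(a, min(a + batch, n))
        out[sl] = model.forward(
            {"tensor": views["tensor"][sl], "raw": views["raw"][sl]},
            train=False)
    return out


def predict_scores(model: SegmentClassifier,
                   views: dict[str, np.ndarray]) -> np.ndarray:
    """Predicted pre-ictal probability per segment, inference mode."""
    from .nn import softmax
    return softmax(_batched_logits(model, views))[:, 1]


def train(model: SegmentClassifier, train_views: dict[str, np.ndarray],
          val_views: dict[str, np.ndarray], cfg: TrainConfig) -> dict:
    """Fit a model by minimizing mean cross-entropy with Adam.

    Tracks per-epoch train/validation loss, stops early when validation
    loss has not improved for ``cfg.patience`` epochs, and restores the
    best-validation-loss parameters.  Fully deterministic under
    ``cfg.seed`` (shuffling) plus the model's own build seed (init and
    dropout masks).
    """
    from .nn import Adam

    y_train = train_views["y"]
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    n = len(y_train)
    batch = min(cfg.batch_size, n)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.param_handles(), lr=cfg.learning_rate)

    history = {"train_loss": [], "val_loss": []}
    best_state, best_val, wait = None, np.inf, 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for a in range(0, n, batch):
            idx = order[a:a + batch]
            logits = model.forward(
                {"tensor": train_views["tensor"][idx],
                 "raw": train_views["raw"][idx]}, train=True)
            loss, _, dlogits = softmax_cross_entropy(logits, y_train[idx])
            model.backward(dlogits.astype(model.dtype))
            opt.step()
            losses.append(loss)
        val_logits = _batched_logits(model, val_views)
        val_loss, _, _ = softmax_cross_entropy(val_logits, val_views["y"])
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-6:
            best_val, best_state, wait = val_loss, model.state_dict(), 0
        else:
            wait += 1
            if wait > cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    history["best_val_loss"] = best_val
    return history


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class Fold:
    fold_id: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


def make_loo_folds(segs: SegmentSet, val_fraction: float = 0.2,
                   seed: int = 0) -> list[Fold]:
    """Leave-one-seizure-out folds over a balanced segment set.

    With K pre-ictal blocks, fold k's test set is every segment of pre-ictal
    block k plus the k-th of K contiguous-in-time chunks of the inter-ictal
    segments (the recordings carry no natural one-to-one pairing of
    inter-ictal stretches to seizures, so contiguous chunking in time order
    is used).  The remaining segments are split into train/validation at the
    segment level, stratified by class, with ``val_fraction`` held out.
    No test-block segment ever appears in train or validation.
    """
    pre_blocks = np.unique(segs.block_id[segs.y == 1])
    k = len(pre_blocks)
    if k < 3:
        raise ValueError(
            f"found {k} pre-ictal blocks; leave-one-seizure-out evaluation "
            "requires subjects with at least three seizures")
    inter_idx = np.flatnonzero(segs.y == 0)
    inter_idx = inter_idx[np.argsort(segs.t0_s[inter_idx], kind="stable")]
    inter_chunks = np.array_split(inter_idx, k)

    rng = np.random.default_rng(seed)
    folds = []
    all_idx = np.arange(len(segs))
    for i, block in enumerate(pre_blocks):
        test = np.sort(np.concatenate([
            np.flatnonzero((segs.y == 1) & (segs.block_id == block)),
            inter_chunks[i]]))
        rest = np.setdiff1d(all_idx, test, assume_unique=False)
        val_parts = []
        for cls in (0, 1):
            cls_idx = rest[segs.y[rest] == cls]
            n_val = int(round(val_fraction * len(cls_idx)))
            val_parts.append(rng.permutation(cls_idx)[:n_val])
        val = np.sort(np.concatenate(val_parts))
        tr = np.setdiff1d(rest, val)
        folds.append(Fold(fold_id=i + 1, train_idx=tr, val_idx=val,
                          test_idx=test))
    return folds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class FoldReport:
    """Confusion counts and derived metrics for one fold (positives =
    pre-ictal)."""
    fold_id: int
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    precision: float
    f1: float
    auc: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"fold_id": self.fold_id, "tp": self.tp, "tn": self.tn,
                "fp": self.fp, "fn": self.fn,
                **{m: getattr(self, m) for m in METRIC_NAMES},
                "degenerate": self.degenerate}


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the empirical ROC curve by trapezoidal integration over
    all score thresholds (ties grouped)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tps = np.cumsum(y == 1)[distinct]
    fps = np.cumsum(y == 0)[distinct]
    n_pos, n_neg = tps[-1], fps[-1]
    if n_pos == 0 or n_neg == 0:
        return 0.0
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return float(np.trapezoid(tpr, fpr))


def compute_metrics(labels, scores, threshold: float = 0.5,
                    fold_id: int = 0) -> FoldReport:
    """Confusion counts at ``threshold`` (ties count as positive) and the
    derived metric suite.  Degenerate denominators yield a defined 0 and
    set the ``degenerate`` flag."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("cannot compute metrics on an empty test set")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    acc, d0 = _safe_div(tp + tn, tp + tn + fp + fn)
    sen, d1 = _safe_div(tp, tp + fn)
    spe, d2 = _safe_div(tn, tn + fp)
    precision, d3 = _safe_div(tp, tp + fp)
    f1, d4 = _safe_div(2.0 * sen * precision, sen + precision)
    degenerate = any((d0, d1, d2, d3, d4))
    if degenerate:
        logger.warning("fold %d: degenerate confusion denominator "
                       "(tp=%d tn=%d fp=%d fn=%d)", fold_id, tp, tn, fp, fn)
    return FoldReport(fold_id=fold_id, tp=tp, tn=tn, fp=fp, fn=fn, acc=acc,
                      sen=sen, spe=spe, precision=precision, f1=f1,
                      auc=roc_auc(labels, scores), degenerate=degenerate)


@dataclass
class SubjectReport:
    """Per-fold reports plus their arithmetic means."""
    subject_id: str
    folds: list[FoldReport]

    def means(self) -> dict[str, float]:
        return {m: float(np.mean([getattr(f, m) for f in self.folds]))
                for m in METRIC_NAMES}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([f.to_dict() for f in self.folds])
        mean_row = {"fold_id": "mean", **self.means()}
        return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


# ---------------------------------------------------------------------------
# Leave-one-seizure-out evaluation and ablation
# ---------------------------------------------------------------------------

def _fold_seed(base: int, *parts: int) -> int:
    return int(np.random.SeedSequence([base, *parts]).generate_state(1)[0]
               % (2 ** 31))


def loo_evaluate(segs: SegmentSet, model_spec: ModelSpec, cfg: TrainConfig,
                 return_models: bool = False):
    """Train and test one architecture over every leave-one-seizure-out fold.

    Each fold fits its own input standardizer on the training split, builds
    a freshly initialized model (seeded from ``cfg.seed`` and the fold id),
    trains with early stopping, and scores the held-out blocks.
    """
    views = prepare_views(segs)
    folds = make_loo_folds(segs, seed=_fold_seed(cfg.seed, 0x5EED))
    reports, models = [], []
    for fold in folds:
        train_v = _take(views, fold.train_idx)
        scaler = Standardizer.fit(train_v)
        train_v = scaler.apply(train_v)
        val_v = scaler.apply(_take(views, fold.val_idx))
        test_v = scaler.apply(_take(views, fold.test_idx))
        model = build_model(model_spec,
                            seed=_fold_seed(cfg.seed, fold.fold_id))
        fold_cfg = replace(cfg, seed=_fold_seed(cfg.seed, fold.fold_id, 2))
        train(model, train_v, val_v, fold_cfg)
        scores = predict_scores(model, test_v)
        reports.append(compute_metrics(test_v["y"], scores,
                                       fold_id=fold.fold_id))
        if return_models:
            models.append(model)
    report = SubjectReport(subject_id=segs.subject_id, folds=reports)
    return (report, models) if return_models else report


@dataclass
class AblationResult:
    """Per-run metric means and their per-model aggregation."""
    runs: pd.DataFrame      # one row per (model, seed)
    summary: pd.DataFrame   # mean and sd per model x metric

    def deltas(self, reference: str = "multiframe") -> pd.DataFrame:
        """Mean-metric differences (reference minus each other model)."""
        means = self.summary.xs("mean", level=1)
        return means.loc[reference] - means.drop(index=reference)


def run_ablation(segs: SegmentSet, specs: dict[str, ModelSpec],
                 cfg: TrainConfig, n_seeds: int = 1) -> AblationResult:
    """Evaluate several architectures side by side on one subject.

    Runs :func:`loo_evaluate` once per (model, seed) — seeds are
    ``cfg.seed .. cfg.seed + n_seeds - 1`` — and aggregates the per-subject
    mean metrics into a per-model mean and standard deviation table.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    shapes = {(s.n_channels, s.seq_len) for s in specs.values()}
    if len(shapes) > 1:
        raise ValueError("all model specs must share n_channels and seq_len")
    rows = []
    for name, spec in specs.items():
        for k in range(n_seeds):
            run_cfg = replace(cfg, seed=cfg.seed + k)
            report = loo_evaluate(segs, spec, run_cfg)
            rows.append({"model": name, "seed": run_cfg.seed,
                         **report.means()})
    runs = pd.DataFrame(rows)
    summary = runs.drop(columns="seed").groupby("model").agg(["mean", "std"])
    summary.columns.names = ["metric", "stat"]
    summary = summary.stack(level="stat", future_stack=True)
    summary.index.names = ["model", "stat"]
    return AblationResult(runs=runs, summary=summary)
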