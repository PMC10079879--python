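"""Training loop, cross-validation protocols, metrics and experiment runners.

Training follows the published recipe: minibatch Adam (batch 64, learning
rate 1e-3) on cross-entropy + L1 loss, with early stopping monitored on a
held-out slice of the training data.  Evaluation reports accuracy,
sensitivity and specificity as percentages; for more than two classes,
sensitivity/specificity are macro-averaged one-vs-rest and the accuracy is
pooled over the one-vs-rest counts (the plain fraction-correct is reported
alongside).  Protocols: shuffled k-fold over segments and
leave-one-subject-out over subjects, plus runners for the stage-ablation
grid and the segment-length sweep.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from . import autograd as ag
from .autograd import Adam, Tensor
from .datasets import RecordingSet, SegmentBatch, segment_trials
from .decoder import loss as loss_fn
from .encoder import combo_name
from .model import EEGformer, ModelConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  val_fraction of the training set is held out
    to monitor early stopping (0 disables it); patience counts epochs
    without a min_delta improvement of validation loss."""

    batch_size: int = 64
    lr: float = 0.001
    max_epochs: int = 100
    patience: int = 20
    min_delta: float = 1e-4
    val_fraction: float = 0.1
    seed: int = 0
    target_train_acc: float | None = None  # stop once training acc reaches this

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr < 0:
            raise ValueError("lr must be >= 0")


def train(model: EEGformer, segments: np.ndarray, labels: np.ndarray,
          cfg: TrainConfig = TrainConfig()) -> dict:
    """Train `model` in place; returns a history dict with per-epoch
    train/validation loss and accuracy.  Fully deterministic given cfg.seed
    (and the model's init seed)."""
    x = np.asarray(segments, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if len(x) != len(y):
        raise ValueError("segments and labels must align")
    if y.max(initial=0) >= model.cfg.n_classes:
        raise ValueError("label outside the model's class range")
    rng = np.random.default_rng(cfg.seed)

    n_val = int(round(cfg.val_fraction * len(x)))
    perm = rng.permutation(len(x))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[tr_idx], y[tr_idx]

    params = model.parameters()
    opt = Adam(params, lr=cfg.lr)
    lam = model.cfg.lambda_l1
    history: dict = {"train_loss": [], "train_acc": [],
                     "val_loss": [], "val_acc": []}
    best_val = np.inf
    best_state = None
    stale = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(xt))
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, len(xt), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            probs = model(Tensor(xt[idx]))
            batch_loss = loss_fn(probs, yt[idx], params, lam)
            if not np.isfinite(batch_loss.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            batch_loss.backward()
            opt.step()
            ep_loss += float(batch_loss.data) * len(idx)
            ep_correct += int((np.argmax(probs.data, 1) == yt[idx]).sum())
        history["train_loss"].append(ep_loss / max(len(xt), 1))
        history["train_acc"].append(ep_correct / max(len(xt), 1))
        if (cfg.target_train_acc is not None
                and history["train_acc"][-1] >= cfg.target_train_acc):
            logger.info("target training accuracy reached at epoch %d", epoch)
            break

        if n_val:
            with ag.no_grad():
                pv = model(Tensor(xv))
                vl = float(loss_fn(pv, yv, (), 0.0).data)
            va = float((np.argmax(pv.data, 1) == yv).mean())
            history["val_loss"].append(vl)
            history["val_acc"].append(va)
            if vl < best_val - cfg.min_delta:
                best_val, stale = vl, 0
                best_state = model.state_dict()
            else:
                stale += 1
                if stale >= cfg.patience:
                    logger.info("early stop at epoch %d", epoch)
                    break
    if best_state is not None:
        model.load_state_dict(best_state)
    return history


# -- metrics -----------------------------------------------------------------

@dataclass
class MetricsReport:
    """ACC/SEN/SPE (percent) per fold with mean +/- SD, for one
    configuration (one ablation row, one sweep point, ...)."""

    config: str = ""
    fold_acc: list = field(default_factory=list)
    fold_sen: list = field(default_factory=list)
    fold_spe: list = field(default_factory=list)
    fold_plain_acc: list = field(default_factory=list)

    def _stat(self, vals):
        a = np.asarray(vals, dtype=float)
        return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0

    @property
    def acc(self):
        return self._stat(self.fold_acc)[0]

    @property
    def sen(self):
        return self._stat(self.fold_sen)[0]

    @property
    def spe(self):
        return self._stat(self.fold_spe)[0]

    @property
    def plain_acc(self):
        return self._stat(self.fold_plain_acc)[0]

    def to_row(self) -> dict:
        m = {}
        for name, vals in (("acc", self.fold_acc), ("spe", self.fold_spe),
                           ("sen", self.fold_sen),
                           ("plain_acc", self.fold_plain_acc)):
            mean, sd = self._stat(vals)
            m[name] = mean
            m[f"{name}_sd"] = sd
        return {"config": self.config, **m}

    def __str__(self):
        r = self.to_row()
        return (f"{self.config}: ACC {r['acc']:.2f}±{r['acc_sd']:.2f}%  "
                f"SPE {r['spe']:.2f}±{r['spe_sd']:.2f}%  "
                f"SEN {r['sen']:.2f}±{r['sen_sd']:.2f}%")


def compute_metrics(pred_labels, true_labels,
                    config: str = "") -> MetricsReport:
    """One-vs-rest accuracy/sensitivity/specificity, as percentages.

    Two classes: the higher label is the positive class and the binary
    formulas apply directly.  More classes: SEN/SPE are macro-averaged
    one-vs-rest over the classes present in the truth (absent classes are
    excluded with a warning) and ACC pools the one-vs-rest counts.
    """
    pred = np.asarray(pred_labels, dtype=np.int64)
    true = np.asarray(true_labels, dtype=np.int64)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("pred and true must be equal-length 1-D")
    classes = np.unique(np.concatenate([true, pred]))
    present = np.unique(true)
    if len(present) < 2:
        raise ValueError("need >= 2 classes present in the truth")

    def ovr_counts(c):
        tp = int(((pred == c) & (true == c)).sum())
        fp = int(((pred == c) & (true != c)).sum())
        fn = int(((pred != c) & (true == c)).sum())
        tn = int(((pred != c) & (true != c)).sum())
        return tp, fp, fn, tn

    if len(classes) == 2:
        pos = classes.max()
        tp, fp, fn, tn = ovr_counts(pos)
        acc = 100.0 * (tp + tn) / (tp + fp + fn + tn)
        sen = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        spe = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    else:
        sens, spes = [], []
        pooled = np.zeros(4, dtype=np.int64)
        for c in classes:
            if c not in present:
                logger.warning("class %d absent from truth: excluded "
                               "from macro average", c)
                continue
            tp, fp, fn, tn = ovr_counts(c)
            pooled += (tp, fp, fn, tn)
            sens.append(tp / (tp + fn) if tp + fn else 0.0)
            spes.append(tn / (tn + fp) if tn + fp else 0.0)
        sen = 100.0 * float(np.mean(sens))
        spe = 100.0 * float(np.mean(spes))
        acc = 100.0 * (pooled[0] + pooled[3]) / pooled.sum()
    report = MetricsReport(config=config)
    report.fold_acc.append(acc)
    report.fold_sen.append(sen)
    report.fold_spe.append(spe)
    report.fold_plain_acc.append(100.0 * float((pred == true).mean()))
    return report


# -- splitters ---------------------------------------------------------------

def kfold_splits(n_samples: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Shuffled k-fold partition: disjoint, exhaustive, sizes differ by <=1.
    Returns the k test-index arrays."""
    if n_samples < k:
        raise ValueError(f"cannot split {n_samples} samples into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in kf.split(np.arange(n_samples))]


def loso_splits(subject_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-subject-out: one (train, test) pair per distinct subject."""
    subs = np.asarray(subject_ids)
    uniq = np.unique(subs)
    if len(uniq) < 2:
        raise ValueError("leave-one-subject-out needs >= 2 subjects")
    splits = []
    for s in uniq:
        test = np.where(subs == s)[0]
        train = np.where(subs != s)[0]
        splits.append((train, test))
    return splits


# -- experiment runners ------------------------------------------------------

def _fit_eval_fold(model_cfg: ModelConfig, batch: SegmentBatch,
                   train_idx: np.ndarray, test_idx: np.ndarray,
                   cfg: TrainConfig) -> MetricsReport:
    model = EEGformer(model_cfg)
    train(model, batch.segments[train_idx], batch.labels[train_idx], cfg)
    pred = model.predict(batch.segments[test_idx])
    return compute_metrics(pred, batch.labels[test_idx])


def run_ablation(batch: SegmentBatch, combos, model_cfg: ModelConfig,
                 cfg: TrainConfig = TrainConfig(),
                 k: int = 5) -> list[MetricsReport]:
    """Train/evaluate each stage combination under identical folds and
    seeds; one MetricsReport (mean +/- SD over folds) per combo.  A combo
    whose training fails is logged and skipped; the rest continue."""
    folds = kfold_splits(len(batch), k=k, seed=cfg.seed)
    all_idx = np.arange(len(batch))
    reports = []
    for combo in combos:
        combo = frozenset(combo)
        mc = dataclasses.replace(model_cfg, combo=combo)
        rep = MetricsReport(config=combo_name(combo))
        try:
            for test in folds:
                train_idx = np.setdiff1d(all_idx, test)
                fold = _fit_eval_fold(mc, batch, train_idx, test, cfg)
                rep.fold_acc += fold.fold_acc
                rep.fold_sen += fold.fold_sen
                rep.fold_spe += fold.fold_spe
                rep.fold_plain_acc += fold.fold_plain_acc
        except Exception:
            logger.exception("combo %s failed; continuing", rep.config)
            continue
        reports.append(rep)
    return reports


def sweep_segment_length(recs: RecordingSet, T_values, model_cfg: ModelConfig,
                         cfg: TrainConfig = TrainConfig(),
                         k: int = 5) -> list[MetricsReport]:
    """Re-window the trials at each segment length T (seconds), retrain and
    report ACC +/- SD per T.  Lengths below the convolutional support are
    skipped with a warning."""
    reports = []
    for T in T_values:
        window = int(round(T * recs.sr))
        if window < model_cfg.conv.support:
            logger.warning("T=%.2fs gives %d samples < conv support %d: "
                           "skipped", T, window, model_cfg.conv.support)
            continue
        batch = segment_trials(recs, ratio=T)
        mc = dataclasses.replace(model_cfg, L=window)
        folds = kfold_splits(len(batch), k=k, seed=cfg.seed)
        all_idx = np.arange(len(batch))
        rep = MetricsReport(config=f"T={T}")
        for test in folds:
            fold = _fit_eval_fold(mc, batch, np.setdiff1d(all_idx, test),
                                  test, cfg)
            rep.fold_acc += fold.fold_acc
            rep.fold_sen += fold.fold_sen
            rep.fold_spe += fold.fold_spe
            rep.fold_plain_acc += fold.fold_plain_acc
        reports.append(rep)
    return reports


# -- report serialization ----------------------------------------------------

def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in reports])


def save_reports(reports: list[MetricsReport], csv_path, json_path=None) -> None:
    """CSV: one row per fold x config; JSON: mean +/- SD summary."""
    rows = []
    for r in reports:
        for i, (a, sp, se, pa) in enumerate(zip(r.fold_acc, r.fold_spe,
                                                r.fold_sen, r.fold_plain_acc)):
            rows.append({"config": r.config, "fold": i, "acc": a,
                         "spe": sp, "sen": se, "plain_acc": pa})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as f:
            json.dump([r.to_row() for r in reports], f, indent=2)
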