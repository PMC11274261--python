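"""Stratified patient-level cross-validation, training loop and metrics.

Protocol: subjects are split into k label-stratified folds; for each fold the
training subjects (only) are offline-augmented, a fresh network is trained
with Adam under a step learning-rate schedule (x0.1 every 30 epochs from
1e-3) with early stopping on the training loss (patience 5), and the model is
evaluated on the held-out subjects.  Augmented copies always follow their
source subject, so no transformed view of a test subject can leak into
training.  Reported metrics are accuracy, specificity, sensitivity, F1 (at
threshold 0.5) and the rank-based AUC, per fold and averaged over folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import losses as L
from .augment import AugmentPolicy, augment_offline
from .data_io import assemble_view_groups
from .model import DMFNet, ModelConfig
from .nn.optim import Adam
from .types import CohortManifest, MultiViewRecord


@dataclass
class TrainConfig:
    epochs: int = 120
    batch_size: int = 16
    lr0: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 30
    early_stop_patience: int = 5
    seed: int = 0
    eval_mode: str = "original_only"   # or "augmented_test"
    image_size: int = 224

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_decay_every) <= 0 or self.lr0 <= 0:
            raise ValueError("training sizes and rates must be positive")
        if self.early_stop_patience > self.epochs:
            raise ValueError("patience must not exceed the epoch budget")
        if self.eval_mode not in ("original_only", "augmented_test"):
            raise ValueError("eval_mode must be original_only or augmented_test")


@dataclass
class FoldSplit:
    k: int
    assignments: dict[str, int]   # subject_id -> fold index
    seed: int

    def fold_subjects(self, fold: int) -> list[str]:
        return [sid for sid, f in self.assignments.items() if f == fold]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class FoldMetrics:
    acc: float
    spe: float
    sen: float
    f1: float
    auc: float | None = None
    counts: ConfusionCounts | None = None


@dataclass
class MetricsReport:
    per_fold: list[FoldMetrics]
    roc_points: list[np.ndarray] = field(default_factory=list)

    @property
    def mean(self) -> FoldMetrics:
        def m(attr):
            vals = [getattr(f, attr) for f in self.per_fold]
            vals = [v for v in vals if v is not None and not math.isnan(v)]
            return float(np.mean(vals)) if vals else float("nan")
        return FoldMetrics(acc=m("acc"), spe=m("spe"), sen=m("sen"),
                           f1=m("f1"), auc=m("auc"))


# ---------------------------------------------------------------------------
# splitting, schedule, metrics
# ---------------------------------------------------------------------------

def stratified_kfold(manifest: CohortManifest, k: int = 5, seed: int = 0) -> FoldSplit:
    """Label-stratified, seed-deterministic subject-level partition."""
    labels = manifest.labels()
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} subjects")
    sids = [r.subject_id for r in manifest.records]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(sids)), labels)):
        for i in test_idx:
            assignments[sids[i]] = fold
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Step decay: lr0 * factor^floor(epoch / decay_every)."""
    if not (0 <= epoch < config.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    return config.lr0 * config.lr_decay_factor ** (epoch // config.lr_decay_every)


def compute_metrics(counts: ConfusionCounts) -> FoldMetrics:
    """Accuracy, specificity, sensitivity and F1 from confusion counts.

    A metric whose denominator is zero is reported as NaN.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = counts.total()
    if n == 0:
        raise ValueError("confusion counts are all zero")
    acc = (tp + tn) / n
    spe = tn / (tn + fp) if tn + fp > 0 else float("nan")
    sen = tp / (tp + fn) if tp + fn > 0 else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else float("nan")
    return FoldMetrics(acc=acc, spe=spe, sen=sen, f1=f1, counts=counts)


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores, labels) -> np.ndarray:
    """(threshold, TPR, FPR) rows at every distinct score threshold."""
    fpr, tpr, thr = roc_curve(np.asarray(labels), np.asarray(scores, dtype=float))
    return np.column_stack([thr, tpr, fpr])


def confusion_from_scores(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (scores >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(((pred == 1) & (labels == 1)).sum()),
        TN=int(((pred == 0) & (labels == 0)).sum()),
        FP=int(((pred == 1) & (labels == 0)).sum()),
        FN=int(((pred == 0) & (labels == 1)).sum()),
    )


# ---------------------------------------------------------------------------
# early stopping
# ---------------------------------------------------------------------------

def early_stop_epoch(losses: list[float], patience: int) -> tuple[int, int]:
    """(stop_epoch, best_epoch) for a monitored loss sequence.

    Training stops after the epoch at which the loss has failed to improve on
    the best value for ``patience`` consecutive epochs; ``stop_epoch`` is the
    index of that last executed epoch.
    """
    best, best_epoch, bad = math.inf, 0, 0
    for e, v in enumerate(losses):
        if v < best:
            best, best_epoch, bad = v, e, 0
        else:
            bad += 1
            if bad >= patience:
                return e, best_epoch
    return len(losses) - 1, best_epoch


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _stack_inputs(records: list[MultiViewRecord], size: int):
    fronts, sides, ys = [], [], []
    for rec in records:
        f, s = assemble_view_groups(rec, size=size)
        fronts.append(f)
        sides.append(s)
        ys.append(rec.label)
    return (np.stack(fronts).astype(np.float32), np.stack(sides).astype(np.float32),
            np.asarray(ys, dtype=np.float32))


def train_fold(train_records: list[MultiViewRecord], model_config: ModelConfig,
               train_config: TrainConfig,
               loss_weights: L.LossWeights | None = None,
               use_focal: bool = True, use_comple: bool = True,
               use_consist: bool = True,
               early_stop: bool = True) -> tuple[DMFNet, list[dict]]:
    """Train one network on one fold's training records.

    Returns the model restored to its best epoch (lowest monitored training
    loss) and the per-epoch history of loss components and learning rate.
    """
    labels = {r.label for r in train_records}
    if labels != {0, 1}:
        raise ValueError("training set must contain both classes")
    weights = loss_weights or L.LossWeights()
    x1, x2, y = _stack_inputs(train_records, train_config.image_size)
    n = len(y)
    model = DMFNet(replace(model_config, seed=model_config.seed + train_config.seed))
    model.build_for_input(train_config.image_size)
    model.train()
    opt = Adam(model.parameters(), lr=train_config.lr0)
    order_rng = np.random.default_rng(train_config.seed + 17)
    drop_rng = np.random.default_rng(train_config.seed + 29)
    history: list[dict] = []
    best_loss, best_state, bad = math.inf, None, 0
    for epoch in range(train_config.epochs):
        opt.lr = lr_schedule(epoch, train_config)
        perm = order_rng.permutation(n)
        epoch_parts = {"total": 0.0, "classification": 0.0,
                       "complementarity": 0.0, "consistency": 0.0}
        n_batches = 0
        for start in range(0, n, train_config.batch_size):
            idx = perm[start:start + train_config.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs more than one sample
            out = model.forward(x1[idx], x2[idx], drop_rng)
            loss, parts = L.total_loss(out.p, y[idx], out.z_cpp, out.z_csp, weights,
                                       use_focal=use_focal, use_comple=use_comple,
                                       use_consist=use_consist)
            model.zero_grad()
            loss.backward()
            opt.step()
            for k in epoch_parts:
                epoch_parts[k] += parts[k]
            n_batches += 1
        for k in epoch_parts:
            epoch_parts[k] /= max(n_batches, 1)
        epoch_parts["lr"] = opt.lr
        epoch_parts["epoch"] = epoch
        history.append(epoch_parts)
        monitored = epoch_parts["total"]
        if monitored < best_loss:
            best_loss, bad = monitored, 0
            best_state = model.state_dict()
        else:
            bad += 1
            if early_stop and bad >= train_config.early_stop_patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def predict(model: DMFNet, records: list[MultiViewRecord], image_size: int,
            batch_size: int = 16) -> np.ndarray:
    model.eval()
    x1, x2, _ = _stack_inputs(records, image_size)
    out = []
    for start in range(0, len(records), batch_size):
        sl = slice(start, start + batch_size)
        out.append(model.forward(x1[sl], x2[sl]).p.data)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# cross-validation and ablation harness
# ---------------------------------------------------------------------------

def run_cv(manifest: CohortManifest, model_config: ModelConfig,
           train_config: TrainConfig, augment_policy: AugmentPolicy | None = None,
           loss_weights: L.LossWeights | None = None,
           use_focal: bool = True, use_comple: bool = True, use_consist: bool = True,
           k: int = 5) -> MetricsReport:
    """Full k-fold protocol; training subjects only are augmented."""
    split = stratified_kfold(manifest, k=k, seed=train_config.seed)
    by_id = {r.subject_id: r for r in manifest.records}
    report = MetricsReport(per_fold=[])
    for fold in range(k):
        test_ids = set(split.fold_subjects(fold))
        train_recs = [r for r in manifest.records if r.subject_id not in test_ids]
        test_recs = [by_id[s] for s in sorted(test_ids)]
        if augment_policy is not None:
            train_man = augment_offline(CohortManifest(list(train_recs), manifest.provenance),
                                        augment_policy)
            train_recs = train_man.records
            assert not any(r.source_id in test_ids for r in train_recs), \
                "augmented copy of a test subject leaked into training"
            if train_config.eval_mode == "augmented_test":
                test_man = augment_offline(CohortManifest(list(test_recs), manifest.provenance),
                                           replace(augment_policy, seed=augment_policy.seed + 9999))
                test_recs = test_man.records
        model, _hist = train_fold(train_recs, model_config, train_config,
                                  loss_weights=loss_weights, use_focal=use_focal,
                                  use_comple=use_comple, use_consist=use_consist)
        scores = predict(model, test_recs, train_config.image_size,
                         train_config.batch_size)
        labels = np.array([r.label for r in test_recs])
        metrics = compute_metrics(confusion_from_scores(scores, labels))
        metrics.auc = roc_auc(scores, labels) if len(np.unique(labels)) == 2 else None
        report.per_fold.append(metrics)
        if len(np.unique(labels)) == 2:
            report.roc_points.append(roc_points(scores, labels))
    return report


#: ablation grid mirroring the published component study: each row switches
#: one more module/loss on, from the plain last-scale + BCE baseline to the
#: full model.
ABLATION_GRID = [
    ("baseline", dict(use_mffm=False, use_hcam=False, use_focal=False,
                      use_comple=False, use_consist=False)),
    ("+mffm", dict(use_mffm=True, use_hcam=False, use_focal=False,
                   use_comple=False, use_consist=False)),
    ("+hcam", dict(use_mffm=True, use_hcam=True, use_focal=False,
                   use_comple=False, use_consist=False)),
    ("+focal", dict(use_mffm=True, use_hcam=True, use_focal=True,
                    use_comple=False, use_consist=False)),
    ("+comple", dict(use_mffm=True, use_hcam=True, use_focal=True,
                     use_comple=True, use_consist=False)),
    ("+consist", dict(use_mffm=True, use_hcam=True, use_focal=True,
                      use_comple=False, use_consist=True)),
    ("full", dict(use_mffm=True, use_hcam=True, use_focal=True,
                  use_comple=True, use_consist=True)),
]


def run_ablation(manifest: CohortManifest, train_config: TrainConfig,
                 grid=None, model_config: ModelConfig | None = None,
                 augment_policy: AugmentPolicy | None = None,
                 k: int = 5) -> list[tuple[str, dict, MetricsReport]]:
    grid = grid if grid is not None else ABLATION_GRID
    base = model_config or ModelConfig()
    results = []
    for name, flags in grid:
        mc = replace(base, use_mffm=flags["use_mffm"], use_hcam=flags["use_hcam"])
        rep = run_cv(manifest, mc, train_config, augment_policy=augment_policy,
                     use_focal=flags["use_focal"], use_comple=flags["use_comple"],
                     use_consist=flags["use_consist"], k=k)
        results.append((name, flags, rep))
    return results
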