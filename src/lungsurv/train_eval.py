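"""Training and evaluation harness for the 3-D CNN survival classifier.

The recipe: stratified 85/15 train/test split, 5-fold cross-validation over
the training portion, SGD with Nesterov momentum (initial learning rate
2e-5, weight decay 1e-6, momentum 0.9, batch size 16, up to 200 epochs),
learning rate multiplied by 0.9 after a 25-epoch validation-loss plateau,
early stopping with best-weights restore.  Reported test metrics (accuracy at
threshold 0.5 and rank-based ROC-AUC) are the mean of the five fold-models
applied to the held-out test set.

Desk-scale experiments use the ``tiny3d`` architecture on small synthetic
stacks; the full ``resnet34_3d`` shares the identical code path.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .losses import Criterion, LossParams, make_criterion


@dataclass
class TrainConfig:
    lr: float = 2e-5
    weight_decay: float = 1e-6
    momentum: float = 0.9
    nesterov: bool = True
    batch_size: int = 16
    epochs: int = 200
    plateau_patience: int = 25
    plateau_tol: float = 1e-4
    lr_factor: float = 0.9
    early_stopping_patience: int = 50
    folds: int = 5
    test_frac: float = 0.15
    loss: str = "bce"
    loss_params: LossParams = field(default_factory=LossParams)
    augmentation: bool = False
    max_rotation_deg: float = 15.0
    max_shift_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lr", "weight_decay", "batch_size", "epochs", "folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.test_frac < 1:
            raise ValueError("test_frac must lie in (0, 1)")

    def criterion(self) -> Criterion:
        if self.loss == "pen_bce":
            return make_criterion("pen_bce", params=self.loss_params)
        return make_criterion(self.loss)


@dataclass
class EvalResult:
    test_loss: float
    acc: float
    auc: float | None
    per_fold: list[dict] = field(default_factory=list)
    n: int = 0


def build_model(arch: str, in_shape: tuple[int, int, int], seed: int = 0) -> nn.Network:
    """Construct a classifier: ``resnet34_3d`` or the test-scale ``tiny3d``."""
    if arch == "resnet34_3d":
        return nn.resnet34_3d(in_shape, seed)
    if arch == "tiny3d":
        return nn.tiny3d(in_shape, seed)
    raise ValueError(f"unknown architecture {arch!r}")


def stratified_split(labels, test_frac: float = 0.15, seed: int = 0
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive stratified index split preserving class balance."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 members")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, stratify=y, random_state=seed, shuffle=True)
    return np.sort(train_idx), np.sort(test_idx)


def _to_batch_tensor(stacks: np.ndarray) -> np.ndarray:
    """(N, H, W, D) volumes -> (N, 1, D, H, W) network input."""
    x = np.asarray(stacks, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError("stacks must be (N, H, W, D)")
    return x.transpose(0, 3, 1, 2)[:, None, :, :, :]


def augment_batch(x: np.ndarray, rng: np.random.Generator, *,
                  max_rotation_deg: float = 15.0, max_shift_frac: float = 0.10
                  ) -> np.ndarray:
    """Random in-plane rotation and horizontal/vertical shift per sample."""
    out = np.empty_like(x)
    n, _, _, h, w = x.shape
    for i in range(n):
        angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
        dr = rng.uniform(-max_shift_frac, max_shift_frac) * h
        dc = rng.uniform(-max_shift_frac, max_shift_frac) * w
        vol = ndimage.rotate(x[i, 0], angle, axes=(1, 2), reshape=False, order=1)
        vol = ndimage.shift(vol, (0, dr, dc), order=1)
        out[i, 0] = np.clip(vol, 0.0, 1.0)
    return out


def train_single(model: nn.Network, x_train, y_train, x_val, y_val,
                 config: TrainConfig, batch_hook=None) -> tuple[nn.Network, dict]:
    """Fit one model with the full recipe on explicit train/val arrays.

    Returns the model (best-validation weights restored) and a history dict
    with per-epoch train/val losses and the learning-rate trace.
    """
    x_train = _to_batch_tensor(x_train)
    x_val = _to_batch_tensor(x_val)
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    crit = config.criterion()
    opt = nn.SGD(model.parameters(), lr=config.lr, momentum=config.momentum,
                 weight_decay=config.weight_decay, nesterov=config.nesterov)
    rng = np.random.default_rng(config.seed)
    history: dict = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_state = model.state()
    plateau, since_best = 0, 0

    for epoch in range(config.epochs):
        order = rng.permutation(len(y_train))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            if config.augmentation:
                xb = augment_batch(xb, rng, max_rotation_deg=config.max_rotation_deg,
                                   max_shift_frac=config.max_shift_frac)
            model.zero_grad()
            probs = model.forward(xb, train=True)
            loss = crit.value(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}; "
                    f"lr={opt.lr:g}, batch probs range "
                    f"[{probs.min():.3g}, {probs.max():.3g}]")
            if batch_hook is not None:
                batch_hook(probs.copy(), yb.copy(), loss)
            model.backward(crit.grad(probs, yb))
            opt.step()
            epoch_losses.append(loss)
        val_probs = model.forward(x_val, train=False)
        val_loss = crit.value(val_probs, y_val)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(float(val_loss))
        history["lr"].append(float(opt.lr))

        if val_loss < best_val - config.plateau_tol:
            best_val = val_loss
            best_state = model.state()
            plateau, since_best = 0, 0
        else:
            plateau += 1
            since_best += 1
            if plateau >= config.plateau_patience:
                opt.lr *= config.lr_factor
                plateau = 0
            if since_best >= config.early_stopping_patience:
                break
    model.load_state(best_state)
    return model, history


class FoldEnsemble:
    """The five fold-models of a cross-validated run."""

    def __init__(self, models: list[nn.Network]):
        self.models = models

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.mean([m.forward(x, train) for m in self.models], axis=0)


def train(model: nn.Network, stacks, labels, config: TrainConfig,
          batch_hook=None) -> tuple[nn.Network | FoldEnsemble, dict]:
    """Train with k-fold cross-validation over the provided training data.

    With ``config.folds == 1`` a stratified 15% of the data becomes the
    validation set and the single fitted model is returned; otherwise each
    fold starts from a copy of the same initial weights and a
    :class:`FoldEnsemble` of the fold-models is returned.
    """
    y = np.asarray(labels, dtype=np.float64)
    x = np.asarray(stacks, dtype=np.float64)
    if len(x) != len(y):
        raise ValueError("stacks and labels must align")
    if config.folds == 1:
        tr, va = stratified_split(y, test_frac=0.15, seed=config.seed)
        return train_single(model, x[tr], y[tr], x[va], y[va], config, batch_hook)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    models, histories = [], []
    for fold, (tr, va) in enumerate(skf.split(x, y)):
        fold_model = copy.deepcopy(model)
        fold_cfg = replace(config, seed=config.seed + fold)
        fold_model, hist = train_single(fold_model, x[tr], y[tr], x[va], y[va],
                                        fold_cfg, batch_hook)
        models.append(fold_model)
        histories.append(hist)
    return FoldEnsemble(models), {"folds": histories}


def accuracy(probs, labels, threshold: float = 0.5) -> float:
    p = np.asarray(probs)
    y = np.asarray(labels)
    return float(np.mean((p > threshold).astype(int) == y))


def roc_auc(probs, labels) -> float | None:
    """Mann–Whitney (midrank) ROC-AUC; ``None`` when only one class present."""
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(p)  # midranks for ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(model, stacks, labels, config: TrainConfig | None = None) -> EvalResult:
    """Accuracy / AUC / loss on held-out data.

    For a :class:`FoldEnsemble` the headline numbers are the mean of the
    per-fold-model metrics (each fold model applied to the same test set),
    with the per-fold values retained.
    """
    x = _to_batch_tensor(np.asarray(stacks, dtype=np.float64))
    y = np.asarray(labels, dtype=np.float64)
    crit = (config or TrainConfig()).criterion()

    def one(m) -> dict:
        p = m.forward(x, train=False)
        auc = roc_auc(p, y)
        return {"test_loss": crit.value(p, y), "acc": accuracy(p, y),
                "auc": auc if auc is not None else np.nan}

    if isinstance(model, FoldEnsemble):
        per_fold = [one(m) for m in model.models]
        aucs = [f["auc"] for f in per_fold if np.isfinite(f["auc"])]
        return EvalResult(
            test_loss=float(np.mean([f["test_loss"] for f in per_fold])),
            acc=float(np.mean([f["acc"] for f in per_fold])),
            auc=float(np.mean(aucs)) if aucs else None,
            per_fold=per_fold, n=len(y))
    r = one(model)
    return EvalResult(test_loss=float(r["test_loss"]), acc=float(r["acc"]),
                      auc=None if not np.isfinite(r["auc"]) else float(r["auc"]),
                      per_fold=[r], n=len(y))


def train_logistic(x, y, criterion: Criterion, lr: float = 0.5,
                   epochs: int = 300) -> tuple[np.ndarray, float]:
    """Fit a logistic model by full-batch gradient descent under any criterion.

    Chain rule through the sigmoid: dL/dz = dL/dp · p(1-p).  Returns weights
    and bias.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.zeros(x.shape[1])
    b = 0.0
    for _ in range(epochs):
        p = 1.0 / (1.0 + np.exp(-(x @ w + b)))
        dz = criterion.grad(p, y) * p * (1 - p)
        w -= lr * (x.T @ dz)
        b -= lr * dz.sum()
    return w, b


def imbalanced_logistic_fp_experiment(
        seeds, n: int = 2000, pos_frac: float = 0.25,
        params: LossParams | None = None) -> dict:
    """False-positive counts of BCE- vs PEN-BCE-trained logistic models.

    A two-feature Gaussian task with a 1:3 positive:negative ratio and
    overlapping classes; per seed both models are fit on half the data and
    false positives are counted at threshold 0.5 on the held-out half.
    Returns per-seed counts and their means.
    """
    params = params or LossParams()
    crit_bce = make_criterion("bce")
    crit_pen = make_criterion("pen_bce", params=params)
    fp_bce, fp_pen = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        n_pos = int(round(n * pos_frac))
        x = np.vstack([rng.normal([1.5, 1.5], 1.0, size=(n_pos, 2)),
                       rng.normal([0.0, 0.0], 1.0, size=(n - n_pos, 2))])
        y = np.concatenate([np.ones(n_pos), np.zeros(n - n_pos)])
        order = rng.permutation(n)
        x, y = x[order], y[order]
        half = n // 2
        counts = []
        for crit in (crit_bce, crit_pen):
            w, b = train_logistic(x[:half], y[:half], crit)
            p = 1.0 / (1.0 + np.exp(-(x[half:] @ w + b)))
            counts.append(int(((p > 0.5) & (y[half:] == 0)).sum()))
        fp_bce.append(counts[0])
        fp_pen.append(counts[1])
    return {"fp_bce": fp_bce, "fp_pen_bce": fp_pen,
            "mean_fp_bce": float(np.mean(fp_bce)),
            "mean_fp_pen_bce": float(np.mean(fp_pen))}


def run_ablation(cells: list[dict], data_provider, base_config: TrainConfig,
                 arch: str = "tiny3d"):
    """Train/evaluate one model per ablation cell and tabulate the results.

    ``cells`` are dicts of :class:`TrainConfig` overrides plus an optional
    ``"data"`` key passed to ``data_provider(cell)`` which must return
    ``(x_train, y_train, x_test, y_test)``.  All cells share the base seed so
    only the varied axis differs between rows.
    """
    import pandas as pd

    rows = []
    for cell in cells:
        overrides = {k: v for k, v in cell.items() if k not in ("name", "data")}
        cfg = replace(base_config, **overrides)
        x_train, y_train, x_test, y_test = data_provider(cell)
        model = build_model(arch, x_train.shape[1:], seed=cfg.seed)
        fitted, _ = train(model, x_train, y_train, cfg)
        res = evaluate(fitted, x_test, y_test, cfg)
        rows.append({"cell": cell.get("name", repr(overrides)),
                     "loss": cfg.loss,
                     "test_loss": res.test_loss, "acc": res.acc, "auc": res.auc})
    return pd.DataFrame(rows)
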