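"""Training, evaluation and multi-seed experiments.

The reference full-scale recipe (SGD, 300 epochs, initial learning rate
1e-5, weight decay 1e-4, rate drops by 10x at 50% and 75% of the epochs,
cross-entropy loss) is the ``fullscale`` preset.  The ``desk`` preset (30
epochs, lr 1e-3, small_cnn backbone on 32 px synthetic patches) runs the
whole pipeline on one CPU in minutes and is what the tests use.

Metrics are per-class precision/recall/F1 from the confusion matrix
(rows = true class), with macro and support-weighted averages; classes with
zero support are excluded from the macro average with a warning.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support as _sk_prfs

from .nn.core import SGD, cross_entropy, softmax
from .model import IHCClassifier, PriorGuidedNetwork, count_parameters
from .perception import upsample_cam
from .stains import anomaly_map_from_rgb
from .synth import CLASS_NAMES, PatchRecord, augment, generate_dataset

__all__ = [
    "TrainConfig",
    "desk_config",
    "fullscale_config",
    "load_preset",
    "lr_at_epoch",
    "EvalReport",
    "report_from_labels",
    "train",
    "evaluate",
    "TrainOutcome",
    "IHCClassifierResults",
    "ExperimentConfig",
    "run_experiment",
    "compare_prior",
    "default_task",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the full-scale recipe)."""

    epochs: int = 300
    lr: float = 1e-5
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_drop_factor: float = 0.1
    lr_milestones: tuple[float, float] = (0.5, 0.75)
    batch_size_train: int = 32
    batch_size_eval: int = 64
    augment: bool = True
    augment_ops: tuple[str, ...] = ("rotation",)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        for m in self.lr_milestones:
            if not 0.0 < m < 1.0:
                raise ValueError("lr milestones must lie strictly inside (0, 1)")


def fullscale_config(**overrides) -> TrainConfig:
    """The full-scale training recipe (300 epochs, lr 1e-5)."""
    return replace(TrainConfig(), **overrides) if overrides else TrainConfig()


def desk_config(**overrides) -> TrainConfig:
    """Desk-scale recipe for CPU runs: 30 epochs at lr 1e-3."""
    cfg = TrainConfig(epochs=30, lr=1e-3)
    return replace(cfg, **overrides) if overrides else cfg


def load_preset(name: str) -> dict:
    """Load a named YAML preset ('desk' or 'fullscale').

    Returns a dict with ``backbone``, ``patch_size``, ``feature_channels``
    and a ``train`` TrainConfig.
    """
    import yaml

    path = os.path.join(os.path.dirname(__file__), "presets", f"{name}.yaml")
    if not os.path.exists(path):
        raise ValueError(f"unknown preset {name!r}; expected 'desk' or 'fullscale'")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    train_data = data.pop("train", {})
    if "lr_milestones" in train_data:
        train_data["lr_milestones"] = tuple(train_data["lr_milestones"])
    data["train"] = TrainConfig(**train_data)
    return data


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate entering 0-based ``epoch``: dropped by ``lr_drop_factor``
    at each of floor(m * epochs) for the configured milestones."""
    drops = sum(epoch >= int(np.floor(m * cfg.epochs)) for m in cfg.lr_milestones)
    return cfg.lr * cfg.lr_drop_factor**drops


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-class and averaged classification metrics.

    ``confusion`` has true classes as rows and predictions as columns;
    row sums equal the class supports.
    """

    classes: tuple[str, ...]
    confusion: np.ndarray
    per_class: pd.DataFrame  # columns: precision, recall, f1, support
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    n: int
    seed: int | None = None
    averaging_note: str = "macro over classes with support > 0; weighted by support"

    def summary(self) -> str:
        lines = [
            f"evaluated patches: {self.n}    accuracy: {self.accuracy:.4f}",
            self.per_class.to_string(float_format=lambda v: f"{v:.4f}"),
            f"macro    P/R/F1: {self.macro_precision:.4f} / "
            f"{self.macro_recall:.4f} / {self.macro_f1:.4f}",
            f"weighted P/R/F1: {self.weighted_precision:.4f} / "
            f"{self.weighted_recall:.4f} / {self.weighted_f1:.4f}",
        ]
        return "\n".join(lines)


def report_from_labels(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    classes: tuple[str, ...],
    seed: int | None = None,
) -> EvalReport:
    """Build an :class:`EvalReport` from true/predicted class indices."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    labels = np.arange(len(classes))
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    precision, recall, f1, support = _sk_prfs(
        y_true, y_pred, labels=labels, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "f1": f1, "support": support},
        index=list(classes),
    )
    present = support > 0
    if not present.all():
        missing = [c for c, p in zip(classes, present) if not p]
        warnings.warn(
            f"classes with zero support excluded from macro average: {missing}",
            stacklevel=2,
        )
    macro = per_class.loc[np.asarray(present), ["precision", "recall", "f1"]].mean()
    weights = support / support.sum()
    weighted = {
        k: float(np.sum(per_class[k].to_numpy() * weights))
        for k in ("precision", "recall", "f1")
    }
    return EvalReport(
        classes=tuple(classes),
        confusion=cm,
        per_class=per_class,
        accuracy=float(np.mean(y_true == y_pred)),
        macro_precision=float(macro["precision"]),
        macro_recall=float(macro["recall"]),
        macro_f1=float(macro["f1"]),
        weighted_precision=weighted["precision"],
        weighted_recall=weighted["recall"],
        weighted_f1=weighted["f1"],
        n=int(y_true.size),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# data marshalling
# ---------------------------------------------------------------------------

def _anomaly(image: np.ndarray) -> np.ndarray:
    return anomaly_map_from_rgb(image).map


def _stack(records: list[PatchRecord], classes: tuple[str, ...]):
    label_to_idx = {c: i for i, c in enumerate(classes)}
    io = np.stack([np.asarray(r.image) for r in records])
    ip = np.stack([_anomaly(np.asarray(r.image)) for r in records])
    y = np.array([label_to_idx[r.label] for r in records], dtype=int)
    return io, ip, y


def _batched_logits(
    network: PriorGuidedNetwork, io: np.ndarray, ip: np.ndarray, batch_size: int
) -> np.ndarray:
    chunks = []
    for start in range(0, io.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        logits, _ = network.forward(io[sl], ip[sl], train=False)
        chunks.append(logits)
    return np.concatenate(chunks)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainOutcome:
    history: pd.DataFrame
    best_state: list
    best_epoch: int
    best_val_macro_f1: float
    report: EvalReport
    config: TrainConfig
    classes: tuple[str, ...]


def train(
    network: PriorGuidedNetwork,
    train_records: list[PatchRecord],
    val_records: list[PatchRecord],
    cfg: TrainConfig,
    classes: tuple[str, ...] = CLASS_NAMES,
    seed: int = 0,
    verbose: bool = False,
    curves_path: str | None = None,
) -> TrainOutcome:
    """Cross-entropy SGD training with per-epoch curves and best-F1 checkpoint.

    Fully deterministic for a fixed (network seed, ``seed``) pair on one
    device.  Raises ``FloatingPointError`` on a non-finite loss.
    """
    if not train_records or not val_records:
        raise ValueError("empty train or validation split")
    train_ids = {r.id for r in train_records}
    if any(r.id in train_ids for r in val_records):
        raise ValueError("train and validation splits overlap")
    rng = np.random.default_rng(seed)
    io_tr, ip_tr, y_tr = _stack(train_records, classes)
    io_val, ip_val, y_val = _stack(val_records, classes)

    opt = SGD(
        network.parameters(),
        lr=cfg.lr,
        momentum=cfg.momentum,
        weight_decay=cfg.weight_decay,
    )
    n = len(train_records)
    rows = []
    best_f1, best_epoch, best_state = -1.0, -1, network.state_dict()
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, cfg.batch_size_train):
            idx = order[start : start + cfg.batch_size_train]
            if cfg.augment:
                images = np.stack(
                    [augment(io_tr[i], ops=cfg.augment_ops, seed=rng) for i in idx]
                )
                maps = np.stack([_anomaly(img) for img in images])
            else:
                images, maps = io_tr[idx], ip_tr[idx]
            logits, _ = network.forward(images, maps, train=True)
            loss, dlogits = cross_entropy(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (lr={opt.lr:g}); aborting"
                )
            opt.zero_grad()
            network.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == y_tr[idx]).sum())

        val_logits = _batched_logits(network, io_val, ip_val, cfg.batch_size_eval)
        val_loss, _ = cross_entropy(val_logits, y_val)
        val_pred = val_logits.argmax(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            val_report = report_from_labels(y_val, val_pred, classes)
        rows.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_loss": epoch_loss / n,
                "train_acc": epoch_correct / n,
                "val_loss": val_loss,
                "val_acc": val_report.accuracy,
                "val_macro_f1": val_report.macro_f1,
            }
        )
        if val_report.macro_f1 > best_f1:
            best_f1 = val_report.macro_f1
            best_epoch = epoch
            best_state = network.state_dict()
        if verbose:
            print(
                f"epoch {epoch:3d}  lr {opt.lr:.2g}  "
                f"train loss {rows[-1]['train_loss']:.4f}  "
                f"val acc {val_report.accuracy:.4f}  "
                f"val macro-F1 {val_report.macro_f1:.4f}"
            )

    network.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    if curves_path:
        history.to_csv(curves_path, index=False)
    final_report = evaluate(network, val_records, classes, cfg.batch_size_eval, seed=seed)
    return TrainOutcome(
        history=history,
        best_state=best_state,
        best_epoch=best_epoch,
        best_val_macro_f1=best_f1,
        report=final_report,
        config=cfg,
        classes=tuple(classes),
    )


def evaluate(
    network: PriorGuidedNetwork,
    records: list[PatchRecord],
    classes: tuple[str, ...] = CLASS_NAMES,
    batch_size: int = 64,
    seed: int | None = None,
) -> EvalReport:
    """Run the network over labeled records and compute the metric report."""
    io, ip, y = _stack(records, classes)
    logits = _batched_logits(network, io, ip, batch_size)
    return report_from_labels(y, logits.argmax(axis=1), classes, seed=seed)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

class IHCClassifierResults:
    """Fitted-model results: curves, metrics, predictions and CAM export."""

    def __init__(
        self,
        model: IHCClassifier,
        network: PriorGuidedNetwork,
        outcome: TrainOutcome,
        seed: int,
    ) -> None:
        self.model = model
        self.network = network
        self.outcome = outcome
        self.seed = seed

    # -- accessors ----------------------------------------------------------
    @property
    def history(self) -> pd.DataFrame:
        return self.outcome.history

    @property
    def report(self) -> EvalReport:
        return self.outcome.report

    @property
    def macro_f1(self) -> float:
        return self.outcome.report.macro_f1

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.network)

    def summary(self) -> str:
        cfg = self.outcome.config
        head = [
            "Prior-guided IHC patch classifier",
            "=" * 48,
            f"backbone: {self.model.backbone}   prior branch: {self.model.use_prior}"
            f"   attention: {self.model.use_attention}",
            f"parameters: {self.n_parameters:,} ({self.n_parameters / 1e6:.2f}M)",
            f"train/val patches: {len(self.model.data.train)}/{len(self.model.data.val)}"
            f"   classes: {len(self.model.classes)}",
            f"epochs: {cfg.epochs}  lr: {cfg.lr:g}  seed: {self.seed}"
            f"   best epoch: {self.outcome.best_epoch}",
            "-" * 48,
        ]
        return "\n".join(head) + "\n" + self.report.summary()

    # -- inference ----------------------------------------------------------
    def predict(self, records: list[PatchRecord]) -> list[str]:
        io = np.stack([np.asarray(r.image) for r in records])
        ip = np.stack([_anomaly(np.asarray(r.image)) for r in records])
        logits = _batched_logits(self.network, io, ip, self.outcome.config.batch_size_eval)
        return [self.model.classes[i] for i in logits.argmax(axis=1)]

    def predict_proba(self, records: list[PatchRecord]) -> np.ndarray:
        io = np.stack([np.asarray(r.image) for r in records])
        ip = np.stack([_anomaly(np.asarray(r.image)) for r in records])
        return softmax(_batched_logits(self.network, io, ip, self.outcome.config.batch_size_eval))

    def cams(self, records: list[PatchRecord]) -> np.ndarray:
        """16x16 activation maps for each record."""
        io = np.stack([np.asarray(r.image) for r in records])
        ip = np.stack([_anomaly(np.asarray(r.image)) for r in records])
        out = []
        for start in range(0, io.shape[0], self.outcome.config.batch_size_eval):
            sl = slice(start, start + self.outcome.config.batch_size_eval)
            _, cam = self.network.forward(io[sl], ip[sl], train=False)
            out.append(cam)
        return np.concatenate(out)

    def export_cams(self, records: list[PatchRecord], out_dir: str, colormap: bool = False) -> list[str]:
        """Write one CAM PNG per record (upsampled to input resolution)."""
        os.makedirs(out_dir, exist_ok=True)
        cams = self.cams(records)
        paths = []
        for rec, cam in zip(records, cams):
            size = np.asarray(rec.image).shape[:2]
            up = upsample_cam(cam, size)
            path = os.path.join(out_dir, f"cam-{rec.id}.png")
            if colormap:
                import matplotlib

                matplotlib.use("Agg", force=False)
                import matplotlib.pyplot as plt

                plt.imsave(path, up, cmap="jet", vmin=0.0, vmax=1.0)
            else:
                from PIL import Image

                Image.fromarray(np.rint(255 * up).astype(np.uint8)).save(path)
            paths.append(path)
        return paths

    # -- plots --------------------------------------------------------------
    def plot_curves(self, path: str) -> str:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        h = self.history
        axes[0].plot(h["epoch"], h["train_loss"], label="train")
        axes[0].plot(h["epoch"], h["val_loss"], label="val")
        axes[0].set_xlabel("epoch"), axes[0].set_ylabel("cross-entropy"), axes[0].legend()
        axes[1].plot(h["epoch"], h["train_acc"], label="train")
        axes[1].plot(h["epoch"], h["val_acc"], label="val")
        axes[1].set_xlabel("epoch"), axes[1].set_ylabel("accuracy"), axes[1].legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path

    def plot_confusion(self, path: str) -> str:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        cm = self.report.confusion
        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(cm, cmap="Blues")
        ax.set_xticks(range(len(self.report.classes)), self.report.classes, rotation=45, ha="right")
        ax.set_yticks(range(len(self.report.classes)), self.report.classes)
        ax.set_xlabel("predicted"), ax.set_ylabel("true")
        for i in range(cm.shape[0]):
            for j in range(cm.shape[1]):
                ax.text(j, i, str(cm[i, j]), ha="center", va="center", fontsize=9)
        fig.colorbar(im, shrink=0.8)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """A multi-seed synthetic experiment (the desk-scale default task)."""

    n_train_per_class: int = 100
    n_val_per_class: int = 40
    patch_size: int = 32
    backbone: str = "small_cnn"
    feature_channels: int = 32
    use_prior: bool = True
    use_attention: bool = True
    train: TrainConfig = field(default_factory=desk_config)
    seeds: tuple[int, ...] = (0, 1, 2)
    data_seed: int = 0


def default_task(
    n_train_per_class: int = 100,
    n_val_per_class: int = 40,
    patch_size: int = 32,
    seed: int = 0,
) -> tuple[list[PatchRecord], list[PatchRecord]]:
    """The default synthetic 4-class task: fixed train/val record lists.

    Train and validation sets are generated from disjoint generator streams
    so counts per class are exact on both sides.
    """
    train_records = generate_dataset(
        {c: n_train_per_class for c in CLASS_NAMES}, patch_size=patch_size, seed=seed
    )
    val_records = generate_dataset(
        {c: n_val_per_class for c in CLASS_NAMES},
        patch_size=patch_size,
        seed=seed + 100_003,
    )
    for r in train_records:
        r.split = "train"
        r.id = "train-" + r.id
    for r in val_records:
        r.split = "val"
        r.id = "val-" + r.id
    return train_records, val_records


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    per_seed: list[IHCClassifierResults]
    aggregate: pd.DataFrame  # rows: metric, columns: mean, sd

    def summary(self) -> str:
        return self.aggregate.to_string(float_format=lambda v: f"{v:.4f}")


_AGG_METRICS = ("macro_precision", "macro_recall", "macro_f1", "accuracy")


def run_experiment(
    cfg: ExperimentConfig,
    out_dir: str | None = None,
    verbose: bool = False,
) -> ExperimentResult:
    """Train/evaluate over ``cfg.seeds`` and aggregate metrics as mean +- sd."""
    train_records, val_records = default_task(
        cfg.n_train_per_class, cfg.n_val_per_class, cfg.patch_size, seed=cfg.data_seed
    )
    model = IHCClassifier(
        train_records,
        val_records,
        backbone=cfg.backbone,
        use_prior=cfg.use_prior,
        use_attention=cfg.use_attention,
        feature_channels=cfg.feature_channels,
    )
    per_seed = [
        model.fit(config=cfg.train, seed=s, verbose=verbose) for s in cfg.seeds
    ]
    values = {
        m: np.array([getattr(r.report, m) for r in per_seed]) for m in _AGG_METRICS
    }
    aggregate = pd.DataFrame(
        {
            "mean": {m: v.mean() for m, v in values.items()},
            "sd": {m: v.std(ddof=1) if len(v) > 1 else 0.0 for m, v in values.items()},
        }
    )
    result = ExperimentResult(config=cfg, per_seed=per_seed, aggregate=aggregate)
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        aggregate.to_csv(os.path.join(out_dir, "aggregate.csv"))
        for res in per_seed:
            tag = f"seed{res.seed}"
            res.history.to_csv(os.path.join(out_dir, f"curves-{tag}.csv"), index=False)
            res.plot_curves(os.path.join(out_dir, f"curves-{tag}.png"))
            res.plot_confusion(os.path.join(out_dir, f"confusion-{tag}.png"))
        sample = val_records[:: max(1, len(val_records) // 8)][:8]
        per_seed[0].export_cams(sample, os.path.join(out_dir, "cams"))
    return result


def compare_prior(
    cfg: ExperimentConfig,
    out_dir: str | None = None,
    verbose: bool = False,
) -> tuple[ExperimentResult, ExperimentResult, pd.DataFrame]:
    """Run the prior-guided model and the no-prior ablation on the same task.

    Returns both experiment results and a comparison table whose
    ``delta_macro_f1`` row is prior-guided minus baseline.
    """
    with_prior = run_experiment(
        replace(cfg, use_prior=True),
        out_dir=os.path.join(out_dir, "with_prior") if out_dir else None,
        verbose=verbose,
    )
    no_prior = run_experiment(
        replace(cfg, use_prior=False),
        out_dir=os.path.join(out_dir, "no_prior") if out_dir else None,
        verbose=verbose,
    )
    table = pd.DataFrame(
        {
            "with_prior": with_prior.aggregate["mean"],
            "no_prior": no_prior.aggregate["mean"],
        }
    )
    table["delta"] = table["with_prior"] - table["no_prior"]
    if out_dir:
        table.to_csv(os.path.join(out_dir, "prior_comparison.csv"))
    return with_prior, no_prior, table
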