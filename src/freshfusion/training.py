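"""Model assembly, training protocol, metrics, efficiency statistics, gate
analysis and activation heatmaps.

The full model couples the image branch (backbone + MDFA -> F_img) and the
chemical branch (TCN + 1-D MDFA -> F_chem) through the context-aware gated
fusion, followed by a 256 -> 128 -> 3 softmax head.  Baselines: ``concat``
(plain [F_img; F_chem] concatenation into the head), ``image_only`` and
``chem_only``.

Training follows a step-decay AdamW protocol: initial learning rate decayed
by 10% every 20 epochs, batch size 16, early stopping on validation accuracy
with patience 15, best-validation checkpoint restored.  The full model's
loss adds the gate interpretability hinge penalty (weight lambda).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from skimage.transform import resize as _sk_resize

from . import nn
from .chem_branch import ChemBranch, ChemNormalizer, TcnConfig
from .fusion import (CAGFusion, GateConstraintConfig, GateRecord,
                     gate_penalty_tensor)
from .image_branch import BackboneConfig, ImageBranch
from .nn import Module, Tensor
from .synthetic import CLASS_NAMES, MultimodalDataset

__all__ = [
    "ModelSizeConfig", "FreshFusionNet", "build_model", "TrainConfig",
    "TrainingData", "prepare_training_data", "train", "evaluate",
    "MetricsTable", "ModelResultRow", "EfficiencyReport",
    "efficiency_metrics", "gate_analysis", "activation_map",
    "stage_from_time",
]

VARIANTS = ("full", "image_only", "chem_only", "concat")

logger = logging.getLogger("freshfusion.training")


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSizeConfig:
    """Architecture size knobs shared by all variants."""

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    embed_dim: int = 256
    head_hidden: int = 128
    n_classes: int = 3
    tcn: TcnConfig = field(default_factory=TcnConfig)

    @classmethod
    def slim(cls) -> "ModelSizeConfig":
        """Quarter-width single-repeat backbone for scaled-down training."""
        return cls(backbone=BackboneConfig(width=0.25, single_repeats=True))


class _Head(Module):
    def __init__(self, in_dim: int, hidden: int, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, n_classes, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(nn.relu(self.fc1(x)))


class FreshFusionNet(Module):
    """Multimodal freshness classifier (or one of its reduced variants)."""

    def __init__(self, variant: str, size: ModelSizeConfig,
                 rng: np.random.Generator):
        super().__init__()
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected {VARIANTS}")
        self.variant = variant
        self.size = size
        d = size.embed_dim
        if variant in ("full", "image_only", "concat"):
            self.image_branch = ImageBranch(size.backbone, rng, d)
        if variant in ("full", "chem_only", "concat"):
            self.chem_branch = ChemBranch(size.tcn, rng)
        if variant == "full":
            self.fusion = CAGFusion(rng, d)
        head_in = 2 * d if variant == "concat" else d
        self.head = _Head(head_in, size.head_hidden, size.n_classes, rng)

    def forward(self, images: Tensor | None = None,
                chem: Tensor | None = None) -> Tensor:
        if self.variant == "image_only":
            feat = self.image_branch(images)
        elif self.variant == "chem_only":
            feat = self.chem_branch(chem)
        elif self.variant == "concat":
            feat = nn.concat([self.image_branch(images),
                              self.chem_branch(chem)], axis=1)
        else:
            f_img = self.image_branch(images)
            f_chem = self.chem_branch(chem)
            feat = self.fusion(f_img, f_chem)
        return self.head(feat)

    @property
    def last_gate(self) -> np.ndarray | None:
        return getattr(self, "fusion", None) and self.fusion._last_gate

    def params_millions(self) -> float:
        return self.num_parameters() / 1e6


def build_model(variant: str, size: ModelSizeConfig | None = None,
                seed: int = 0) -> FreshFusionNet:
    """Construct a seeded model of the requested variant."""
    if size is None:
        size = ModelSizeConfig()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    return FreshFusionNet(variant, size, rng)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

@dataclass
class TrainingData:
    """Model-ready arrays for one dataset (train + validation splits)."""

    images: np.ndarray          # (N, 3, H, W) float32 in [0, 1]
    chem: np.ndarray            # (N, 3, T) float32, z-scored
    labels: np.ndarray          # (N,) int
    ph: np.ndarray              # (N,) stored capture pH (for the penalty)
    time_h: np.ndarray          # (N,) capture time
    split: np.ndarray           # (N,) "train" / "val"
    sample_ids: np.ndarray      # (N,) image paths
    normalizer: ChemNormalizer

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.split == split)


def sequence_for_sample(traj_times: np.ndarray, traj_chem: np.ndarray,
                        time_h: float, row_chem: np.ndarray,
                        target_t: int = 6) -> np.ndarray:
    """3xT chemical input for one captured image.

    The sequence is the specimen's trajectory-to-date (measurements at times
    <= capture time) with the final step replaced by the row's own stored
    assay values, left-padded by repeating the first column when shorter
    than ``target_t``.
    """
    mask = traj_times <= time_h + 1e-9
    seq = traj_chem[:, mask].astype(float).copy()
    if seq.shape[1] == 0:
        seq = np.asarray(row_chem, dtype=float).reshape(3, 1)
    seq[:, -1] = row_chem
    t = seq.shape[1]
    if t < target_t:
        pad = np.repeat(seq[:, :1], target_t - t, axis=1)
        seq = np.concatenate([pad, seq], axis=1)
    elif t > target_t:
        seq = seq[:, -target_t:]
    return seq


def prepare_training_data(dataset: MultimodalDataset, target_t: int = 6,
                          ) -> TrainingData:
    """Convert a split dataset into model-ready arrays.

    Images go channels-first; chemical sequences are built per sample and
    z-scored per indicator with statistics from the training split only.
    """
    meta = dataset.meta
    if not set(meta["split"]) <= {"train", "val"}:
        raise ValueError("dataset must be split before training")
    images = np.transpose(dataset.images, (0, 3, 1, 2)).astype(np.float32)
    trajs = {sid: dataset.trajectory_array(sid)
             for sid in meta["specimen_id"].unique()}
    chem = np.empty((len(meta), 3, target_t), dtype=np.float64)
    for i, row in enumerate(meta.itertuples(index=False)):
        times, arr = trajs[row.specimen_id]
        row_chem = np.array([row.ph, row.tvbn_mg_per_100g,
                             row.tvc_log_cfu_per_g])
        chem[i] = sequence_for_sample(times, arr, row.time_h, row_chem,
                                      target_t)
    labels = meta["label"].map({c: i for i, c in enumerate(CLASS_NAMES)})
    split = meta["split"].to_numpy()
    normalizer = ChemNormalizer().fit(chem[split == "train"])
    chem = normalizer.transform(chem).astype(np.float32)
    return TrainingData(images=images, chem=chem,
                        labels=labels.to_numpy().astype(int),
                        ph=meta["ph"].to_numpy(dtype=float),
                        time_h=meta["time_h"].to_numpy(dtype=float),
                        split=split,
                        sample_ids=meta["image_path"].to_numpy(),
                        normalizer=normalizer)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol (defaults follow the study-scale recipe)."""

    lr0: float = 1e-4
    lr_decay: float = 0.9
    lr_decay_every: int = 20
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 15
    weight_decay: float = 1e-4
    gate_lambda: float = 0.1
    gate_constraint: GateConstraintConfig = field(
        default_factory=GateConstraintConfig)
    seed: int = 0

    def __post_init__(self):
        if self.lr0 <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("lr0, batch_size and max_epochs must be positive")

    def lr_at_epoch(self, epoch: int) -> float:
        """Step decay: lr0 * decay^(epoch // every); epochs are 1-based."""
        return self.lr0 * self.lr_decay ** ((epoch - 1) // self.lr_decay_every)

    @classmethod
    def slim(cls, **overrides) -> "TrainConfig":
        """Scaled-down protocol for the slim model on small synthetic data."""
        defaults = dict(lr0=1e-3, max_epochs=12)
        defaults.update(overrides)
        return cls(**defaults)


def _forward_batches(model: FreshFusionNet, data: TrainingData,
                     idx: np.ndarray, batch_size: int = 64,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eval-mode forward over ``idx``; returns (logits, gates, sims)."""
    model.eval()
    logits = np.empty((len(idx), model.size.n_classes), dtype=np.float64)
    gates = np.full(len(idx), np.nan)
    sims = np.full(len(idx), np.nan)
    uses_img = model.variant != "chem_only"
    uses_chem = model.variant != "image_only"
    for start in range(0, len(idx), batch_size):
        b = idx[start:start + batch_size]
        imgs = Tensor(data.images[b]) if uses_img else None
        chem = Tensor(data.chem[b]) if uses_chem else None
        out = model(imgs, chem)
        logits[start:start + len(b)] = out.data
        if model.variant == "full":
            gates[start:start + len(b)] = model.fusion._last_gate.ravel()
            sims[start:start + len(b)] = model.fusion._last_similarity.ravel()
    return logits, gates, sims


def train(model: FreshFusionNet, data: TrainingData,
          cfg: TrainConfig | None = None) -> dict:
    """Train in place; returns the per-epoch history.

    Cross-entropy (+ lambda * gate penalty for the full variant), AdamW with
    the step-decay schedule, early stopping on validation accuracy, best
    checkpoint restored before returning.
    """
    if cfg is None:
        cfg = TrainConfig()
    train_idx = data.indices("train")
    val_idx = data.indices("val")
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("both train and validation splits must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed))
    opt = nn.AdamW(model.parameters(), lr=cfg.lr0,
                   weight_decay=cfg.weight_decay)
    uses_img = model.variant != "chem_only"
    uses_chem = model.variant != "image_only"
    use_penalty = model.variant == "full" and cfg.gate_lambda > 0
    penalty_cfg = dataclasses.replace(cfg.gate_constraint,
                                      weight=cfg.gate_lambda)
    history = {"epoch": [], "lr": [], "train_loss": [], "val_accuracy": []}
    best_acc, best_state, best_epoch = -1.0, None, 0
    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = cfg.lr_at_epoch(epoch)
        model.train()
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            b = order[start:start + cfg.batch_size]
            if len(b) < 2:
                continue  # batch statistics need >= 2 samples
            imgs = Tensor(data.images[b]) if uses_img else None
            chem = Tensor(data.chem[b]) if uses_chem else None
            logits = model(imgs, chem)
            loss = nn.softmax_cross_entropy(logits, data.labels[b])
            if use_penalty:
                pen = gate_penalty_tensor(model.fusion._last_gate_tensor,
                                          data.ph[b], penalty_cfg)
                loss = nn.add(loss, pen)
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        logits, _, _ = _forward_batches(model, data, val_idx)
        val_acc = float(np.mean(logits.argmax(axis=1) == data.labels[val_idx]))
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_accuracy"].append(val_acc)
        logger.info("epoch=%d lr=%.2e train_loss=%.4f val_accuracy=%.4f",
                    epoch, opt.lr, history["train_loss"][-1], val_acc)
        if val_acc > best_acc:
            best_acc, best_state, best_epoch = val_acc, nn.clone_state(model), epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_accuracy"] = best_acc
    return history


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsTable:
    """Classification metrics plus the evaluated model's parameter count."""

    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class: pd.DataFrame          # precision/recall/f1/support per class
    confusion: np.ndarray            # rows = true class, cols = predicted
    n_parameters: int
    class_names: tuple[str, ...] = CLASS_NAMES

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "n_parameters": self.n_parameters,
        }


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           n_classes: int = 3,
                           class_names: tuple[str, ...] = CLASS_NAMES,
                           n_parameters: int = 0) -> MetricsTable:
    """Confusion-matrix based accuracy and macro precision/recall/F1.

    Classes absent from both truth and prediction contribute 0 to the macro
    averages (the usual zero-division convention).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    tp = np.diag(cm).astype(float)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / predicted, 0.0)
        recall = np.where(support > 0, tp / support, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    per_class = pd.DataFrame({
        "class": class_names[:n_classes],
        "precision": precision, "recall": recall, "f1": f1,
        "support": support,
    })
    return MetricsTable(
        accuracy=float(tp.sum() / max(cm.sum(), 1)),
        precision_macro=float(precision.mean()),
        recall_macro=float(recall.mean()),
        f1_macro=float(f1.mean()),
        per_class=per_class, confusion=cm, n_parameters=n_parameters,
        class_names=tuple(class_names[:n_classes]))


def evaluate(model: FreshFusionNet, data: TrainingData, split: str = "val",
             ) -> tuple[MetricsTable, pd.DataFrame]:
    """Metrics plus the per-sample gate-record table for ``split``.

    Gate columns (s, g) are NaN for variants without the fusion module.
    """
    idx = data.indices(split)
    if len(idx) == 0:
        raise ValueError(f"split {split!r} is empty")
    logits, gates, sims = _forward_batches(model, data, idx)
    preds = logits.argmax(axis=1)
    metrics = classification_metrics(data.labels[idx], preds,
                                     n_parameters=model.num_parameters())
    records = pd.DataFrame({
        "sample_id": data.sample_ids[idx],
        "s": sims,
        "g": gates,
        "ph": data.ph[idx],
        "stage": [stage_from_time(t) for t in data.time_h[idx]],
        "predicted": [CLASS_NAMES[p] for p in preds],
        "true": [CLASS_NAMES[t] for t in data.labels[idx]],
    })
    return metrics, records


# ---------------------------------------------------------------------------
# Efficiency statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelResultRow:
    """One model's headline numbers (percent metrics, parameters in M)."""

    name: str
    acc: float
    recall: float
    f1: float
    params_m: float
    precision: float | None = None
    fps: float | None = None


@dataclass
class EfficiencyReport:
    """Derived parameter-efficiency statistics for one result row."""

    name: str
    acc_per_mparam: float            # accuracy% / M params, 2 d.p.
    f1_per_mparam: float
    precision_recall_gap: float | None  # |precision - recall| in points
    delta_acc_pp: float | None = None       # accuracy gain vs reference
    delta_params_pct: float | None = None   # parameter increase vs reference


def efficiency_metrics(row: ModelResultRow,
                       reference: ModelResultRow | None = None,
                       ) -> EfficiencyReport:
    """Parameter-efficiency statistics, optionally versus a reference row."""
    if row.params_m <= 0:
        raise ValueError("parameter count must be positive")
    gap = (None if row.precision is None
           else round(abs(row.precision - row.recall), 2))
    report = EfficiencyReport(
        name=row.name,
        acc_per_mparam=round(row.acc / row.params_m, 2),
        f1_per_mparam=round(row.f1 / row.params_m, 2),
        precision_recall_gap=gap)
    if reference is not None:
        report.delta_acc_pp = round(row.acc - reference.acc, 2)
        report.delta_params_pct = round(
            100.0 * (row.params_m - reference.params_m) / reference.params_m, 1)
    return report


# ---------------------------------------------------------------------------
# Gate analysis
# ---------------------------------------------------------------------------

def stage_from_time(time_h: float) -> str:
    """Spoilage stage bucket by capture time: early <= 10 h, late >= 20 h."""
    if time_h <= 10.0:
        return "early"
    if time_h < 20.0:
        return "mid"
    return "late"


def gate_analysis(records: pd.DataFrame,
                  cfg: GateConstraintConfig | None = None) -> dict:
    """Summary of gate behaviour versus pH.

    Reports the Pearson correlation of g with pH (flagged undefined when
    either is constant), mean gate per stage bucket, mean gate in the low/high
    pH regimes, and the fraction of samples satisfying each constraint.
    """
    if cfg is None:
        cfg = GateConstraintConfig()
    recs = records.dropna(subset=["g", "ph"])
    if len(recs) < 2:
        raise ValueError("need at least 2 gate records with varying pH")
    g = recs["g"].to_numpy(dtype=float)
    ph = recs["ph"].to_numpy(dtype=float)
    undefined = bool(np.std(g) == 0 or np.std(ph) == 0)
    r = float("nan") if undefined else float(pearsonr(g, ph).statistic)
    low = ph < cfg.ph_low
    high = ph > cfg.ph_high
    out = {
        "pearson_r": r,
        "undefined_correlation": undefined,
        "mean_g_by_stage": recs.groupby("stage")["g"].mean().to_dict(),
        "n_low_ph": int(low.sum()),
        "n_high_ph": int(high.sum()),
        "mean_g_low_ph": float(g[low].mean()) if low.any() else float("nan"),
        "mean_g_high_ph": float(g[high].mean()) if high.any() else float("nan"),
        "frac_low_ph_satisfied": (float((g[low] > cfg.g_high).mean())
                                  if low.any() else float("nan")),
        "frac_high_ph_satisfied": (float((g[high] < cfg.g_low).mean())
                                   if high.any() else float("nan")),
    }
    return out


# ---------------------------------------------------------------------------
# Activation heatmaps
# ---------------------------------------------------------------------------

def activation_map(model: FreshFusionNet, image: np.ndarray, class_index: int,
                   chem: np.ndarray | None = None) -> np.ndarray:
    """Gradient-weighted class activation map over the MDFA output.

    Channel weights are the spatial means of the class logit's gradient on
    the MDFA output map; the weighted channel sum is rectified, normalised to
    [0, 1] (an all-zero map stays zero) and bilinearly upsampled to the input
    size.
    """
    if model.variant == "chem_only":
        raise ValueError("activation maps require an image branch")
    if not 0 <= class_index < model.size.n_classes:
        raise ValueError("class index out of range")
    model.eval()
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[2] == 3:
        img = np.transpose(img, (2, 0, 1))
    img_t = Tensor(img[None])
    chem_t = None
    if model.variant in ("full", "concat"):
        if chem is None:
            chem = np.zeros((3, 6), dtype=np.float32)  # neutral z-scored prior
        chem_t = Tensor(np.asarray(chem, dtype=np.float32)[None])
    logits = model(img_t, chem_t)
    onehot = np.zeros_like(logits.data)
    onehot[0, class_index] = 1.0
    logits.backward(onehot)
    act = model.image_branch._last_mdfa_out
    grad = act.grad[0]          # (C, h, w)
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    if cam.max() > 0:
        cam = cam / cam.max()
    h, w = img.shape[1], img.shape[2]
    return _sk_resize(cam, (h, w), order=1, preserve_range=True,
                      anti_aliasing=False).astype(np.float64)
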