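"""Dataset readers/writers, run-configuration schema, checkpoints, and the
prediction/report helpers behind the command-line interface.

On-disk dataset layout (produced by the simulator, consumed everywhere):

    <dir>/images/img_000000.png ...
    <dir>/metadata.csv       one row per image (capture metadata + chemistry
                             + label + split)
    <dir>/trajectories.csv   one row per (specimen, time): shared chemistry

Checkpoints are a ``.npz`` of parameter arrays plus a JSON sidecar echoing
the architecture hyperparameters and the chemical normalisation statistics,
validated on reload.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from pydantic import BaseModel, ConfigDict, field_validator

from .chem_branch import ChemNormalizer
from .image_branch import BackboneConfig
from .preprocess import AugmentPolicy, resize_image
from .synthetic import (CLASS_NAMES, METADATA_COLUMNS, DatasetConfig,
                        MultimodalDataset)
from .training import (FreshFusionNet, ModelSizeConfig, TrainConfig,
                       build_model, efficiency_metrics, ModelResultRow,
                       sequence_for_sample)
from . import nn
from .nn import Tensor

__all__ = [
    "RunConfig", "load_dataset", "save_checkpoint", "load_checkpoint",
    "predict", "report",
]


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    n_specimens: int = 4
    image_size: int = 512
    shots_per_condition: int = 10
    seed: int = 0

    def to_dataset_config(self) -> DatasetConfig:
        return DatasetConfig(n_specimens=self.n_specimens,
                             image_size=self.image_size,
                             shots_per_condition=self.shots_per_condition)


class AugmentSection(_Section):
    rotation_deg: float = 15.0
    hflip_prob: float = 0.5
    scale_lo: float = 0.8
    scale_hi: float = 1.2
    gamma_lo: float = 0.5
    gamma_hi: float = 1.5
    occlusion_lo: float = 0.10
    occlusion_hi: float = 0.20
    copies_per_image: int = 1
    seed: int = 0

    def to_policy(self) -> AugmentPolicy:
        return AugmentPolicy(
            rotation_deg=self.rotation_deg, hflip_prob=self.hflip_prob,
            scale_range=(self.scale_lo, self.scale_hi),
            gamma_range=(self.gamma_lo, self.gamma_hi),
            occlusion_area_frac=(self.occlusion_lo, self.occlusion_hi),
            copies_per_image=self.copies_per_image, seed=self.seed)


class ModelSection(_Section):
    variant: str = "full"
    slim: bool = False

    @field_validator("variant")
    @classmethod
    def _check_variant(cls, v):
        if v not in ("full", "image_only", "chem_only", "concat"):
            raise ValueError(f"unknown model variant {v!r}")
        return v

    def to_size_config(self) -> ModelSizeConfig:
        return ModelSizeConfig.slim() if self.slim else ModelSizeConfig()


class TrainSection(_Section):
    lr0: float = 1e-4
    lr_decay: float = 0.9
    lr_decay_every: int = 20
    batch_size: int = 16
    max_epochs: int = 50
    patience: int = 15
    weight_decay: float = 1e-4
    gate_lambda: float = 0.1
    train_frac: float = 0.8
    seed: int = 0

    def to_train_config(self) -> TrainConfig:
        return TrainConfig(lr0=self.lr0, lr_decay=self.lr_decay,
                           lr_decay_every=self.lr_decay_every,
                           batch_size=self.batch_size,
                           max_epochs=self.max_epochs, patience=self.patience,
                           weight_decay=self.weight_decay,
                           gate_lambda=self.gate_lambda, seed=self.seed)


class EvaluateSection(_Section):
    split: str = "val"


class RunConfig(_Section):
    """Nested run configuration; unknown keys are rejected on parse."""

    simulate: SimulateSection = SimulateSection()
    augment: AugmentSection = AugmentSection()
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    evaluate: EvaluateSection = EvaluateSection()

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RunConfig":
        text = str(source)
        if "\n" not in text and len(text) < 4096 and Path(text).exists():
            text = Path(text).read_text()
        return cls.model_validate(yaml.safe_load(text) or {})

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Dataset loading
# ---------------------------------------------------------------------------

def load_dataset(directory: str | Path) -> MultimodalDataset:
    """Load a dataset directory; malformed rows are reported by row number."""
    directory = Path(directory)
    meta_path = directory / "metadata.csv"
    if not meta_path.exists():
        raise FileNotFoundError(
            f"no dataset at {directory}: metadata.csv is missing")
    meta = pd.read_csv(meta_path, keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata.csv lacks columns {missing_cols}")
    bad_rows = []
    for i, row in enumerate(meta.itertuples(index=False)):
        if row.label not in CLASS_NAMES:
            bad_rows.append((i, f"unknown label {row.label!r}"))
        if not (directory / row.image_path).exists():
            bad_rows.append((i, f"missing image file {row.image_path}"))
    if bad_rows:
        listing = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:20])
        raise ValueError(f"invalid dataset rows -- {listing}")
    traj_path = directory / "trajectories.csv"
    trajectories = (pd.read_csv(traj_path) if traj_path.exists()
                    else pd.DataFrame(columns=["specimen_id", "time_h", "ph",
                                               "tvbn_mg_per_100g",
                                               "tvc_log_cfu_per_g"]))
    images = None
    for i, rel in enumerate(meta["image_path"]):
        arr = np.asarray(Image.open(directory / rel).convert("RGB"),
                         dtype=np.float32) / 255.0
        if images is None:
            images = np.empty((len(meta),) + arr.shape, dtype=np.float32)
        images[i] = arr
    if images is None:
        images = np.empty((0, 0, 0, 3), dtype=np.float32)
    return MultimodalDataset(images=images, meta=meta,
                             trajectories=trajectories)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: FreshFusionNet, path: str | Path,
                    normalizer: ChemNormalizer | None = None,
                    extra: dict | None = None) -> None:
    """Write ``<path>.npz`` (weights) and ``<path>.json`` (architecture)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    sidecar = {
        "variant": model.variant,
        "backbone_width": model.size.backbone.width,
        "backbone_single_repeats": model.size.backbone.single_repeats,
        "embed_dim": model.size.embed_dim,
        "head_hidden": model.size.head_hidden,
        "n_classes": model.size.n_classes,
        "class_names": list(CLASS_NAMES),
        "normalizer": normalizer.state() if normalizer else None,
    }
    sidecar.update(extra or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path,
                    ) -> tuple[FreshFusionNet, ChemNormalizer | None, dict]:
    """Rebuild the model from the sidecar and load the weights."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    size = ModelSizeConfig(
        backbone=BackboneConfig(width=sidecar["backbone_width"],
                                single_repeats=sidecar["backbone_single_repeats"]),
        embed_dim=sidecar["embed_dim"], head_hidden=sidecar["head_hidden"],
        n_classes=sidecar["n_classes"])
    model = build_model(sidecar["variant"], size)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    norm = (ChemNormalizer.from_state(sidecar["normalizer"])
            if sidecar.get("normalizer") else None)
    return model, norm, sidecar


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(model: FreshFusionNet, image_path: str | Path,
            chem_csv: str | Path | None = None,
            normalizer: ChemNormalizer | None = None,
            image_size: int | None = None, target_t: int = 6) -> dict:
    """Classify one film image, optionally with its chemical history.

    ``chem_csv`` must carry columns (time_h, ph, tvbn_mg_per_100g,
    tvc_log_cfu_per_g); the most recent row is the capture state.  Without
    chemical data the chemical branch receives the neutral (z-scored zero)
    prior and the output is flagged ``image_only``.
    """
    image_path = Path(image_path)
    if not image_path.exists():
        raise FileNotFoundError(f"unreadable image {image_path}")
    img = np.asarray(Image.open(image_path).convert("RGB"),
                     dtype=np.float32) / 255.0
    if image_size is not None and img.shape[:2] != (image_size, image_size):
        img = resize_image(img, image_size).astype(np.float32)
    img_t = Tensor(np.transpose(img, (2, 0, 1))[None])

    chem_echo = None
    image_only = chem_csv is None
    chem_arr = np.zeros((3, target_t), dtype=np.float32)
    if chem_csv is not None:
        chem_df = pd.read_csv(chem_csv).sort_values("time_h")
        needed = {"time_h", "ph", "tvbn_mg_per_100g", "tvc_log_cfu_per_g"}
        if chem_df.empty or not needed <= set(chem_df.columns):
            image_only = True
        else:
            times = chem_df["time_h"].to_numpy(dtype=float)
            arr = chem_df[["ph", "tvbn_mg_per_100g",
                           "tvc_log_cfu_per_g"]].to_numpy().T
            seq = sequence_for_sample(times, arr, times[-1], arr[:, -1],
                                      target_t)
            if normalizer is not None:
                seq = normalizer.transform(seq[None])[0]
            chem_arr = seq.astype(np.float32)
            chem_echo = {"ph": float(arr[0, -1]), "tvbn": float(arr[1, -1]),
                         "tvc": float(arr[2, -1])}
    chem_t = Tensor(chem_arr[None])
    model.eval()
    if model.variant == "image_only":
        logits = model(img_t, None)
    elif model.variant == "chem_only":
        logits = model(None, chem_t)
    else:
        logits = model(img_t, chem_t)
    probs = nn.softmax(logits.data)[0]
    out = {
        "label": CLASS_NAMES[int(probs.argmax())],
        "probabilities": {c: float(p) for c, p in zip(CLASS_NAMES, probs)},
        "image_only": bool(image_only),
        "chem": chem_echo,
    }
    if model.variant == "full":
        out["g"] = float(model.fusion._last_gate.ravel()[0])
        out["s"] = float(model.fusion._last_similarity.ravel()[0])
    return out


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

_RESULT_KEYS = ("name", "acc", "recall", "f1", "params_m")


def _rows_from_source(source) -> list[ModelResultRow]:
    if isinstance(source, ModelResultRow):
        return [source]
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text())
        docs = doc if isinstance(doc, list) else [doc]
        return [ModelResultRow(name=d["name"], acc=d["acc"], recall=d["recall"],
                               f1=d["f1"], params_m=d["params_m"],
                               precision=d.get("precision"), fps=d.get("fps"))
                for d in docs]
    raise TypeError(f"unsupported metrics source {source!r}")


def report(sources, reference: ModelResultRow | None = None) -> pd.DataFrame:
    """Merge result rows into one comparison table with efficiency columns.

    Duplicate model names are disambiguated with numeric suffixes.  When a
    ``reference`` row is given, per-row deltas (accuracy in points,
    parameters in percent) are included.
    """
    rows: list[ModelResultRow] = []
    for source in (sources if isinstance(sources, (list, tuple)) else [sources]):
        rows.extend(_rows_from_source(source))
    if not rows:
        raise ValueError("report needs at least one metrics row")
    seen: dict[str, int] = {}
    table = []
    for row in rows:
        n = seen.get(row.name, 0)
        seen[row.name] = n + 1
        name = row.name if n == 0 else f"{row.name}_{n + 1}"
        eff = efficiency_metrics(row, reference)
        entry = {
            "name": name, "acc": row.acc, "recall": row.recall, "f1": row.f1,
            "precision": row.precision, "params_m": row.params_m,
            "acc_per_mparam": eff.acc_per_mparam,
            "f1_per_mparam": eff.f1_per_mparam,
            "precision_recall_gap": eff.precision_recall_gap,
        }
        if reference is not None:
            entry["delta_acc_pp"] = eff.delta_acc_pp
            entry["delta_params_pct"] = eff.delta_params_pct
        table.append(entry)
    return pd.DataFrame(table)
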