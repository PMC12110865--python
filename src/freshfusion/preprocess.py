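"""Image preprocessing, augmentation, dataset expansion/split, and the
pH-from-RGB calibration.

The augmentation pipeline mirrors a film-photography robustness recipe:
histogram equalization (luminance only, so hue -- the freshness signal -- is
preserved), gamma correction sampled in [0.5, 1.5], random rotation within
+/-15 degrees, horizontal flip with probability 0.5, random rescale in
[0.8, 1.2] (reflection-padded/cropped back to the source frame) and one
rectangular occlusion covering 10-20% of the image area.  Applying one
augmented copy per source image doubles the dataset (e.g. 3600 -> 7200).

The calibration maps the film's color to pH: the mean RGB of the central
window is reduced to a single hue-angle scalar (monotone across the film's
dark-red -> yellow transition) and a least-squares cubic maps that scalar to
pH, clamped to the film's response range [5.8, 8.6].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from skimage.transform import rescale as _sk_rescale
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

from .synthetic import FILM_PH_RANGE, MultimodalDataset

__all__ = [
    "resize_image", "normalize_rgb", "equalize_histogram", "gamma_correct",
    "AugmentPolicy", "AugmentParams", "sample_augment_params",
    "apply_augment", "augment_image", "augment_dataset", "split_dataset",
    "extract_center_rgb", "color_scalar", "PhCalibration",
    "fit_ph_calibration", "rgb_to_ph",
]

COLOR_SCALAR_DEF = (
    "hue angle (degrees) of the mean RGB, unwrapped to the interval "
    "[-70, 290) so the film's dark-red -> yellow transition is monotone"
)


# ---------------------------------------------------------------------------
# Elementary image operations
# ---------------------------------------------------------------------------

def resize_image(image: np.ndarray, target: int = 512) -> np.ndarray:
    """Bilinear resize to ``target`` x ``target`` (channels preserved)."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    if image.shape[:2] == (target, target):
        return image.copy()
    out = _sk_resize(image, (target, target), order=1, preserve_range=True,
                     anti_aliasing=False)
    return out.astype(image.dtype if np.issubdtype(image.dtype, np.floating)
                      else np.float64)


def normalize_rgb(image: np.ndarray) -> np.ndarray:
    """Linearly map 8-bit channel values 0-255 to [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 255:
        raise ValueError("normalize_rgb expects values within [0, 255]")
    return image / 255.0


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Exact CDF equalization of the luminance (HSV value) channel.

    Hue and saturation are untouched so the film's color signal survives;
    each luminance level v is mapped to P(V <= v) over the image.  A
    constant image is returned unchanged (degenerate CDF contract).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("equalize_histogram expects values within [0, 1]")
    hsv = rgb_to_hsv(image)
    v = hsv[..., 2]
    if v.max() - v.min() < 1e-12:
        return image.copy()
    flat = np.sort(v.ravel())
    cdf = np.searchsorted(flat, v, side="right") / flat.size
    hsv = hsv.copy()
    hsv[..., 2] = cdf
    return np.clip(hsv_to_rgb(hsv), 0.0, 1.0)


def gamma_correct(image: np.ndarray, gamma: float) -> np.ndarray:
    """Elementwise power-law correction ``out = in ** gamma``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("gamma_correct expects values within [0, 1]")
    return image ** gamma


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentPolicy:
    """Ranges of the stochastic augmentation operators."""

    rotation_deg: float = 15.0
    hflip_prob: float = 0.5
    scale_range: tuple[float, float] = (0.8, 1.2)
    gamma_range: tuple[float, float] = (0.5, 1.5)
    occlusion_area_frac: tuple[float, float] = (0.10, 0.20)
    copies_per_image: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hflip_prob <= 1.0:
            raise ValueError("hflip_prob must lie in [0, 1]")
        for name in ("scale_range", "gamma_range", "occlusion_area_frac"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (lo <= hi)")
        lo, hi = self.occlusion_area_frac
        if not (0.0 < lo and hi < 1.0):
            raise ValueError("occlusion_area_frac must lie within (0, 1)")
        if self.rotation_deg < 0:
            raise ValueError("rotation_deg must be non-negative")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


@dataclass(frozen=True)
class AugmentParams:
    """One concrete draw from an :class:`AugmentPolicy`."""

    gamma: float
    rotation_deg: float
    hflip: bool
    scale: float
    occlusion_frac: float
    occlusion_aspect: float
    occlusion_cx: float  # center, as a fraction of width
    occlusion_cy: float


def sample_augment_params(policy: AugmentPolicy,
                          rng: np.random.Generator) -> AugmentParams:
    return AugmentParams(
        gamma=float(rng.uniform(*policy.gamma_range)),
        rotation_deg=float(rng.uniform(-policy.rotation_deg, policy.rotation_deg)),
        hflip=bool(rng.random() < policy.hflip_prob),
        scale=float(rng.uniform(*policy.scale_range)),
        occlusion_frac=float(rng.uniform(*policy.occlusion_area_frac)),
        occlusion_aspect=float(rng.uniform(0.5, 2.0)),
        occlusion_cx=float(rng.uniform(0.0, 1.0)),
        occlusion_cy=float(rng.uniform(0.0, 1.0)),
    )


def _rescale_keep_frame(image: np.ndarray, scale: float) -> np.ndarray:
    """Rescale then center-crop (zoom in) or reflect-pad (zoom out) back."""
    h, w = image.shape[:2]
    out = _sk_rescale(image, scale, order=1, mode="reflect",
                      channel_axis=2, anti_aliasing=False)
    oh, ow = out.shape[:2]
    if oh >= h:
        top = (oh - h) // 2
        left = (ow - w) // 2
        return out[top:top + h, left:left + w]
    pad_h, pad_w = h - oh, w - ow
    return np.pad(out, ((pad_h // 2, pad_h - pad_h // 2),
                        (pad_w // 2, pad_w - pad_w // 2), (0, 0)),
                  mode="reflect")


def _occlude(image: np.ndarray, params: AugmentParams,
             fill: float = 0.5) -> np.ndarray:
    h, w = image.shape[:2]
    area = params.occlusion_frac * h * w
    rw = int(round(np.sqrt(area * params.occlusion_aspect)))
    rh = int(round(area / max(rw, 1)))
    rw, rh = min(max(rw, 1), w), min(max(rh, 1), h)
    cx = int(params.occlusion_cx * (w - rw))
    cy = int(params.occlusion_cy * (h - rh))
    out = image.copy()
    out[cy:cy + rh, cx:cx + rw] = fill
    return out


def apply_augment(image: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Deterministically apply one sampled augmentation.

    Order: equalize -> gamma -> rotate -> flip -> scale -> occlusion.
    Rotation and rescale use reflection padding back to the source frame, so
    shape and the [0, 1] range are preserved.
    """
    out = equalize_histogram(image)
    out = gamma_correct(out, params.gamma)
    out = _sk_rotate(out, params.rotation_deg, mode="reflect", order=1)
    if params.hflip:
        out = out[:, ::-1]
    out = _rescale_keep_frame(out, params.scale)
    out = _occlude(out, params)
    return np.clip(out, 0.0, 1.0)


def augment_image(image: np.ndarray, policy: AugmentPolicy,
                  seed: int = 0) -> np.ndarray:
    """Sample one augmentation from ``policy`` (seeded) and apply it."""
    rng = np.random.default_rng(seed)
    return apply_augment(image, sample_augment_params(policy, rng))


def augment_dataset(dataset: MultimodalDataset,
                    policy: AugmentPolicy) -> MultimodalDataset:
    """Expand the dataset with ``copies_per_image`` augmented copies per image.

    Output size is input x (1 + copies); originals are retained and each
    augmented row carries a ``source_image_path`` provenance link and
    inherits its source's split assignment.
    """
    n = len(dataset)
    meta = dataset.meta.copy()
    if "source_image_path" not in meta.columns:
        meta["source_image_path"] = ""
    if n == 0 or policy.copies_per_image == 0:
        return MultimodalDataset(dataset.images.copy(), meta,
                                 dataset.trajectories.copy())
    seeds = np.random.SeedSequence(entropy=policy.seed).generate_state(
        n * policy.copies_per_image) & 0x7FFFFFFF
    new_images = [dataset.images]
    new_rows = []
    k = 0
    for copy_idx in range(policy.copies_per_image):
        batch = np.empty_like(dataset.images)
        for i in range(n):
            batch[i] = augment_image(
                dataset.images[i].astype(np.float64), policy,
                seed=int(seeds[k])).astype(np.float32)
            k += 1
        new_images.append(batch)
        rows = dataset.meta.copy()
        rows["source_image_path"] = rows["image_path"]
        rows["image_path"] = [
            p.replace(".png", f"_aug{copy_idx}.png") for p in rows["image_path"]]
        if "source_image_path" not in rows.columns:
            rows["source_image_path"] = ""
        new_rows.append(rows)
    meta_out = pd.concat([meta] + new_rows, ignore_index=True)
    return MultimodalDataset(np.concatenate(new_images, axis=0), meta_out,
                             dataset.trajectories.copy())


# ---------------------------------------------------------------------------
# Split
# ---------------------------------------------------------------------------

def split_dataset(dataset: MultimodalDataset, train_frac: float = 0.8,
                  seed: int = 0) -> MultimodalDataset:
    """Stratified train/validation assignment, written to the split column.

    Per class, ``round(train_frac * n_class)`` rows go to train (within one
    sample of the requested fraction); classes with fewer than 2 rows are
    placed in train with a warning.  Deterministic given ``seed``.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    meta = dataset.meta.copy()
    split = np.empty(len(meta), dtype=object)
    for label, group in meta.groupby("label", sort=True):
        idx = group.index.to_numpy()
        if len(idx) < 2:
            warnings.warn(
                f"class {label!r} has fewer than 2 samples; placed in train")
            split[idx] = "train"
            continue
        perm = rng.permutation(len(idx))
        k = int(round(train_frac * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        split[idx[perm[:k]]] = "train"
        split[idx[perm[k:]]] = "val"
    meta["split"] = split
    return MultimodalDataset(dataset.images, meta, dataset.trajectories)


# ---------------------------------------------------------------------------
# pH calibration
# ---------------------------------------------------------------------------

def extract_center_rgb(image: np.ndarray, window: int = 100) -> np.ndarray:
    """Mean RGB over the centered ``window`` x ``window`` region."""
    h, w = image.shape[:2]
    if h < window or w < window:
        raise ValueError(f"image ({h}x{w}) smaller than window {window}")
    top = (h - window) // 2
    left = (w - window) // 2
    return np.asarray(
        image[top:top + window, left:left + window].reshape(-1, image.shape[2])
        .mean(axis=0))


def color_scalar(rgb: np.ndarray) -> float:
    """Reduce an RGB triple to the calibration abscissa (unwrapped hue angle)."""
    rgb = np.clip(np.asarray(rgb, dtype=np.float64), 0.0, 1.0)
    hue_deg = float(rgb_to_hsv(rgb.reshape(1, 1, 3))[0, 0, 0]) * 360.0
    return ((hue_deg + 70.0) % 360.0) - 70.0


@dataclass
class PhCalibration:
    """Cubic polynomial mapping the film's color scalar to pH."""

    coefficients: np.ndarray  # length 4, highest degree first
    r_squared: float
    color_scalar_def: str = COLOR_SCALAR_DEF

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (4,):
            raise ValueError("calibration must be a cubic (4 coefficients)")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({
            "coefficients": self.coefficients.tolist(),
            "r_squared": self.r_squared,
            "color_scalar_def": self.color_scalar_def,
        }, indent=2)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "PhCalibration":
        text = str(source)
        if "\n" not in text and len(text) < 4096 and Path(text).exists():
            text = Path(text).read_text()
        doc = json.loads(text)
        return cls(np.asarray(doc["coefficients"]), float(doc["r_squared"]),
                   doc.get("color_scalar_def", COLOR_SCALAR_DEF))


def fit_ph_calibration(color_scalars: np.ndarray,
                       ph_values: np.ndarray) -> PhCalibration:
    """Least-squares cubic fit of pH against the color scalar."""
    x = np.asarray(color_scalars, dtype=float)
    y = np.asarray(ph_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("color_scalars and ph_values must be equal-length 1-D")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct color scalars for a cubic fit")
    coeffs = np.polyfit(x, y, deg=3)
    resid = y - np.polyval(coeffs, x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-12 else 1.0 - ss_res / max(ss_tot, 1e-300)
    return PhCalibration(coeffs, r2)


def rgb_to_ph(calibration: PhCalibration, rgb: np.ndarray) -> float:
    """Evaluate the calibration at an RGB triple, clamped to the film range."""
    if calibration is None or calibration.coefficients is None:
        raise ValueError("calibration has not been fitted")
    ph = float(np.polyval(calibration.coefficients, color_scalar(rgb)))
    return float(np.clip(ph, *FILM_PH_RANGE))
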