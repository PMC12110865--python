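"""Synthetic multimodal spoilage-data simulator.

Emulates the data a smartphone-based fish-freshness study collects: fish
specimens spoil at 25 degC over 25 h; a betalain pH-indicator film placed on
the fish drifts from dark red toward yellow as volatile amines raise the pH;
a phone photographs the film every 5 h under three lighting conditions and
five angles; pH, total volatile basic nitrogen (TVB-N, mg/100 g) and total
viable count (TVC, log10 CFU/g) are recorded alongside.

Chemical kinetics are three-parameter logistic curves per indicator between
anchor values typical for fresh and severely spoiled fish.  Lighting is a
diagonal RGB gain plus a brightness scale; viewing angle is an elliptical
foreshortening of the film disc.  All randomness flows from a single integer
seed through :class:`numpy.random.SeedSequence` spawning, so the generator is
fully reproducible and no global random state is touched.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from PIL import Image

__all__ = [
    "KineticsParams", "SpoilageTrajectory", "CaptureCondition",
    "FilmImageSample", "DatasetConfig", "MultimodalDataset",
    "simulate_trajectory", "ph_to_film_color", "render_film_image",
    "label_sample", "generate_dataset", "default_capture_times",
    "LIGHTING_CONDITIONS", "CAPTURE_ANGLES_DEG", "CLASS_NAMES",
    "FILM_PH_RANGE", "FILM_ACID_HSV", "FILM_ALKALINE_HSV",
    "DEFAULT_LABEL_BOUNDARIES",
]

CLASS_NAMES = ("fresh", "qualified", "inedible")

#: Response range of the betalain indicator film (clamped outside).
FILM_PH_RANGE = (5.8, 8.6)

#: HSV anchors of the film color.  Hue is expressed in degrees and runs
#: monotonically from dark red (-10 deg == 350 deg) to yellow (55 deg) as pH
#: rises, so hue angle is an invertible readout of pH.
FILM_ACID_HSV = (-10.0, 0.85, 0.45)     # dark red at pH <= 5.8
FILM_ALKALINE_HSV = (55.0, 0.88, 0.92)  # yellow at pH >= 8.6

#: Lighting conditions: name -> (RGB gain triple, brightness scale, lux).
LIGHTING_CONDITIONS = {
    "natural_D65": ((1.00, 1.00, 1.00), 1.00, 1000),
    "cool_LED": ((0.92, 0.97, 1.08), 0.90, 500),
    "warm_LED": ((1.08, 1.00, 0.88), 0.80, 300),
}

CAPTURE_ANGLES_DEG = (0, 30, 60, 90, 120)

#: TVB-N class boundaries (mg/100 g): fresh < b1, qualified in [b1, b2],
#: inedible > b2.  Common regulatory convention; configurable.
DEFAULT_LABEL_BOUNDARIES = (15.0, 30.0)


def default_capture_times(span_h: float = 25.0, n_points: int = 6) -> np.ndarray:
    """Capture grid: every 5 h over 25 h -> {0, 5, 10, 15, 20, 25} h."""
    return np.linspace(0.0, span_h, n_points)


# ---------------------------------------------------------------------------
# Chemical kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticsParams:
    """Logistic spoilage kinetics for the three chemical indicators.

    Each indicator follows ``start + (end - start) / (1 + exp(-steepness *
    (t - midpoint_h)))``.  Defaults anchor the fresh state near pH 6.20,
    TVB-N < 6.08 mg/100 g, TVC < 5.40 log CFU/g and the severely spoiled
    state above TVB-N 50 mg/100 g.
    """

    ph_start: float = 6.20
    ph_end: float = 7.50
    tvbn_start: float = 5.0
    tvbn_end: float = 60.0
    tvc_start: float = 4.5
    tvc_end: float = 9.5
    midpoint_h: float = 12.5
    steepness: float = 0.35
    noise_sd: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (pH, TVB-N, TVC)
    seed: int = 0

    def __post_init__(self):
        for lo, hi, name in ((self.ph_start, self.ph_end, "ph"),
                             (self.tvbn_start, self.tvbn_end, "tvbn"),
                             (self.tvc_start, self.tvc_end, "tvc")):
            if lo > hi:
                raise ValueError(f"{name}: start must not exceed end")
        if any(sd < 0 for sd in self.noise_sd):
            raise ValueError("noise_sd must be non-negative")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")


@dataclass
class SpoilageTrajectory:
    """Chemical time series for one specimen."""

    times: np.ndarray        # hours, ascending
    ph: np.ndarray
    tvbn: np.ndarray         # mg/100 g
    tvc: np.ndarray          # log CFU/g
    specimen_id: str = "specimen_0"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        self.tvbn = np.asarray(self.tvbn, dtype=float)
        self.tvc = np.asarray(self.tvc, dtype=float)
        n = len(self.times)
        if not (len(self.ph) == len(self.tvbn) == len(self.tvc) == n):
            raise ValueError("all series must have equal length")
        if n and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def values_at(self, index: int) -> tuple[float, float, float]:
        return float(self.ph[index]), float(self.tvbn[index]), float(self.tvc[index])

    def as_array(self) -> np.ndarray:
        """3 x N array with rows (pH, TVB-N, TVC)."""
        return np.stack([self.ph, self.tvbn, self.tvc])


def _logistic(t: np.ndarray, start: float, end: float, mid: float,
              steep: float) -> np.ndarray:
    return start + (end - start) / (1.0 + np.exp(-steep * (t - mid)))


def simulate_trajectory(params: KineticsParams,
                        times: np.ndarray | None = None,
                        specimen_id: str = "specimen_0",
                        rng: np.random.Generator | None = None,
                        ) -> SpoilageTrajectory:
    """Simulate one specimen's chemical trajectory on the given time grid.

    With ``noise_sd == 0`` the series are deterministic monotone sigmoids
    between the start/end anchors; otherwise i.i.d. Gaussian measurement
    noise is added per time point.
    """
    if times is None:
        times = default_capture_times()
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    ph = _logistic(times, params.ph_start, params.ph_end,
                   params.midpoint_h, params.steepness)
    tvbn = _logistic(times, params.tvbn_start, params.tvbn_end,
                     params.midpoint_h, params.steepness)
    tvc = _logistic(times, params.tvc_start, params.tvc_end,
                    params.midpoint_h, params.steepness)
    sd_ph, sd_tvbn, sd_tvc = params.noise_sd
    if sd_ph:
        ph = ph + rng.normal(0.0, sd_ph, size=times.shape)
    if sd_tvbn:
        tvbn = tvbn + rng.normal(0.0, sd_tvbn, size=times.shape)
    if sd_tvc:
        tvc = tvc + rng.normal(0.0, sd_tvc, size=times.shape)
    return SpoilageTrajectory(times, ph, tvbn, tvc, specimen_id)


# ---------------------------------------------------------------------------
# Film color model
# ---------------------------------------------------------------------------

def ph_to_film_color(ph: float) -> np.ndarray:
    """Base RGB color (values in [0, 1]) of the indicator film at a given pH.

    Linear interpolation in HSV between the dark-red anchor at pH <= 5.8 and
    the yellow anchor at pH >= 8.6; hue moves monotonically through red and
    orange.  pH outside the film's response range is clamped.
    """
    if not math.isfinite(ph):
        raise ValueError("pH must be finite")
    lo, hi = FILM_PH_RANGE
    frac = np.clip((ph - lo) / (hi - lo), 0.0, 1.0)
    h = FILM_ACID_HSV[0] + frac * (FILM_ALKALINE_HSV[0] - FILM_ACID_HSV[0])
    s = FILM_ACID_HSV[1] + frac * (FILM_ALKALINE_HSV[1] - FILM_ACID_HSV[1])
    v = FILM_ACID_HSV[2] + frac * (FILM_ALKALINE_HSV[2] - FILM_ACID_HSV[2])
    return hsv_to_rgb(((h % 360.0) / 360.0, s, v)).astype(np.float64)


def film_hue_angle(ph: float) -> float:
    """Unwrapped hue angle in degrees (monotone increasing in pH)."""
    lo, hi = FILM_PH_RANGE
    frac = np.clip((ph - lo) / (hi - lo), 0.0, 1.0)
    return FILM_ACID_HSV[0] + frac * (FILM_ALKALINE_HSV[0] - FILM_ACID_HSV[0])


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CaptureCondition:
    """One photographic condition: lighting regime and shooting angle."""

    lighting: str = "natural_D65"
    angle_deg: int = 0

    def __post_init__(self):
        if self.lighting not in LIGHTING_CONDITIONS:
            raise ValueError(
                f"unknown lighting {self.lighting!r}; expected one of "
                f"{sorted(LIGHTING_CONDITIONS)}")
        if self.angle_deg not in CAPTURE_ANGLES_DEG:
            raise ValueError(
                f"angle_deg must be one of {CAPTURE_ANGLES_DEG}")

    @property
    def illuminance_lux(self) -> int:
        return LIGHTING_CONDITIONS[self.lighting][2]

    @property
    def rgb_gain(self) -> np.ndarray:
        gain, brightness, _ = LIGHTING_CONDITIONS[self.lighting]
        return np.asarray(gain) * brightness


BACKGROUND_GRAY = 0.72
FILM_RADIUS_FRAC = 0.38


def render_film_image(color: np.ndarray, condition: CaptureCondition,
                      size: int = 64, seed: int = 0,
                      noise_sd: float = 0.02) -> np.ndarray:
    """Render a film patch of the given base color on a neutral background.

    The film is an ellipse (a disc foreshortened by the shooting angle) of
    uniform base color.  The lighting condition applies a deterministic
    diagonal RGB gain and brightness scale to the whole frame, so the film
    interior mean equals ``color * gain`` exactly when ``noise_sd == 0``.
    Seeded Gaussian speckle noise is added on top; output is HxWx3 float32
    clamped to [0, 1].
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    color = np.asarray(color, dtype=np.float64)
    gain = condition.rgb_gain
    rng = np.random.default_rng(seed)

    img = np.full((size, size, 3), BACKGROUND_GRAY, dtype=np.float64)
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    # foreshortening: front view (0 deg) is a circle, oblique views squash
    # the vertical axis; 120 deg looks like 60 deg from the other side
    squash = 0.4 + 0.6 * abs(math.cos(math.radians(condition.angle_deg)))
    a = FILM_RADIUS_FRAC * size
    b = a * squash
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    img[mask] = color
    img *= gain[None, None, :]
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def label_sample(chem: tuple[float, float, float],
                 boundaries: tuple[float, float] = DEFAULT_LABEL_BOUNDARIES,
                 ) -> str:
    """Three-way freshness label from the TVB-N value.

    fresh if TVB-N < b1, qualified if b1 <= TVB-N <= b2, inedible if > b2.
    """
    b1, b2 = boundaries
    if b1 >= b2:
        raise ValueError("label boundaries must satisfy b1 < b2")
    tvbn = chem[1]
    if tvbn < b1:
        return "fresh"
    if tvbn <= b2:
        return "qualified"
    return "inedible"


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetConfig:
    """Factorised design of the synthetic capture campaign.

    The default factorisation (4 specimens x 6 time points x 3 lightings x
    5 angles x 10 shots) yields 3600 images, matching the study-scale design;
    ``expected_total`` cross-checks the arithmetic.  Per-specimen kinetic
    variation (midpoint/steepness/endpoint jitter) makes specimens
    heterogeneous, and ``capture_noise_sd`` adds an independent
    assay-replicate error to the chemical values stored with each image.
    """

    n_specimens: int = 4
    times: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)
    lightings: tuple[str, ...] = ("natural_D65", "cool_LED", "warm_LED")
    angles_deg: tuple[int, ...] = CAPTURE_ANGLES_DEG
    shots_per_condition: int = 10
    image_size: int = 512
    expected_total: int | None = None
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    # per-specimen biological variability
    midpoint_jitter_sd_h: float = 1.5
    steepness_jitter_frac: float = 0.15
    endpoint_jitter_frac: float = 0.04
    # per-image assay-replicate noise on stored (pH, TVB-N, TVC)
    capture_noise_sd: tuple[float, float, float] = (0.08, 2.0, 0.25)
    render_noise_sd: float = 0.02
    label_boundaries: tuple[float, float] = DEFAULT_LABEL_BOUNDARIES

    @property
    def total_images(self) -> int:
        return (self.n_specimens * len(self.times) * len(self.lightings)
                * len(self.angles_deg) * self.shots_per_condition)

    def validate(self) -> None:
        if self.expected_total is not None and self.total_images != self.expected_total:
            raise ValueError(
                f"configured factors produce {self.total_images} images, "
                f"but expected_total={self.expected_total}")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_specimens < 1 or self.shots_per_condition < 1:
            raise ValueError("n_specimens and shots_per_condition must be >= 1")


@dataclass(frozen=True)
class FilmImageSample:
    """One rendered film image with its capture metadata and label."""

    image: np.ndarray
    condition: CaptureCondition
    time_h: float
    specimen_id: str
    label: str
    chem_at_capture: tuple[float, float, float]


METADATA_COLUMNS = [
    "image_path", "specimen_id", "time_h", "lighting", "illuminance_lux",
    "angle_deg", "ph", "tvbn_mg_per_100g", "tvc_log_cfu_per_g", "label",
    "split",
]


@dataclass
class MultimodalDataset:
    """Aligned images + chemical metadata + per-specimen trajectories.

    ``images`` is an (N, H, W, 3) float32 array in [0, 1]; ``meta`` carries
    one row per image with the columns of the on-disk CSV; ``trajectories``
    has one row per (specimen, time) with the shared measured chemistry.
    """

    images: np.ndarray
    meta: pd.DataFrame
    trajectories: pd.DataFrame

    def __len__(self) -> int:
        return len(self.meta)

    def class_counts(self) -> dict[str, int]:
        counts = self.meta["label"].value_counts().to_dict()
        return {name: int(counts.get(name, 0)) for name in CLASS_NAMES}

    def trajectory_array(self, specimen_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, 3xT chem array) for one specimen, rows (pH, TVB-N, TVC)."""
        rows = self.trajectories[self.trajectories["specimen_id"] == specimen_id]
        rows = rows.sort_values("time_h")
        if rows.empty:
            raise KeyError(f"unknown specimen {specimen_id!r}")
        chem = rows[["ph", "tvbn_mg_per_100g", "tvc_log_cfu_per_g"]].to_numpy().T
        return rows["time_h"].to_numpy(), chem

    def save(self, out_dir: str | Path) -> None:
        """Write PNG images plus metadata.csv / trajectories.csv."""
        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        for path, img in zip(self.meta["image_path"], self.images):
            arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(out_dir / path)
        self.meta.to_csv(out_dir / "metadata.csv", index=False)
        self.trajectories.to_csv(out_dir / "trajectories.csv", index=False)


def _jittered_params(base: KineticsParams, rng: np.random.Generator,
                     cfg: DatasetConfig) -> KineticsParams:
    j = cfg.endpoint_jitter_frac
    return dataclasses.replace(
        base,
        midpoint_h=base.midpoint_h + rng.normal(0.0, cfg.midpoint_jitter_sd_h),
        steepness=base.steepness * float(
            rng.uniform(1.0 - cfg.steepness_jitter_frac,
                        1.0 + cfg.steepness_jitter_frac)),
        ph_end=base.ph_end * float(rng.uniform(1 - j, 1 + j)),
        tvbn_end=base.tvbn_end * float(rng.uniform(1 - j, 1 + j)),
        tvc_end=base.tvc_end * float(rng.uniform(1 - j, 1 + j)),
    )


def generate_dataset(config: DatasetConfig | None = None, seed: int = 0,
                     out_dir: str | Path | None = None) -> MultimodalDataset:
    """Generate the full multimodal dataset described by ``config``.

    Every image row stores the specimen trajectory's chemical values at the
    capture time plus an independent assay-replicate noise draw; the label is
    derived from those stored values, so labels are always re-derivable from
    the metadata table alone.  If ``out_dir`` is given the dataset is also
    written to disk as PNG images plus CSV tables.
    """
    if config is None:
        config = DatasetConfig()
    config.validate()
    children = np.random.SeedSequence(entropy=seed).spawn(3)
    traj_rng = np.random.default_rng(children[0])
    capture_rng = np.random.default_rng(children[1])
    render_seeds = children[2].generate_state(config.total_images) & 0x7FFFFFFF

    times = np.asarray(config.times, dtype=float)
    trajectories: list[SpoilageTrajectory] = []
    traj_rows = []
    for s in range(config.n_specimens):
        sid = f"specimen_{s:03d}"
        params = _jittered_params(config.kinetics, traj_rng, config)
        traj = simulate_trajectory(params, times, specimen_id=sid, rng=traj_rng)
        trajectories.append(traj)
        for i, t in enumerate(times):
            ph, tvbn, tvc = traj.values_at(i)
            traj_rows.append({"specimen_id": sid, "time_h": t, "ph": ph,
                              "tvbn_mg_per_100g": tvbn,
                              "tvc_log_cfu_per_g": tvc})

    n = config.total_images
    size = config.image_size
    images = np.empty((n, size, size, 3), dtype=np.float32)
    rows = []
    idx = 0
    sd_ph, sd_tvbn, sd_tvc = config.capture_noise_sd
    for traj in trajectories:
        for i, t in enumerate(times):
            ph_true, tvbn_true, tvc_true = traj.values_at(i)
            base_color = ph_to_film_color(ph_true)
            for lighting in config.lightings:
                for angle in config.angles_deg:
                    condition = CaptureCondition(lighting, angle)
                    for _ in range(config.shots_per_condition):
                        ph = ph_true + capture_rng.normal(0.0, sd_ph)
                        tvbn = tvbn_true + capture_rng.normal(0.0, sd_tvbn)
                        tvc = tvc_true + capture_rng.normal(0.0, sd_tvc)
                        label = label_sample((ph, tvbn, tvc),
                                             config.label_boundaries)
                        images[idx] = render_film_image(
                            base_color, condition, size=size,
                            seed=int(render_seeds[idx]),
                            noise_sd=config.render_noise_sd)
                        rows.append({
                            "image_path": f"images/img_{idx:06d}.png",
                            "specimen_id": traj.specimen_id,
                            "time_h": t,
                            "lighting": lighting,
                            "illuminance_lux": condition.illuminance_lux,
                            "angle_deg": angle,
                            "ph": ph,
                            "tvbn_mg_per_100g": tvbn,
                            "tvc_log_cfu_per_g": tvc,
                            "label": label,
                            "split": "",
                        })
                        idx += 1
    meta = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    dataset = MultimodalDataset(images=images, meta=meta,
                                trajectories=pd.DataFrame(traj_rows))
    if out_dir is not None:
        dataset.save(out_dir)
    return dataset


def slim_dataset_config(n_specimens: int = 14, image_size: int = 64,
                        shots_per_condition: int = 1) -> DatasetConfig:
    """Scaled-down study conditions: 14 x 6 x 3 x 5 x 1 = 1260 images at 64 px."""
    return DatasetConfig(n_specimens=n_specimens, image_size=image_size,
                         shots_per_condition=shots_per_condition)
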