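"""Chemical pathway: pseudo-temporal sequence construction, causal dilated
temporal convolutions, 1-D multi-scale attention, and projection to the 256-d
chemical embedding F_chem.

The three spoilage indicators (pH, TVB-N, TVC) are measured at a handful of
discrete time points; piecewise-linear interpolation resamples them onto a
length-T grid ("pseudo-temporal sequence").  A linear per-timestep expansion
(3 -> 64 channels) feeds three causal dilated conv layers (kernel 3,
dilations 2, 4, 8; left zero-padding preserves length), giving a temporal
receptive field of 1 + 2*(2+4+8) = 29 steps.  A 1-D variant of the MDFA
block (branch dilations 3 and 6 plus a global-average branch) re-weights the
hidden sequence before temporal mean-pooling and a fully connected 64 -> 256
projection.

Indicators are z-scored per indicator with training-set statistics before
entering the branch; the statistics are persisted with the model so
inference normalises identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Module, Tensor

__all__ = [
    "ChemSequence", "TcnConfig", "build_pseudo_sequence", "dilated_conv1d",
    "ChemNormalizer", "Tcn", "MDFA1D", "ChemBranch",
]

INDICATOR_NAMES = ("ph", "tvbn", "tvc")


@dataclass
class ChemSequence:
    """A 3xT chemical sequence (rows: pH, TVB-N, TVC) on a uniform time grid."""

    values: np.ndarray
    times: np.ndarray
    normalization: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 3:
            raise ValueError("values must be a 3xT array (pH, TVB-N, TVC rows)")
        if self.values.shape[1] != self.times.size:
            raise ValueError("times length must match the number of columns")
        if self.values.shape[1] < 2:
            raise ValueError("sequences need at least T=2 steps")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("chemical values must be finite")


@dataclass(frozen=True)
class TcnConfig:
    hidden: int = 64
    kernel: int = 3
    dilations: tuple[int, ...] = (2, 4, 8)
    mdfa1d_dilations: tuple[int, int] = (3, 6)
    out_dim: int = 256

    def __post_init__(self):
        if any(d <= 0 for d in self.dilations) or list(self.dilations) != sorted(
                self.dilations):
            raise ValueError("dilations must be positive ascending")
        if self.out_dim != 256:
            raise ValueError("the chemical embedding dimension is fixed at 256")


def build_pseudo_sequence(measurements: np.ndarray, times: np.ndarray,
                          target_t: int) -> ChemSequence:
    """Resample 3 indicators at N time points onto ``target_t`` uniform steps.

    Piecewise-linear interpolation spans [t_first, t_last]; endpoints are
    preserved exactly, and when the original grid is already uniform with
    ``target_t == N`` the output equals the input.
    """
    measurements = np.asarray(measurements, dtype=float)
    times = np.asarray(times, dtype=float)
    if measurements.ndim != 2 or measurements.shape[0] != 3:
        raise ValueError("measurements must be 3xN")
    n = measurements.shape[1]
    if n < 2:
        raise ValueError("need at least 2 measurements to interpolate")
    if times.size != n or np.any(np.diff(times) <= 0):
        raise ValueError("times must be ascending and match measurements")
    if target_t < n:
        raise ValueError("target_t must be >= the number of measurements")
    grid = np.linspace(times[0], times[-1], target_t)
    values = np.stack([np.interp(grid, times, row) for row in measurements])
    return ChemSequence(values, grid)


def dilated_conv1d(x: np.ndarray, w: np.ndarray, d: int) -> np.ndarray:
    """Causal dilated convolution of a 1-D sequence.

    ``y[t] = sum_k w[k] * x[t - d*k]`` with zeros for indices before the
    sequence start, so the output has the input's length.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size == 0:
        raise ValueError("input sequence must be non-empty")
    if w.ndim != 1 or w.size < 1 or d < 1:
        raise ValueError("w must be a 1-D kernel and d >= 1")
    y = np.zeros_like(x)
    for k, wk in enumerate(w):
        shift = d * k
        if shift == 0:
            y += wk * x
        elif shift < x.size:
            y[shift:] += wk * x[:-shift]
    return y


class ChemNormalizer:
    """Per-indicator z-scoring with persisted training statistics."""

    def __init__(self, mean: np.ndarray | None = None,
                 std: np.ndarray | None = None):
        self.mean = None if mean is None else np.asarray(mean, dtype=float)
        self.std = None if std is None else np.asarray(std, dtype=float)

    def fit(self, sequences: np.ndarray) -> "ChemNormalizer":
        """``sequences`` is (N, 3, T); statistics pool over samples and time."""
        seqs = np.asarray(sequences, dtype=float)
        self.mean = seqs.mean(axis=(0, 2))
        self.std = np.maximum(seqs.std(axis=(0, 2)), 1e-8)
        return self

    def transform(self, sequences: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("normalizer has not been fitted")
        return ((np.asarray(sequences, dtype=float)
                 - self.mean[None, :, None]) / self.std[None, :, None])

    def state(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_state(cls, state: dict) -> "ChemNormalizer":
        return cls(np.asarray(state["mean"]), np.asarray(state["std"]))


class Tcn(Module):
    """Per-timestep 3->hidden expansion followed by the dilated conv stack."""

    def __init__(self, cfg: TcnConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.expand = nn.Conv1dCausal(3, cfg.hidden, 1, rng)
        layers, bns = [], []
        for d in cfg.dilations:
            layers.append(nn.Conv1dCausal(cfg.hidden, cfg.hidden, cfg.kernel,
                                          rng, dilation=d, bias=False))
            bns.append(nn.BatchNorm1d(cfg.hidden))
        self.convs = nn.ModuleList(layers)
        self.bns = nn.ModuleList(bns)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[1] != 3:
            raise ValueError("TCN expects an (N, 3, T) batch")
        if x.shape[2] < 1:
            raise ValueError("sequence length must be >= 1")
        h = nn.relu(self.expand(x))
        for conv, bn in zip(self.convs, self.bns):
            h = nn.relu(bn(conv(h)))
        return h


class MDFA1D(Module):
    """1-D multi-scale attention: dilated branches + global pooling branch,
    fused by a 1x1 conv and modulated by sigmoid attention."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 dilations: tuple[int, int] = (3, 6)):
        super().__init__()
        self.channels = channels
        d1, d2 = dilations
        self.branch1 = nn.Conv1dCausal(channels, channels, 3, rng, dilation=d1,
                                       bias=False)
        self.bn1 = nn.BatchNorm1d(channels)
        self.branch2 = nn.Conv1dCausal(channels, channels, 3, rng, dilation=d2,
                                       bias=False)
        self.bn2 = nn.BatchNorm1d(channels)
        self.fuse = nn.Conv1dCausal(3 * channels, channels, 1, rng)
        self.attn = nn.Conv1dCausal(channels, channels, 1, rng)

    def forward(self, h: Tensor) -> Tensor:
        if h.ndim != 3 or h.shape[1] != self.channels:
            raise ValueError(
                f"MDFA1D expects (N, {self.channels}, T), got {h.shape}")
        t = h.shape[2]
        b1 = nn.relu(self.bn1(self.branch1(h)))
        b2 = nn.relu(self.bn2(self.branch2(h)))
        pooled = nn.tensor_mean(h, axis=2, keepdims=True)  # (N, C, 1)
        # broadcast the sequence-level statistics across all T steps
        zeros = nn.Tensor(np.zeros(h.shape, dtype=h.data.dtype))
        global_branch = nn.add(zeros, pooled)
        fused = nn.relu(self.fuse(nn.concat([b1, b2, global_branch], axis=1)))
        attention = nn.sigmoid(self.attn(fused))
        return nn.mul(fused, attention)


class ChemBranch(Module):
    """Full chemical encoder: TCN -> MDFA_1D -> mean pool -> FC to 256."""

    def __init__(self, cfg: TcnConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.tcn = Tcn(cfg, rng)
        self.mdfa1d = MDFA1D(cfg.hidden, rng, cfg.mdfa1d_dilations)
        self.fc = nn.Linear(cfg.hidden, cfg.out_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        hidden = self.tcn(x)
        attended = self.mdfa1d(hidden)
        pooled = nn.tensor_mean(attended, axis=2)
        return self.fc(pooled)


def chem_feature_vector(branch: ChemBranch, attended: Tensor) -> Tensor:
    """Temporal mean pool + fully connected projection to 256."""
    return branch.fc(nn.tensor_mean(attended, axis=2))
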