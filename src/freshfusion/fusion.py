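"""Context-aware gated fusion of the image and chemical embeddings.

The two 256-d embeddings are compared by cosine similarity s; an MLP over
``[s; F_img; F_chem]`` (513 -> 64 -> 1, sigmoid) produces the gate g, and
the fused representation is the convex combination ``g * F_img + (1 - g) *
F_chem`` -- g is the *image* weight.

An interpretability hinge penalty ties the gate to the spoilage stage: early
(pH < 6.8) the gate should favour the image modality (g > 0.7), late
(pH > 7.2) the chemical modality (g < 0.3).  The penalty is differentiable
and added to the classification loss with weight lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Module, Tensor

__all__ = [
    "cosine_similarity", "GateMLP", "fuse", "GateConstraintConfig",
    "gate_constraint_penalty", "CAGFusion", "GateRecord",
]


@dataclass(frozen=True)
class GateConstraintConfig:
    """Thresholds of the gate-pH interpretability constraint."""

    ph_low: float = 6.8
    g_high: float = 0.7
    ph_high: float = 7.2
    g_low: float = 0.3
    weight: float = 0.1

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("penalty weight must be non-negative")


@dataclass
class GateRecord:
    """Per-sample fusion diagnostics used by the gate-analysis report."""

    sample_id: str
    s: float
    g: float
    ph: float
    stage: str
    predicted: str | None = None
    true: str | None = None


def cosine_similarity(f_img: np.ndarray, f_chem: np.ndarray) -> float:
    """Cosine similarity of two embeddings, with s = 0 for zero-norm inputs."""
    a = np.asarray(f_img, dtype=float)
    b = np.asarray(f_chem, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        warnings.warn("zero-norm embedding in cosine similarity; returning 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


class GateMLP(Module):
    """513 -> 64 -> 1 gating network with sigmoid output."""

    def __init__(self, rng: np.random.Generator, embed_dim: int = 256,
                 hidden: int = 64):
        super().__init__()
        self.in_width = 1 + 2 * embed_dim
        self.fc1 = nn.Linear(self.in_width, hidden, rng)
        self.fc2 = nn.Linear(hidden, 1, rng)

    def forward(self, context: Tensor) -> Tensor:
        if context.shape[1] != self.in_width:
            raise ValueError(
                f"gate input width must be {self.in_width}, got {context.shape[1]}")
        return nn.sigmoid(self.fc2(nn.relu(self.fc1(context))))


def fuse(f_img: np.ndarray, f_chem: np.ndarray, g: float) -> np.ndarray:
    """Convex combination ``g * F_img + (1 - g) * F_chem``."""
    if not 0.0 <= g <= 1.0:
        raise ValueError("gate value must lie in [0, 1]")
    a = np.asarray(f_img, dtype=float)
    b = np.asarray(f_chem, dtype=float)
    if a.shape != b.shape:
        raise ValueError("embeddings must have equal shape")
    return g * a + (1.0 - g) * b


def gate_constraint_penalty(g: np.ndarray, ph: np.ndarray,
                            cfg: GateConstraintConfig | None = None) -> float:
    """Hinge penalty enforcing the gate-pH correlation, averaged over a batch.

    ``weight * mean[ max(0, g_high - g) * 1(ph < ph_low)
                   + max(0, g - g_low) * 1(ph > ph_high) ]``;
    zero whenever both constraints are satisfied.
    """
    if cfg is None:
        cfg = GateConstraintConfig()
    g = np.atleast_1d(np.asarray(g, dtype=float))
    ph = np.atleast_1d(np.asarray(ph, dtype=float))
    low = (ph < cfg.ph_low) * np.maximum(0.0, cfg.g_high - g)
    high = (ph > cfg.ph_high) * np.maximum(0.0, g - cfg.g_low)
    return float(cfg.weight * np.mean(low + high))


def gate_penalty_tensor(g: Tensor, ph: np.ndarray,
                        cfg: GateConstraintConfig) -> Tensor:
    """Differentiable version of the hinge penalty for training.

    ``g`` is an (N, 1) gate tensor; ``ph`` is the per-sample pH array.
    """
    ph = np.asarray(ph, dtype=float).reshape(-1, 1)
    low_mask = (ph < cfg.ph_low).astype(g.data.dtype)
    high_mask = (ph > cfg.ph_high).astype(g.data.dtype)
    low = nn.mul(nn.relu(nn.sub(nn.Tensor(np.full_like(ph, cfg.g_high,
                                                       dtype=g.data.dtype)), g)),
                 nn.Tensor(low_mask))
    high = nn.mul(nn.relu(nn.sub(g, nn.Tensor(np.full_like(ph, cfg.g_low,
                                                           dtype=g.data.dtype)))),
                  nn.Tensor(high_mask))
    return nn.mul(nn.tensor_mean(nn.add(low, high)),
                  nn.Tensor(np.asarray(cfg.weight, dtype=g.data.dtype)))


class CAGFusion(Module):
    """Cosine-context gating and convex fusion of the two modality embeddings."""

    def __init__(self, rng: np.random.Generator, embed_dim: int = 256,
                 eps: float = 1e-8):
        super().__init__()
        self.embed_dim = embed_dim
        self.eps = eps
        self.gate_mlp = GateMLP(rng, embed_dim)
        self._last_gate: np.ndarray | None = None
        self._last_similarity: np.ndarray | None = None

    def similarity(self, f_img: Tensor, f_chem: Tensor) -> Tensor:
        """Batched cosine similarity as an (N, 1) tensor (eps-guarded)."""
        dot = nn.tensor_sum(nn.mul(f_img, f_chem), axis=1, keepdims=True)
        na = nn.sqrt(nn.tensor_sum(nn.mul(f_img, f_img), axis=1, keepdims=True)
                     + nn.Tensor(np.asarray(self.eps)))
        nb = nn.sqrt(nn.tensor_sum(nn.mul(f_chem, f_chem), axis=1, keepdims=True)
                     + nn.Tensor(np.asarray(self.eps)))
        return nn.div(dot, nn.mul(na, nb))

    def forward(self, f_img: Tensor, f_chem: Tensor) -> Tensor:
        if f_img.shape != f_chem.shape or f_img.shape[1] != self.embed_dim:
            raise ValueError("embeddings must both be (N, embed_dim)")
        s = self.similarity(f_img, f_chem)
        context = nn.concat([s, f_img, f_chem], axis=1)
        g = self.gate_mlp(context)
        self._last_gate = g.data.copy()
        self._last_similarity = s.data.copy()
        one = nn.Tensor(np.ones_like(g.data))
        fused = nn.add(nn.mul(g, f_img), nn.mul(nn.sub(one, g), f_chem))
        self._last_gate_tensor = g
        return fused
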