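"""Residual multimodal fusion and the match classifier.

The molecule embedding ``f_final`` (128-d) and spectral embedding
``f_spec`` (32-d) are concatenated into the joint representation ``u``.
Fusion is residual: a two-layer nonlinear main branch
``FC2(BN(ReLU(FC1(u))))`` summed with a linear skip projection
``FC_skip(u)`` in the same output space.  The classifier is a small MLP
``sigmoid(FC_out(BN(ReLU(FC_pred(F_fused)))))`` producing a match
probability in (0,1); the binary decision thresholds at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .nn import BatchNorm1d, Linear, Module


@dataclass
class FusionHeadConfig:
    mol_dim: int = 128
    spec_dim: int = 32
    fusion_width: int = 128
    head_hidden: int = 64
    threshold: float = 0.5


class ResidualFusion(Module):
    def __init__(self, cfg: FusionHeadConfig, rng: np.random.Generator):
        super().__init__()
        in_dim = cfg.mol_dim + cfg.spec_dim
        self.fc1 = Linear(in_dim, cfg.fusion_width, rng)
        self.bn = BatchNorm1d(cfg.fusion_width)
        self.fc2 = Linear(cfg.fusion_width, cfg.fusion_width, rng)
        self.fc_skip = Linear(in_dim, cfg.fusion_width, rng)

    def forward(self, u: Tensor) -> Tensor:
        main = self.fc2(self.bn(self.fc1(u).relu()))
        return main + self.fc_skip(u)


class MatchClassifier(Module):
    def __init__(self, cfg: FusionHeadConfig, rng: np.random.Generator):
        super().__init__()
        self.fc_pred = Linear(cfg.fusion_width, cfg.head_hidden, rng)
        self.bn = BatchNorm1d(cfg.head_hidden)
        self.fc_out = Linear(cfg.head_hidden, 1, rng)

    def forward(self, fused: Tensor) -> Tensor:
        return self.fc_out(self.bn(self.fc_pred(fused).relu())).sigmoid()


class FusionHead(Module):
    """[f_final ; f_spec] -> match probability."""

    def __init__(self, cfg: FusionHeadConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.fusion = ResidualFusion(cfg, rng)
        self.classifier = MatchClassifier(cfg, rng)

    def forward(self, f_final: Tensor, f_spec: Tensor) -> Tensor:
        u = concat([f_final, f_spec], axis=1)
        return self.classifier(self.fusion(u))

    def predict_label(self, prob: np.ndarray) -> np.ndarray:
        return (np.asarray(prob) >= self.cfg.threshold).astype(np.int64)
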