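"""Shared 3D VGG-style convolutional encoder.

Each stage applies [conv 3x3x3 -> batch norm -> ReLU] x blocks followed by
dropout; stride-2 max pooling sits between stages. A terminal
global max+average pooling collapses the final feature maps into one
``feature_dim``-dimensional vector per input, independent of the input's
spatial size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from bpfuse.nn import Conv3d, BatchNorm3d, Dropout, Module, ReLU, Sequential, Tensor
from bpfuse.nn.layers import GlobalMaxAvgPool
from bpfuse.nn.tensor import maxpool3d

__all__ = ["EncoderSpec", "Encoder"]


@dataclass
class EncoderSpec:
    """Architecture of one encoder branch.

    Defaults follow the full-scale configuration (stage widths
    [64, 128, 256, 512], blocks per stage [1, 2, 3, 4], dropout 0.5); tests
    and desk profiles shrink these.
    """

    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, ...] = (1, 2, 3, 4)
    dropout: float = 0.5
    in_channels: int = 1

    def __post_init__(self) -> None:
        self.stage_widths = tuple(self.stage_widths)
        self.blocks_per_stage = tuple(self.blocks_per_stage)
        if len(self.stage_widths) != len(self.blocks_per_stage):
            raise ValueError(
                f"stage_widths {self.stage_widths} and blocks_per_stage "
                f"{self.blocks_per_stage} must have equal length"
            )
        if any(w <= 0 for w in self.stage_widths) or any(b <= 0 for b in self.blocks_per_stage):
            raise ValueError("stage widths and block counts must be positive")

    @property
    def feature_dim(self) -> int:
        """Output dimensionality; equals the last stage width."""
        return self.stage_widths[-1]

    @property
    def min_spatial(self) -> int:
        """Smallest input extent that survives the inter-stage pooling ladder."""
        return 2 ** (len(self.stage_widths) - 1)

    def to_dict(self) -> dict:
        return {
            "stage_widths": list(self.stage_widths),
            "blocks_per_stage": list(self.blocks_per_stage),
            "dropout": self.dropout,
            "in_channels": self.in_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderSpec":
        return cls(**d)


class Encoder(Module):
    """Map a batch of (in_channels, D, H, W) volumes to feature vectors."""

    def __init__(self, spec: EncoderSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        self.stages: list[Sequential] = []
        in_ch = spec.in_channels
        for width, blocks in zip(spec.stage_widths, spec.blocks_per_stage):
            layers: list[Module] = []
            for _ in range(blocks):
                layers += [Conv3d(in_ch, width, rng=rng), BatchNorm3d(width), ReLU()]
                in_ch = width
            layers.append(Dropout(spec.dropout))
            self.stages.append(Sequential(*layers))
        self.pool = GlobalMaxAvgPool()

    def forward(self, x: Tensor) -> Tensor:
        spatial = x.shape[2:]
        m = self.spec.min_spatial
        if min(spatial) < m:
            raise ValueError(
                f"input spatial shape {tuple(spatial)} too small for the "
                f"downsampling ladder; every axis must be >= {m}"
            )
        for i, stage in enumerate(self.stages):
            x = stage(x)
            if i < len(self.stages) - 1:
                x = maxpool3d(x, 2)
        return self.pool(x)
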