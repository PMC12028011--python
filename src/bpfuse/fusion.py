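"""The three patient-level classification architectures.

* 3-Channel: one encoder over the channel-stacked sequences.
* Multi-encoder fusion: one encoder per sequence, features concatenated.
* Cross-attention fusion: per-sequence encoders whose feature vectors are
  mixed by a multi-head cross-sequence attention module before fusion.

All models end in a single linear layer mapping the fused vector (plus the
normalized clinical scalars when enabled) to one logit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from bpfuse.encoder import Encoder, EncoderSpec
from bpfuse.nn import Linear, Module, Parameter, Tensor, concat

__all__ = [
    "AttentionSpec",
    "FusionModelSpec",
    "CrossSequenceAttention",
    "ThreeChannelModel",
    "MultiEncoderModel",
    "CrossAttentionModel",
    "build_model",
    "SEQUENCE_ORDER",
]

# canonical channel order everywhere: (T2W, DWI high-b, ADC)
SEQUENCE_ORDER = ("T2W", "DWI_HIGH_B", "ADC")
N_SEQUENCES = 3


@dataclass
class AttentionSpec:
    """Configuration of the cross-sequence attention module.

    ``d`` must be divisible by the head count ``H``; each head operates on a
    ``d_h = d // H`` slice of the projected queries/keys/values. With
    ``cascade`` on, heads run sequentially and each head's output is added
    back into its slice of the running feature before the next head's
    projections are read.
    """

    d: int = 512
    H: int = 2
    residual_policy: Literal["ADD", "REPLACE"] = "ADD"
    cascade: bool = True
    share_projections: bool = False
    init_scale: float = 0.02

    def __post_init__(self) -> None:
        if self.d % self.H != 0:
            raise ValueError(f"feature dim d={self.d} not divisible by H={self.H}")

    @property
    def d_h(self) -> int:
        return self.d // self.H


class CrossSequenceAttention(Module):
    """Multi-head attention across the three sequence feature vectors.

    Input: three (B, d) feature tensors. Each slot i carries its own query
    projection; keys and values are projected from all three slots. Scores
    are scaled dot products over the per-head slices, normalized by softmax
    over the three key slots. Head outputs are concatenated back to d
    dimensions; the residual policy decides whether the input is added.
    """

    def __init__(self, spec: AttentionSpec, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        d = spec.d

        def make():
            return Parameter(rng.normal(0.0, spec.init_scale / np.sqrt(d), size=(d, d)))

        n_slots = 1 if spec.share_projections else N_SEQUENCES
        self.w_q = [make() for _ in range(n_slots)]
        self.w_k = [make() for _ in range(n_slots)]
        self.w_v = [make() for _ in range(n_slots)]
        # populated on every forward: (H, B, 3, 3) softmax probabilities
        self.last_attn_probs: Optional[np.ndarray] = None

    def _proj(self, ws: list[Parameter], slot: int) -> Parameter:
        return ws[0] if self.spec.share_projections else ws[slot]

    def forward(self, hs: Sequence[Tensor]) -> list[Tensor]:
        if len(hs) != N_SEQUENCES:
            raise ValueError(f"expected {N_SEQUENCES} feature vectors, got {len(hs)}")
        for h in hs:
            if not np.all(np.isfinite(h.data)):
                raise ValueError("non-finite attention inputs")
        spec = self.spec
        d, H, dh = spec.d, spec.H, spec.d_h
        if hs[0].shape[-1] != d:
            raise ValueError(f"feature dim {hs[0].shape[-1]} does not match spec d={d}")
        B = hs[0].shape[0]

        running = list(hs)
        head_outputs: list[list[Tensor]] = [[] for _ in range(N_SEQUENCES)]
        probs_log = np.zeros((H, B, N_SEQUENCES, N_SEQUENCES))

        for head in range(H):
            lo, hi = head * dh, (head + 1) * dh
            source = running if spec.cascade else list(hs)
            q = [source[i] @ self._proj(self.w_q, i)[:, lo:hi] for i in range(N_SEQUENCES)]
            k = [source[j] @ self._proj(self.w_k, j)[:, lo:hi] for j in range(N_SEQUENCES)]
            v = [source[j] @ self._proj(self.w_v, j)[:, lo:hi] for j in range(N_SEQUENCES)]

            outs = []
            for i in range(N_SEQUENCES):
                scores = [(q[i] * k[j]).sum(axis=1) * (dh**-0.5) for j in range(N_SEQUENCES)]
                smax = np.max([s.data for s in scores], axis=0)  # detached shift
                exps = [(s - Tensor(smax)).exp() for s in scores]
                denom = exps[0] + exps[1] + exps[2]
                probs = [e / denom for e in exps]
                for j in range(N_SEQUENCES):
                    probs_log[head, :, i, j] = probs[j].data
                out_i = sum(
                    (probs[j].reshape(B, 1) * v[j] for j in range(N_SEQUENCES)),
                    start=Tensor(np.zeros((B, dh))),
                )
                outs.append(out_i)
                head_outputs[i].append(out_i)

            if spec.cascade:
                new_running = []
                for i in range(N_SEQUENCES):
                    r = running[i]
                    updated = concat([r[:, :lo], r[:, lo:hi] + outs[i], r[:, hi:]], axis=1)
                    new_running.append(updated)
                running = new_running

        self.last_attn_probs = probs_log
        attended = []
        for i in range(N_SEQUENCES):
            concat_out = concat(head_outputs[i], axis=1)
            if spec.residual_policy == "ADD":
                attended.append(hs[i] + concat_out)
            else:
                attended.append(concat_out)
        return attended


@dataclass
class FusionModelSpec:
    """Which architecture to build, and how."""

    family: Literal["3ch", "me", "meca"] = "meca"
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    use_clinical: bool = True
    n_clinical: int = 3
    attention: Optional[AttentionSpec] = None
    # restrict the 3-Channel model to a subset of sequences (single-modality
    # ablations); indices into SEQUENCE_ORDER
    sequence_subset: Optional[tuple[int, ...]] = None
    share_encoders: bool = False

    def __post_init__(self) -> None:
        if self.family == "meca" and self.attention is None:
            self.attention = AttentionSpec(d=self.encoder.feature_dim)
        if self.attention is not None and self.attention.d != self.encoder.feature_dim:
            raise ValueError(
                f"attention d={self.attention.d} must equal encoder feature dim "
                f"{self.encoder.feature_dim}"
            )
        if self.sequence_subset is not None and self.family != "3ch":
            raise ValueError("sequence_subset only applies to the 3ch family")

    @property
    def fused_dim(self) -> int:
        d = self.encoder.feature_dim
        base = d if self.family == "3ch" else N_SEQUENCES * d
        return base + (self.n_clinical if self.use_clinical else 0)


class _FusionBase(Module):
    """Shared classifier head + probability helpers."""

    def __init__(self, spec: FusionModelSpec, rng: np.random.Generator):
        super().__init__()
        self.model_spec = spec
        self.classifier = Linear(spec.fused_dim, 1, rng=rng)
        self.last_fused_dim: Optional[int] = None

    def _classify(self, fused: Tensor, clinical: Optional[np.ndarray]) -> Tensor:
        if self.model_spec.use_clinical:
            if clinical is None:
                raise ValueError("model expects clinical variables but none were given")
            clinical = np.asarray(clinical, dtype=np.float64)
            if clinical.shape != (fused.shape[0], self.model_spec.n_clinical):
                raise ValueError(
                    f"clinical array shape {clinical.shape} != "
                    f"{(fused.shape[0], self.model_spec.n_clinical)}"
                )
            fused = concat([fused, Tensor(clinical)], axis=1)
        self.last_fused_dim = fused.shape[-1]
        return self.classifier(fused).reshape(fused.shape[0])

    @staticmethod
    def _volumes_tensor(volumes: np.ndarray | Tensor) -> Tensor:
        x = volumes if isinstance(volumes, Tensor) else Tensor(np.asarray(volumes))
        if x.ndim != 5 or x.shape[1] != N_SEQUENCES:
            raise ValueError(
                f"expected volumes of shape (B, {N_SEQUENCES}, D, H, W), got {x.shape}"
            )
        return x

    def predict_proba(self, volumes, clinical=None) -> np.ndarray:
        """Per-case probability of cancer presence, in (0, 1)."""
        logits = self.forward(volumes, clinical)
        return 1.0 / (1.0 + np.exp(-np.clip(logits.data, -60, 60)))


class ThreeChannelModel(_FusionBase):
    """Sequences stacked into the input channels of a single encoder."""

    def __init__(self, spec: FusionModelSpec, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        subset = spec.sequence_subset or tuple(range(N_SEQUENCES))
        enc_spec = EncoderSpec(
            stage_widths=spec.encoder.stage_widths,
            blocks_per_stage=spec.encoder.blocks_per_stage,
            dropout=spec.encoder.dropout,
            in_channels=len(subset),
        )
        super().__init__(spec, rng)
        self.subset = subset
        self.encoder = Encoder(enc_spec, rng=rng)

    def forward(self, volumes, clinical=None) -> Tensor:
        x = self._volumes_tensor(volumes)
        x = x[:, list(self.subset)]
        feat = self.encoder(x)
        return self._classify(feat, clinical)


class _MultiEncoderBase(_FusionBase):
    def __init__(self, spec: FusionModelSpec, rng: np.random.Generator):
        super().__init__(spec, rng)
        if spec.encoder.in_channels != 1:
            raise ValueError("multi-encoder families require in_channels=1 encoders")
        if spec.share_encoders:
            shared = Encoder(spec.encoder, rng=rng)
            self.encoders = [shared, shared, shared]
        else:
            self.encoders = [Encoder(spec.encoder, rng=rng) for _ in range(N_SEQUENCES)]

    def _encode_each(self, volumes) -> list[Tensor]:
        x = self._volumes_tensor(volumes)
        return [
            self.encoders[i](x[:, i].reshape(x.shape[0], 1, *x.shape[2:]))
            for i in range(N_SEQUENCES)
        ]


class MultiEncoderModel(_MultiEncoderBase):
    """Per-sequence encoders with feature-level concatenation."""

    def __init__(self, spec: FusionModelSpec, rng: Optional[np.random.Generator] = None):
        super().__init__(spec, rng or np.random.default_rng(0))

    def forward(self, volumes, clinical=None) -> Tensor:
        feats = self._encode_each(volumes)
        return self._classify(concat(feats, axis=1), clinical)


class CrossAttentionModel(_MultiEncoderBase):
    """Per-sequence encoders, cross-sequence attention, then fusion."""

    def __init__(self, spec: FusionModelSpec, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        super().__init__(spec, rng)
        assert spec.attention is not None
        self.attention = CrossSequenceAttention(spec.attention, rng=rng)

    def forward(self, volumes, clinical=None) -> Tensor:
        feats = self._encode_each(volumes)
        attended = self.attention(feats)
        return self._classify(concat(attended, axis=1), clinical)


_FAMILIES = {
    "3ch": ThreeChannelModel,
    "me": MultiEncoderModel,
    "meca": CrossAttentionModel,
}


def build_model(spec: FusionModelSpec, seed: int = 0) -> _FusionBase:
    """Instantiate a model family with seeded weight initialization."""
    rng = np.random.default_rng(seed)
    try:
        cls = _FAMILIES[spec.family]
    except KeyError:
        raise ValueError(f"unknown model family {spec.family!r}") from None
    model = cls(spec, rng=rng)
    model.set_rng(np.random.default_rng(seed + 1))
    return model
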