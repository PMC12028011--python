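"""End-to-end optimization loop: augmentation, regularized BCE, and
validation-AUC model selection.

Reported test metrics always come from the retained best-validation
checkpoint, never the last epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from bpfuse.data_model import BpMriCase, SequenceKind
from bpfuse.evaluation import auc
from bpfuse.fusion import SEQUENCE_ORDER, _FusionBase
from bpfuse.nn import Adam, Tensor, apply_weight_penalties, bce_with_logits, weight_penalty_value

__all__ = ["TrainConfig", "TrainResult", "cases_to_arrays", "augment", "train"]


@dataclass
class TrainConfig:
    lr: float = 3e-5
    l1_weight: float = 3e-5
    l2_weight: float = 3e-5
    epochs: int = 20
    batch_size: int = 8
    flip_axes: tuple[int, ...] = (2,)  # left-right (col) axis of (slice,row,col)
    rotation_degrees: float = 10.0  # in-plane, +/- range; 0 disables
    augment: bool = True
    selection_metric: Literal["VAL_AUC", "VAL_LOSS"] = "VAL_AUC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr < 0 or self.l1_weight < 0 or self.l2_weight < 0:
            raise ValueError("lr and regularization weights must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainResult:
    model: _FusionBase
    history: pd.DataFrame
    best_epoch: int
    best_metric: float
    best_state: dict


def cases_to_arrays(cases: Sequence[BpMriCase]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack preprocessed cases into (volumes, clinical, labels) arrays.

    Volumes: (N, 3, D, H, W) float32 in the canonical sequence order;
    clinical: (N, 3) normalized scalars; labels: (N,) int.
    """
    vols, clin, labels = [], [], []
    for c in cases:
        vols.append(
            np.stack([c.volumes[SequenceKind(k)].voxels for k in SEQUENCE_ORDER]).astype(
                np.float32
            )
        )
        clin.append(c.clinical.normalized_vector())
        labels.append(c.label)
    return np.stack(vols), np.stack(clin), np.asarray(labels, dtype=int)


def augment(
    volumes: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random flip + in-plane rotation, identical across a case's sequences.

    ``volumes`` is (N, 3, D, H, W); axes in ``config.flip_axes`` index the
    spatial (D, H, W) triple as 0/1/2.
    """
    out = volumes.copy()
    for n in range(out.shape[0]):
        for ax in config.flip_axes:
            if rng.random() < 0.5:
                out[n] = np.flip(out[n], axis=1 + ax)
        if config.rotation_degrees > 0:
            angle = float(rng.uniform(-config.rotation_degrees, config.rotation_degrees))
            if abs(angle) > 1e-6:
                # same in-plane rotation for all three sequences of the case
                out[n] = ndimage.rotate(
                    out[n], angle, axes=(2, 3), reshape=False, order=1, mode="nearest"
                )
    return out


def _score_batched(model: _FusionBase, vols, clin, batch_size: int) -> np.ndarray:
    probs = []
    for a in range(0, len(vols), batch_size):
        b = a + batch_size
        probs.append(model.predict_proba(vols[a:b], clin[a:b] if clin is not None else None))
    return np.concatenate(probs)


def train(
    model: _FusionBase,
    train_cases: Sequence[BpMriCase],
    val_cases: Sequence[BpMriCase],
    config: TrainConfig,
) -> TrainResult:
    """Optimize ``model`` with Adam on regularized BCE.

    Per epoch: one augmented pass over the shuffled training cohort, then a
    validation scoring; the checkpoint with the best selection metric is
    retained and restored into the model before returning.
    """
    train_ids = {c.case_id for c in train_cases}
    if train_ids & {c.case_id for c in val_cases}:
        raise ValueError("train and validation cohorts overlap")
    tv, tc, ty = cases_to_arrays(train_cases)
    vv, vc, vy = cases_to_arrays(val_cases)
    if vy.min() == vy.max():
        raise ValueError("validation cohort has a single class; AUC is undefined")

    use_clin = model.model_spec.use_clinical
    rng = np.random.default_rng(config.seed)
    model.set_rng(np.random.default_rng(config.seed + 1))
    opt = Adam(model.parameters(), lr=config.lr)

    rows = []
    best_metric = -np.inf
    best_epoch = -1
    best_state: dict = model.state_dict()
    n = len(ty)
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for a in range(0, n, config.batch_size):
            idx = order[a : a + config.batch_size]
            xb = tv[idx]
            if config.augment:
                xb = augment(xb, config, rng)
            logits = model.forward(xb, tc[idx] if use_clin else None)
            loss = bce_with_logits(logits, ty[idx])
            model.zero_grad()
            loss.backward()
            apply_weight_penalties(model, config.l1_weight, config.l2_weight)
            opt.step()
            epoch_losses.append(
                float(loss.data)
                + weight_penalty_value(model, config.l1_weight, config.l2_weight)
            )

        model.eval()
        val_probs = _score_batched(model, vv, vc if use_clin else None, config.batch_size)
        val_auc = auc(val_probs, vy)
        eps = 1e-12
        val_loss = float(
            -np.mean(vy * np.log(val_probs + eps) + (1 - vy) * np.log(1 - val_probs + eps))
        )
        metric = val_auc if config.selection_metric == "VAL_AUC" else -val_loss
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_auc": val_auc,
                "val_loss": val_loss,
            }
        )
        if metric > best_metric:
            best_metric = metric
            best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    model.eval()
    history = pd.DataFrame(rows)
    return TrainResult(
        model=model,
        history=history,
        best_epoch=best_epoch,
        best_metric=float(best_metric if config.selection_metric == "VAL_AUC" else -best_metric),
        best_state=best_state,
    )
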