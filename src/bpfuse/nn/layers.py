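"""Neural-network modules built on the Tensor autograd engine."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from bpfuse.nn.tensor import Tensor, batchnorm_train, conv3d, max_reduce, maxpool3d

__all__ = [
    "Parameter",
    "Module",
    "Conv3d",
    "BatchNorm3d",
    "Linear",
    "Dropout",
    "ReLU",
    "MaxPool3d",
    "GlobalMaxAvgPool",
    "Sequential",
]


class Parameter(Tensor):
    """A trainable tensor. ``is_weight`` marks parameters subject to L1/L2
    penalties (convolution/linear weights, not biases or BN affines)."""

    __slots__ = ("is_weight",)

    def __init__(self, data, is_weight: bool = True, name: str = "",
                 dtype=np.float32):
        super().__init__(np.asarray(data, dtype=dtype), requires_grad=True, name=name)
        self.is_weight = is_weight


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self) -> None:
        self.training = True
        self.rng: np.random.Generator = np.random.default_rng(0)

    # -- traversal --------------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{k}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{k}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{prefix}{k}.{i}", item

    def parameters(self) -> list[Parameter]:
        # dedupe by identity: shared submodules must not yield duplicates
        seen: set[int] = set()
        out = []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    # -- modes / rng ------------------------------------------------------
    def train(self) -> "Module":
        self.training = True
        for c in self.children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self.children():
            c.eval()
        return self

    def set_rng(self, rng: np.random.Generator) -> "Module":
        self.rng = rng
        for c in self.children():
            c.set_rng(rng)
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state ------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{k}.{i}.")
            elif k.startswith("running_") and isinstance(v, np.ndarray):
                yield f"{prefix}{k}", v

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self._buffer_owners())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=params[name].data.dtype).copy()
            elif name in bufs:
                owner, attr = bufs[name]
                setattr(owner, attr, np.asarray(value).copy())
            else:
                raise KeyError(f"unknown state entry {name!r}")

    def _buffer_owners(self, prefix: str = "") -> Iterator[tuple[str, tuple["Module", str]]]:
        for k, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v._buffer_owners(f"{prefix}{k}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item._buffer_owners(f"{prefix}{k}.{i}.")
            elif k.startswith("running_") and isinstance(v, np.ndarray):
                yield f"{prefix}{k}", (self, k)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 padding: int = 1, rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k**3
        self.padding = padding
        self.weight = Parameter(_kaiming(rng, (out_channels, in_channels, k, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels), is_weight=False)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm3d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features), is_weight=False)
        self.beta = Parameter(np.zeros(num_features), is_weight=False)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        shape = (1, -1, 1, 1, 1)
        if self.training:
            out, m, v = batchnorm_train(x, self.gamma, self.beta, self.eps)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * v
            return out
        mean = Tensor(self.running_mean.reshape(shape).astype(x.data.dtype))
        std_inv = Tensor(
            ((self.running_var.reshape(shape) + self.eps) ** -0.5).astype(x.data.dtype)
        )
        xhat = (x - mean) * std_inv
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features), is_weight=False)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout p must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.data.dtype)
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool3d(Module):
    def __init__(self, k: int = 2):
        super().__init__()
        self.k = k

    def forward(self, x: Tensor) -> Tensor:
        return maxpool3d(x, self.k)


class GlobalMaxAvgPool(Module):
    """Collapse (B, C, D, H, W) to (B, C) as the element-wise mean of the
    global max-pooled and global average-pooled feature maps, keeping the
    channel dimensionality unchanged."""

    def forward(self, x: Tensor) -> Tensor:
        mx = max_reduce(x, axis=(2, 3, 4))
        av = x.mean(axis=(2, 3, 4))
        return (mx + av) * 0.5


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.steps:
            x = m(x)
        return x
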