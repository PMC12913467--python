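"""Layer modules over the autograd core.

Initialization is the DCGAN/pix2pix convention: convolution and dense
weights ~ N(0, 0.02), biases zero, batch-norm gain one — drawn from a
caller-supplied seeded generator so identical seeds give identical networks.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "BatchNorm3d",
    "Dense",
    "state_dict",
    "load_state_dict",
]

DTYPE = np.float32
INIT_SD = 0.02


class Module:
    """Base class: parameter discovery by attribute walk (deterministic order)."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for name in sorted(vars(self)):
            value = getattr(self, name)
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad and id(item) not in seen:
                    seen.add(id(item))
                    params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def named_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """All parameter and buffer arrays, keyed by dotted attribute path."""
        out: dict[str, np.ndarray] = {}
        for name in sorted(vars(self)):
            value = getattr(self, name)
            items = (
                list(enumerate(value)) if isinstance(value, (list, tuple)) else [("", value)]
            )
            for sub, item in items:
                key = f"{prefix}{name}" + (f".{sub}" if sub != "" else "")
                if isinstance(item, Tensor):
                    out[key] = item.data
                elif isinstance(item, Module):
                    out.update(item.named_arrays(prefix=key + "."))
                elif isinstance(item, np.ndarray):
                    out[key] = item
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self.training = True
        for m in self._submodules():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._submodules():
            m.eval()

    def _submodules(self) -> list["Module"]:
        subs = []
        for name in sorted(vars(self)):
            value = getattr(self, name)
            items = value if isinstance(value, (list, tuple)) else [value]
            subs.extend(m for m in items if isinstance(m, Module))
        return subs


def state_dict(module: Module) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in module.named_arrays().items()}


def load_state_dict(module: Module, state: dict[str, np.ndarray]) -> None:
    arrays = module.named_arrays()
    if set(arrays) != set(state):
        missing = set(arrays) ^ set(state)
        raise ValueError(f"state dict keys do not match module: {sorted(missing)[:5]}")
    for key, arr in arrays.items():
        arr[...] = state[key]


def _init(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.normal(0.0, INIT_SD, size=shape).astype(DTYPE)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, bias: bool = True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.weight = Tensor(_init(rng, (out_ch, in_ch, kernel, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, self.bias, self.stride)


class ConvTranspose3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator, bias: bool = True):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.weight = Tensor(_init(rng, (in_ch, out_ch, kernel, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv_transpose3d(self.weight, self.bias, self.stride)


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        return x.batch_norm(
            self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features, self.out_features = in_features, out_features
        self.weight = Tensor(_init(rng, (in_features, out_features)), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias
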