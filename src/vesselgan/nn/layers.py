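"""Network building blocks on top of the autograd engine.

Weight initialization is N(0, 0.02) from a caller-supplied generator, the
convention for image-to-image GANs; instance-norm scale starts at 1, shifts
and conv biases at 0.
"""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor,
    conv2d,
    conv_transpose2d,
    dropout,
    instance_norm,
    leaky_relu,
    sigmoid,
    tanh,
)

_F32 = np.float32
WEIGHT_STD = 0.02


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, train/eval mode,
    state dicts for checkpointing."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=_F32).copy()


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.modules = list(modules)

    def forward(self, x):
        for m in self.modules:
            x = m(x)
        return x


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel_size, rng, stride=1, padding="same", bias=True):
        super().__init__()
        k = kernel_size
        self.stride, self.padding = stride, padding
        self.weight = Parameter(rng.normal(0.0, WEIGHT_STD, (out_ch, in_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Stride-s transposed conv; output side = s x input side."""

    def __init__(self, in_ch, out_ch, kernel_size, rng, stride=2, padding=1, bias=True):
        super().__init__()
        k = kernel_size
        self.stride, self.padding = stride, padding
        self.weight = Parameter(rng.normal(0.0, WEIGHT_STD, (in_ch, out_ch, k, k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class InstanceNorm2d(Module):
    def __init__(self, num_ch, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(num_ch))
        self.bias = Parameter(np.zeros(num_ch))

    def forward(self, x):
        return instance_norm(x, self.weight, self.bias, eps=self.eps)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.2):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x):
        return leaky_relu(x, self.negative_slope)


class Tanh(Module):
    def forward(self, x):
        return tanh(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class Dropout(Module):
    """Inverted dropout driven by a shared generator so a seeded build gives a
    seeded training trajectory. Active only in training mode (a flag can keep
    it on at inference to realize the noise input z)."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x):
        return dropout(x, self.p, self.rng, training=self.training)
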