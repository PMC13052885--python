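"""Neural-network building blocks on top of the autodiff tensor.

Layers follow the conventions of the reference point-cloud classifiers:
channel-last layout (features live on the trailing axis), affine maps shared
across points, batch normalization over all leading axes, and Kaiming-uniform
initialization.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor, index_points, logsumexp

__all__ = [
    "Module", "Parameter", "Linear", "BatchNorm", "Dropout", "ReLU",
    "LeakyReLU", "Sequential", "Adam", "cross_entropy",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: parameter traversal and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map on the trailing axis: ``y = x W^T + b``."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        bound = float(np.sqrt(1.0 / in_features))
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(rng.uniform(-bound, bound, out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.swapaxes(0, 1)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm(Module):
    """Normalize the trailing (channel) axis over all leading axes.

    Batch statistics are used in training mode; exponentially averaged
    running statistics in eval mode.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            n = x.data.size // x.shape[-1]
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1).astype(np.float32))
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_var = ((1 - m) * self.running_var
                                + m * unbiased.astype(np.float32))
        else:
            mu = Tensor(self.running_mean)
            xc = x - mu
            var = Tensor(self.running_var)
        inv = (var + self.eps) ** -0.5
        return xc * inv * self.weight + self.bias


class Dropout(Module):
    """Inverted dropout; active only in training mode.

    The generator is owned by the enclosing model so that training runs are
    reproducible from a single seed.
    """

    def __init__(self, p: float, rng_holder: dict):
        super().__init__()
        self.p = p
        self._rng_holder = rng_holder

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        rng: np.random.Generator = self._rng_holder["rng"]
        mask = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits`` (B, C)."""
    labels = np.asarray(labels)
    lse = logsumexp(logits, axis=-1).reshape(logits.shape[0])
    picked = index_points(logits, labels)
    return (lse - picked).mean()


class Adam:
    """Adam optimizer with a mutable learning rate (for step schedules)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
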