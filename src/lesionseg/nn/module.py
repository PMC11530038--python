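"""Layer containers over the autograd engine: Module, Conv2d, Linear, BatchNorm2d."""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from . import functional as F
from .tensor import DTYPE, Tensor


class Parameter(Tensor):
    """A tensor registered for optimization."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; children and parameters are discovered from attributes."""

    def __init__(self):
        self.training = True

    # attribute scan is ordered by insertion -> deterministic naming
    def _children(self) -> Iterator[Tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def _own_params(self) -> Iterator[Tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield name, val

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, p in self._own_params():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- serialization -----------------------------------------------------
    def _buffers(self) -> Iterator[Tuple[str, np.ndarray]]:
        return iter(())

    def state_dict(self, prefix: str = "") -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for name, p in self._own_params():
            out[prefix + name] = p.data.copy()
        for name, b in self._buffers():
            out[prefix + name] = b.copy()
        for cname, child in self._children():
            out.update(child.state_dict(prefix + cname + "."))
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray], prefix: str = "") -> None:
        for name, p in self._own_params():
            key = prefix + name
            if key not in state:
                raise KeyError(f"missing parameter {key!r} in state dict")
            if state[key].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: {state[key].shape} vs {p.data.shape}"
                )
            p.data = np.asarray(state[key], dtype=DTYPE).copy()
        self._load_buffers(state, prefix)
        for cname, child in self._children():
            child.load_state_dict(state, prefix + cname + ".")

    def _load_buffers(self, state: Dict[str, np.ndarray], prefix: str) -> None:
        pass

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.padding = padding
        self.weight = Parameter(np.zeros((out_channels, in_channels, k, k), dtype=DTYPE))
        self.bias = Parameter(np.zeros(out_channels, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(np.zeros((out_features, in_features), dtype=DTYPE))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        # gradient is routed to the stored (out, in) layout
        out = x @ _transposed_view(self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


def _transposed_view(p: Parameter) -> Tensor:
    from .tensor import is_grad_enabled

    t = Tensor(p.data.T)
    if is_grad_enabled():
        t._parents = (p,)

        def bw(g):
            p._accumulate(g.T)

        t._backward = bw
    return t


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) per channel.

    Training uses batch statistics and updates running averages with the
    given momentum; evaluation uses the running averages.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features, dtype=DTYPE))
        self.bias = Parameter(np.zeros(num_features, dtype=DTYPE))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def _buffers(self):
        yield "running_mean", self.running_mean
        yield "running_var", self.running_var

    def _load_buffers(self, state, prefix):
        self.running_mean = np.asarray(state[prefix + "running_mean"], dtype=DTYPE).copy()
        self.running_var = np.asarray(state[prefix + "running_var"], dtype=DTYPE).copy()

    def forward(self, x: Tensor) -> Tensor:
        c = x.data.shape[1]
        if c != self.num_features:
            raise ValueError(f"BatchNorm2d expected {self.num_features} channels, got {c}")
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var * (n / max(n - 1, 1))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            ).astype(DTYPE)
            return F.batch_norm(x, self.weight, self.bias, mean, var, self.eps, True)
        return F.batch_norm(
            x, self.weight, self.bias, self.running_mean, self.running_var, self.eps, False
        )


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
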