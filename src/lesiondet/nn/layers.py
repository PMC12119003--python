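"""Neural-network modules built on the autodiff core.

The module system mirrors the familiar container/parameter pattern:
``Module`` discovers parameters and submodules from instance attributes,
supports train/eval modes and flat ``state_dict`` round-trips.  ``Conv2d``
records its most recent output spatial size so the complexity profiler can
account FLOPs without a separate shape-inference pass.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, max_pool2d, upsample_nearest2x

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "SiLU",
    "ReLU",
    "Sigmoid",
    "Identity",
    "Sequential",
    "ModuleList",
    "MaxPool2d",
    "Upsample",
    "SGD",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -- discovery ------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}{name}.")

    def num_params(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    # -- modes ----------------------------------------------------------
    def train(self):
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self):
        for _, m in self.named_modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- serialization --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self.named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                key = f"{mname}.{bname}" if mname else bname
                out[key] = buf.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        for mname, m in self.named_modules():
            for bname in getattr(m, "_buffers", {}):
                key = f"{mname}.{bname}" if mname else bname
                buffers[key] = (m, bname)
        for key, arr in state.items():
            if key in params:
                if params[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = arr.astype(np.float32).copy()
            elif key in buffers:
                m, bname = buffers[key]
                m._buffers[bname] = arr.astype(np.float32).copy()
            else:
                raise KeyError(f"unexpected state entry {key}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Grouped 2-D convolution; ``padding=None`` gives 'same' for odd kernels."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int | tuple[int, int],
                 stride: int = 1, padding=None, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(kernel_size, int):
            kernel_size = (kernel_size, kernel_size)
        if in_channels % groups or out_channels % groups:
            raise ValueError("groups must divide in_channels and out_channels")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        kh, kw = kernel_size
        fan_in = in_channels // groups * kh * kw
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, (out_channels, in_channels // groups, kh, kw)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.last_out_hw: tuple[int, int] | None = None
        self._recorded_out_hws: list[tuple[int, int]] | None = None

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)
        self.last_out_hw = out.shape[2:]
        if self._recorded_out_hws is not None:
            # profiling: a shared layer applied k times costs k applications
            self._recorded_out_hws.append(out.shape[2:])
        return out


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self._buffers = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        c = self.channels
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(c)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(c)
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            mu = self._buffers["running_mean"].reshape(1, c, 1, 1)
            var = self._buffers["running_var"].reshape(1, c, 1, 1)
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._n = len(mods)

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def forward(self, x: Tensor) -> Tensor:
        for m in self:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods):
        super().__init__()
        mods = list(mods)
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._n = len(mods)

    def __len__(self):
        return self._n

    def __iter__(self):
        return (getattr(self, f"m{i}") for i in range(self._n))

    def __getitem__(self, i):
        return getattr(self, f"m{i}")

    def forward(self, x):  # pragma: no cover - containers are iterated, not called
        raise NotImplementedError


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int = 1, padding: int | None = None):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.padding = (kernel - 1) // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)


class Upsample(Module):
    """Nearest-neighbour 2x upsampling (the only mode the neck needs)."""

    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest2x(x)


class SGD:
    """SGD with classical momentum and decoupled weight decay on conv weights."""

    def __init__(self, params, lr: float, momentum: float = 0.937, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
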