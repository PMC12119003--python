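"""Parameter and FLOP accounting.

FLOPs follow the convention ``2*H*W*(Cin*K^2 + 1)*Cout`` per convolution
output map (the +1 is the per-output-element bias/accumulation term and is
charged whether or not the layer carries an explicit bias) plus
``(2*I - 1)*O`` per fully-connected layer.  Normalization, activation,
pooling and resampling layers are charged zero FLOPs; their parameters are
still counted.  For grouped/depthwise convolutions ``Cin`` is the
per-group fan-in.  Totals are reported as GFLOPs (1e9) and parameters in
millions, rounded half-up to one decimal for table-style comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LayerDims",
    "LayerRecord",
    "ComplexityReport",
    "conv_flops",
    "fc_flops",
    "count_params",
    "count_flops",
    "profile_model",
    "round1",
]


def round1(x: float) -> float:
    """Half-up rounding to one decimal (table convention)."""
    return float(np.floor(x * 10 + 0.5) / 10)


@dataclass(frozen=True)
class LayerDims:
    """Dimensions for one analytic FLOP term."""

    H: int = 0
    W: int = 0
    Cin: int = 0
    Cout: int = 0
    K: int = 0
    I: int = 0
    O: int = 0


def conv_flops(h: int, w: int, cin: int, cout: int, k: int | tuple[int, int]) -> int:
    if isinstance(k, tuple):
        ksq = k[0] * k[1]
    else:
        ksq = k * k
    return 2 * h * w * (cin * ksq + 1) * cout


def fc_flops(i: int, o: int) -> int:
    return (2 * i - 1) * o


@dataclass
class LayerRecord:
    name: str
    params: int
    flops: int


@dataclass
class ComplexityReport:
    variant: str
    input_hw: tuple[int, int]
    layers: list[LayerRecord] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(r.params for r in self.layers)

    @property
    def total_flops(self) -> int:
        return sum(r.flops for r in self.layers)

    @property
    def gflops(self) -> float:
        return self.total_flops / 1e9

    @property
    def params_m(self) -> float:
        return self.total_params / 1e6

    def summary_row(self) -> str:
        return (f"{self.variant:>18}  params {round1(self.params_m):4.1f} M  "
                f"GFLOPs {round1(self.gflops):5.1f}  (input {self.input_hw[0]}x{self.input_hw[1]})")

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant,
            "input_hw": list(self.input_hw),
            "total_params": self.total_params,
            "gflops": self.gflops,
            "layers": [{"name": r.name, "params": r.params, "flops": r.flops}
                       for r in self.layers],
        }, indent=2)


def count_params(model: nn.Module) -> int:
    """Exact count of trainable scalars."""
    return model.num_params()


def _module_own_params(m: nn.Module) -> int:
    return sum(int(v.data.size) for v in vars(m).values() if isinstance(v, nn.Parameter))


def profile_model(model, input_hw: tuple[int, int] = (640, 640),
                  variant_name: str | None = None,
                  in_channels: int = 3) -> ComplexityReport:
    """Walk the model, recording per-layer params and FLOPs.

    A forward pass on a zero input records each convolution's output size
    (per application, so shared layers are charged for every call); FLOPs
    are then computed analytically per layer.
    """
    h, w = input_hw
    model.eval()
    convs = [m for _, m in model.named_modules() if isinstance(m, nn.Conv2d)]
    for m in convs:
        m._recorded_out_hws = []
    try:
        model(Tensor(np.zeros((1, in_channels, h, w), dtype=np.float32)))
        name = variant_name or getattr(getattr(model, "variant", None), "name", "model")
        report = ComplexityReport(variant=name, input_hw=(h, w))
        for mname, m in model.named_modules():
            own = _module_own_params(m)
            if own == 0 and not isinstance(m, nn.Conv2d):
                continue
            flops = 0
            if isinstance(m, nn.Conv2d):
                if not m._recorded_out_hws:
                    raise RuntimeError(f"layer {mname} was never executed")
                # a layer shared across k call sites is charged once per call
                flops = sum(
                    conv_flops(oh, ow, m.in_channels // m.groups, m.out_channels,
                               m.kernel_size)
                    for oh, ow in m._recorded_out_hws
                )
            report.layers.append(LayerRecord(name=mname or "root", params=own, flops=flops))
    finally:
        for m in convs:
            m._recorded_out_hws = None
    return report


def count_flops(model_or_dims, input_hw: tuple[int, int] = (640, 640)) -> int:
    """Total FLOPs, either analytically from :class:`LayerDims` or by profiling."""
    if isinstance(model_or_dims, LayerDims):
        d = model_or_dims
        total = 0
        if d.Cout and d.H and d.W and d.K:
            total += conv_flops(d.H, d.W, d.Cin, d.Cout, d.K)
        if d.I and d.O:
            total += fc_flops(d.I, d.O)
        return total
    return profile_model(model_or_dims, input_hw).total_flops
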