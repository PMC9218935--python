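"""Analytic parameter and FLOP accounting.

A convolution with kernel K, C_in input channels, C_out output channels and
an H_out x W_out output costs

    params = (K^2 * C_in + 1) * C_out            (bias included)
    FLOPs  = 2 * K^2 * C_in * C_out * H_out * W_out

i.e. FLOPs are two operations per multiply-accumulate. A Ghost module with
ratio s=2 and cheap kernel d spends a primary conv on half the output
channels plus a depthwise conv on those maps:

    params = (K^2*C_in + 1)*C_out/2 + (d^2 + 1)*C_out/2
    FLOPs  = 2*K^2*C_in*(C_out/2)*H*W + 2*d^2*(C_out/2)*H*W

(for d = K these collapse to [K^2*(C_in+1)+2]*C_out/2 and
2*K^2*(C_in+1)*(C_out/2)*H*W). A transposed convolution's FLOPs scale with
its *input* spatial size:

    FLOPs = 2 * K^2 * C_in * C_out * H_in * W_in

Bias, batchnorm, activation, pooling, interpolation and elementwise
addition are costed at zero FLOPs; batchnorm contributes 2 parameters per
channel (scale + shift), running statistics are not counted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .architectures import NetworkSpec
from .blocks import ConvSpec, DeconvSpec, GhostSpec

__all__ = [
    "conv_params",
    "conv_flops",
    "ghost_params",
    "ghost_flops",
    "deconv_params",
    "deconv_flops",
    "count_network",
    "ComplexityReport",
    "format_count",
    "verify_against_runtime",
]


def conv_params(spec: ConvSpec) -> int:
    p = (spec.kernel_size**2 * spec.in_channels + (1 if spec.has_bias else 0)) \
        * spec.out_channels
    if spec.with_batchnorm:
        p += 2 * spec.out_channels
    return p


def conv_flops(spec: ConvSpec, hout: int, wout: int) -> int:
    return 2 * spec.kernel_size**2 * spec.in_channels * spec.out_channels * hout * wout


def ghost_params(spec: GhostSpec) -> int:
    half = spec.out_channels // 2
    primary = (spec.kernel_size**2 * spec.in_channels + 1) * half
    cheap = (spec.cheap_kernel**2 + 1) * half
    p = primary + cheap
    if spec.with_batchnorm:
        p += 2 * spec.out_channels  # scale+shift on both halves
    return p


def ghost_flops(spec: GhostSpec, hout: int, wout: int) -> int:
    half = spec.out_channels // 2
    hw = hout * wout
    return (2 * spec.kernel_size**2 * spec.in_channels * half * hw
            + 2 * spec.cheap_kernel**2 * half * hw)


def deconv_params(spec: DeconvSpec) -> int:
    return (spec.kernel_size**2 * spec.in_channels + 1) * spec.out_channels


def deconv_flops(spec: DeconvSpec, hin: int | None = None, win: int | None = None) -> int:
    hin = spec.input_height if hin is None else hin
    win = spec.input_width if win is None else win
    if hin is None or win is None:
        raise ValueError("deconv FLOPs need the input spatial size")
    return 2 * spec.kernel_size**2 * spec.in_channels * spec.out_channels * hin * win


# ---------------------------------------------------------------------------
# whole-network ledgers


def format_count(n: int, unit: str | None = None) -> str:
    """Human-readable count: two decimals, round half up, K/M/G units."""
    scales = {"K": 10**3, "M": 10**6, "G": 10**9}
    if unit is None:
        unit = "G" if n >= 10**9 else ("M" if n >= 10**6 else "K")
    q = (Decimal(n) / scales[unit]).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return f"{q} {unit}"


@dataclass
class ReportRow:
    name: str
    kind: str
    params: int
    flops: int


@dataclass
class ComplexityReport:
    network: str
    input_shape: tuple
    rows: list = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(r.params for r in self.rows)

    @property
    def total_flops(self) -> int:
        return sum(r.flops for r in self.rows)

    def params_str(self, unit: str = "M") -> str:
        return format_count(self.total_params, unit)

    def flops_str(self, unit: str = "G") -> str:
        return format_count(self.total_flops, unit)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["layer", "kind", "params", "flops"])
            for r in self.rows:
                w.writerow([r.name, r.kind, r.params, r.flops])
            w.writerow(["total", "", self.total_params, self.total_flops])


def _node_cost(node, shapes):
    c = node.cfg
    if node.kind == "conv":
        cout, h, w = shapes[node.name]
        spec = ConvSpec(c["k"], c["cin"], c["cout"], has_bias=c.get("bias", True),
                        with_batchnorm=c.get("batchnorm", False))
        return conv_params(spec), conv_flops(spec, h, w)
    if node.kind == "ghost":
        cout, h, w = shapes[node.name]
        spec = GhostSpec(c["k"], c["cin"], c["cout"], ratio=c.get("s", 2),
                         cheap_kernel=c.get("d", 3),
                         with_batchnorm=c.get("batchnorm", True))
        return ghost_params(spec), ghost_flops(spec, h, w)
    if node.kind == "deconv":
        _, hin, win = shapes[node.inputs[0]]
        spec = DeconvSpec(c["k"], c["cin"], c["cout"])
        return deconv_params(spec), deconv_flops(spec, hin, win)
    return 0, 0  # pooling, interpolation, add, concat, activations


def count_network(network: NetworkSpec, input_shape=None) -> ComplexityReport:
    """Traverse a network graph and produce a per-layer ledger of analytic
    parameter and FLOP counts, resolving spatial sizes from the input."""
    input_shape = tuple(input_shape or network.input_shape)
    shapes = network.infer_shapes(input_shape)
    report = ComplexityReport(network.name, input_shape)
    for node in network.nodes:
        if node.kind == "input":
            continue
        p, f = _node_cost(node, shapes)
        report.rows.append(ReportRow(node.name, node.kind, p, f))
    return report


def verify_against_runtime(network: NetworkSpec, input_shape=None, seed=0) -> dict:
    """Cross-check the analytic parameter total against a brute-force
    enumeration of every learnable scalar in an instantiated runtime model."""
    from .runtime import Model

    analytic = count_network(network, input_shape).total_params
    model = Model(network, seed=seed)
    enumerated = sum(
        int(arr.size) for _, _, _, arr in model.parameters()
    )
    return {"analytic": analytic, "enumerated": enumerated,
            "equal": analytic == enumerated}
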