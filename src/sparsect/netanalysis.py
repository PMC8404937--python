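"""Green-AI accounting: receptive fields, parameters, FLOPs.

The receptive field of layer t follows the layer-wise recursion

    r_0 = 1,    r_t = r_{t-1} + (k_t - 1) * prod_{i<=t} s_i,

i.e. each layer widens the field by its kernel extent scaled by the
cumulative stride.  ``receptive_field`` evaluates this recursion (the
``"recursion"`` convention, the one used to compare the two architectures).

A caveat the recursion hides: for a layer with kernel > 1 *and* stride > 1
(a 2x2/2 pool) it scales the kernel extent by the *post*-stride sampling
density, which over-counts the true input support; the alignment-exact
rule (the ``"support"`` convention) scales by the pre-stride product,
    r_t = r_{t-1} + (k_t - 1) * prod_{i<t} s_i,
and the two agree exactly whenever every strided layer has kernel 1, and on
all stride-1 stacks.  ``empirical_rf`` is an independent oracle measuring
the true input support of one output response on a positively-weighted
linearized copy of the network; it reproduces the ``support`` convention on
arbitrary conv/pool stacks and therefore also the recursion wherever the
two conventions coincide (e.g. the three-layer single-scale net).

Cost accounting convention (stated in every report): FLOPs count 2
operations per multiply-accumulate, convolution layers only (biases,
normalization and activations excluded); the headline parameter count is
convolution weights only, with the all-trainable count (biases + norm
affine terms) reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .networks import NetworkSpec

__all__ = ["RFResult", "CostReport", "receptive_field", "empirical_rf",
           "count_parameters", "count_flops"]

FLOP_CONVENTION = "2 ops per MAC, conv layers only"


@dataclass
class RFResult:
    per_layer: list[int]          # r_0 .. r_T (r_0 = 1)
    increments: list[int]         # A_1 .. A_T
    max_rf: int
    input_side: int = 512

    @property
    def percent_of_input(self) -> float:
        """max_rf^2 as a percentage of the input_side^2 image area."""
        return 100.0 * self.max_rf ** 2 / self.input_side ** 2


@dataclass
class CostReport:
    weight_params: int
    all_trainable_params: int
    flops: float | None = None
    input_side: int | None = None
    convention: str = FLOP_CONVENTION


def receptive_field(layers, input_side: int = 512,
                    convention: str = "recursion") -> RFResult:
    """Receptive fields of ordered (kernel, stride) pairs.

    ``convention="recursion"`` (default) is the published layer-wise
    recursion; ``"support"`` is the alignment-exact variant matched by
    :func:`empirical_rf` (see module docstring).  An empty list yields
    max_rf = 1 (the input pixel itself).
    """
    if convention not in ("recursion", "support"):
        raise ValueError(f"unknown convention {convention!r}")
    r = [1]
    incs = []
    stride_prod = 1
    for k, s in layers:
        if k < 1 or s < 1:
            raise ValueError("kernels and strides must be >= 1")
        if convention == "recursion":
            stride_prod *= s
            a = (k - 1) * stride_prod
        else:
            a = (k - 1) * stride_prod
            stride_prod *= s
        incs.append(a)
        r.append(r[-1] + a)
    return RFResult(per_layer=r, increments=incs, max_rf=r[-1],
                    input_side=input_side)


def _oracle_modules(pairs: list[tuple[int, int]]) -> list[nn.Module]:
    """Positively-weighted, linear, single-channel twin of a conv/pool
    stack: conv weights 1/k^2 (bias 0), average pooling, no normalization
    or nonlinearity.  Its adjoint support equals the receptive field."""
    mods: list[nn.Module] = []
    for k, s in pairs:
        if s == 1:
            conv = nn.Conv2d(1, 1, k, name="probe")
            conv.weight.value[...] = 1.0 / (k * k)
            conv.bias.value[...] = 0.0
            mods.append(conv)
        elif k == 2 and s == 2:
            mods.append(nn.AvgPool2x2())
        else:
            raise ValueError("oracle supports stride-1 convs and 2x2/2 pools")
    return mods


def empirical_rf(spec: NetworkSpec | list, input_side: int = 96) -> int:
    """Measured receptive field: side of the input bounding box that one
    central output response depends on.

    Works on a NetworkSpec (its receptive-field-defining path) or directly
    on a list of (kernel, stride) pairs.  The probe runs one forward pass to
    shape the graph and one adjoint pass from a unit impulse at the central
    output pixel; the support of the returned input gradient is the
    receptive field, independent of the analytic recursion.
    """
    pairs = spec.rf_layers() if isinstance(spec, NetworkSpec) else list(spec)
    mods = _oracle_modules(pairs)
    x = np.ones((1, input_side, input_side, 1), np.float32)
    for m in mods:
        if x.shape[1] < 2:
            raise ValueError("input_side too small for this stack's pooling")
        x = m.forward(x, training=True)
    out_side = x.shape[1]
    dy = np.zeros_like(x)
    dy[0, out_side // 2, out_side // 2, 0] = 1.0
    for m in reversed(mods):
        dy = m.backward(dy)
    support = np.argwhere(np.abs(dy[0, :, :, 0]) > 0)
    if support.size == 0:
        return 1
    (r0, c0), (r1, c1) = support.min(axis=0), support.max(axis=0)
    if r0 == 0 or c0 == 0 or r1 == input_side - 1 or c1 == input_side - 1:
        raise ValueError(
            f"receptive field reaches the {input_side}px input border; "
            "re-run with a larger input_side")
    return int(max(r1 - r0, c1 - c0) + 1)


def count_parameters(spec: NetworkSpec) -> CostReport:
    """Convolution weights (k^2 * c_in * c_out), plus biases and batch-norm
    affine pairs for the all-trainable figure; pool/upsample layers are
    parameter-free."""
    weights = 0
    trainable = 0
    for layer, _ in spec.flat_layers():
        if layer.kind != "conv":
            continue
        w = layer.kernel ** 2 * layer.in_channels * layer.out_channels
        weights += w
        trainable += w + layer.out_channels
        if layer.normalization:
            trainable += 2 * layer.out_channels
    return CostReport(weight_params=weights, all_trainable_params=trainable)


def count_flops(spec: NetworkSpec, input_side: int) -> CostReport:
    """Forward FLOPs at the given input size: sum over conv layers of
    2 * H_t * W_t * k^2 * c_in * c_out, with H_t, W_t after the preceding
    pooling/upsampling stages."""
    report = count_parameters(spec)
    flops = 0.0
    for layer, scale in spec.flat_layers():
        if layer.kind != "conv":
            continue
        side = input_side * scale
        flops += 2.0 * side * side * layer.kernel ** 2 \
            * layer.in_channels * layer.out_channels
    report.flops = flops
    report.input_side = input_side
    return report
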