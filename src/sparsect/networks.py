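"""Declarative CNN architecture specs and runtime models.

Two architectures are provided for learned post-processing of FBP
reconstructions:

* **3L-SSNet** — a three-layer single-scale CNN (no pooling), trained as a
  direct correction map ``x̄ = F(y)``.  The textual description of this net
  (kernels {9,5,3}, constant 128 channels) and its published cost figures
  (≈85k parameters) are mutually inconsistent; both readings are available
  as the ``as-text`` and ``table-consistent`` variants, the latter being the
  default because it matches the published parameter/FLOP budget.
* **ResUNet** — a symmetric encoder–decoder UNet with additive skip
  connections and a global input→output residual link, trained as a residual
  map ``x̄ = y + R(y)`` whose final activation is ``tanh``.

A :class:`NetworkSpec` is a pure description (layers, channels, residual
mode) plus an optional parameter container; :class:`Network` materializes it
into the NumPy layer graph and runs forward/backward passes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "Network",
    "build_3lssnet",
    "build_resunet",
    "forward",
]


@dataclass
class LayerSpec:
    """One layer of a network description.

    kind: "conv", "pool" (2x2 stride-2 max) or "upsample" (nearest x2).
    Conv layers are stride 1 with zero 'same' padding.
    """
    kind: str
    kernel: int = 1
    stride: int = 1
    in_channels: int = 0
    out_channels: int = 0
    normalization: bool = False
    activation: str = "linear"  # relu | tanh | linear

    def __post_init__(self):
        if self.kind not in ("conv", "pool", "upsample"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be >= 1")


@dataclass
class NetworkSpec:
    """Architecture description; holds trained parameters opaquely.

    ``topology`` is "sequential" (flat ``layers`` list) or "encoder-decoder"
    (levels/channel-doubling UNet described by ``levels``, ``n_convs``,
    ``c0``).  ``residual_mode`` selects x̄ = y + R(y) over x̄ = F(y).
    """
    name: str
    topology: str
    layers: list = field(default_factory=list)          # sequential only
    levels: int = 0                                      # encoder-decoder
    n_convs: int = 0
    c0: int = 0
    residual_mode: bool = False
    params: dict = field(default_factory=dict, repr=False)

    # -- structure enumeration -------------------------------------------
    def flat_layers(self) -> list[tuple[LayerSpec, float]]:
        """All layers in forward order with their spatial scale factor
        (output side / input side) at the layer's *output*."""
        if self.topology == "sequential":
            return [(l, 1.0) for l in self.layers]
        out: list[tuple[LayerSpec, float]] = []
        scale = 1.0
        L, n, c0 = self.levels, self.n_convs, self.c0
        ch = [c0 * 2 ** l for l in range(L + 1)]
        # encoder
        for l in range(L + 1):
            cin = 1 if l == 0 else ch[l - 1]
            for i in range(n):
                out.append((LayerSpec("conv", 3, 1, cin if i == 0 else ch[l],
                                      ch[l], True, "relu"), scale))
            if l < L:
                scale /= 2
                out.append((LayerSpec("pool", 2, 2), scale))
        # decoder
        for l in range(L - 1, -1, -1):
            scale *= 2
            out.append((LayerSpec("upsample", 1, 1), scale))
            out.append((LayerSpec("conv", 3, 1, ch[l + 1], ch[l], True,
                                  "relu"), scale))
            for _ in range(n):
                out.append((LayerSpec("conv", 3, 1, ch[l], ch[l], True,
                                      "relu"), scale))
        out.append((LayerSpec("conv", 3, 1, c0, 1, False, "tanh"), scale))
        return out

    def rf_layers(self) -> list[tuple[int, int]]:
        """(kernel, stride) pairs along the receptive-field-defining path.

        For the encoder–decoder topology this is the encoder path down to the
        bottleneck, the network's deepest contracting branch; decoder
        upsampling layers have fractional stride and fall outside the
        integer-stride receptive-field recursion.
        """
        if self.topology == "sequential":
            return [(l.kernel, l.stride) for l in self.layers
                    if l.kind in ("conv", "pool")]
        pairs = []
        for l in range(self.levels + 1):
            pairs.extend([(3, 1)] * self.n_convs)
            if l < self.levels:
                pairs.append((2, 2))
        return pairs

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        d.pop("params")
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        d = json.loads(text)
        d["layers"] = [LayerSpec(**l) for l in d.get("layers", [])]
        return cls(**d)

    def save(self, path) -> None:
        """Checkpoint: architecture JSON + weights in one .npz file."""
        np.savez(path, __spec__=np.frombuffer(self.to_json().encode(), np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path) -> "NetworkSpec":
        with np.load(path) as z:
            spec = cls.from_json(bytes(z["__spec__"]).decode())
            spec.params = {k: z[k] for k in z.files if k != "__spec__"}
        return spec


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_3lssnet(variant: str = "table-consistent") -> NetworkSpec:
    """Three-layer single-scale CNN.

    ``table-consistent`` (default): conv9(1→128) / conv3(128→64) /
    conv5(64→1), matching the published ≈85k-parameter budget.
    ``as-text``: conv9(1→128) / conv5(128→128) / conv3(128→1), the literal
    {9,5,3}-kernel, constant-128-channel reading.  Hidden blocks are
    Conv2D + BatchNorm + ReLU; the output conv is linear (the net learns the
    correction map directly, not a residual).
    """
    if variant == "table-consistent":
        dims = [(9, 1, 128), (3, 128, 64), (5, 64, 1)]
    elif variant == "as-text":
        dims = [(9, 1, 128), (5, 128, 128), (3, 128, 1)]
    else:
        raise ValueError(f"unknown 3L-SSNet variant {variant!r}")
    layers = []
    for i, (k, cin, cout) in enumerate(dims):
        last = i == len(dims) - 1
        layers.append(LayerSpec("conv", k, 1, cin, cout,
                                normalization=not last,
                                activation="linear" if last else "relu"))
    return NetworkSpec(name=f"3L-SSNet[{variant}]", topology="sequential",
                       layers=layers, residual_mode=False)


def build_resunet(c0: int = 64, L: int = 4, n: int = 3) -> NetworkSpec:
    """Residual UNet: L+1 levels, n 3x3 convs per level, channels doubling
    from c0, 2x2 max pools, nearest-neighbour upsampling + 3x3 conv,
    additive skips, global residual with tanh-activated final conv."""
    if c0 < 1 or L < 1 or n < 1:
        raise ValueError("c0, L, n must be >= 1")
    return NetworkSpec(name=f"ResUNet[c0={c0},L={L},n={n}]",
                       topology="encoder-decoder", levels=L, n_convs=n,
                       c0=c0, residual_mode=True)


# ---------------------------------------------------------------------------
# runtime model
# ---------------------------------------------------------------------------

def _act(name: str) -> nn.Module:
    return {"relu": nn.ReLU, "tanh": nn.Tanh, "linear": nn.Identity}[name]()


def _conv_block(spec: LayerSpec, rng, name, first=False) -> nn.Sequential:
    mods: list[nn.Module] = [nn.Conv2d(spec.in_channels, spec.out_channels,
                                       spec.kernel, rng, name, first_layer=first)]
    if spec.normalization:
        mods.append(nn.BatchNorm2d(spec.out_channels, name=name + ".norm"))
    mods.append(_act(spec.activation))
    return nn.Sequential(*mods)


class _UNetCore(nn.Module):
    """Encoder–decoder graph with additive skips (the R of x̄ = y + R(y))."""

    def __init__(self, spec: NetworkSpec, rng):
        L, n, c0 = spec.levels, spec.n_convs, spec.c0
        ch = [c0 * 2 ** l for l in range(L + 1)]
        self.L = L
        self.enc: list[nn.Sequential] = []
        for l in range(L + 1):
            blocks = []
            for i in range(n):
                cin = (1 if l == 0 else ch[l - 1]) if i == 0 else ch[l]
                blocks.append(_conv_block(
                    LayerSpec("conv", 3, 1, cin, ch[l], True, "relu"), rng,
                    f"enc{l}.{i}", first=(l == 0 and i == 0)))
            self.enc.append(nn.Sequential(*blocks))
        self.pools = [nn.MaxPool2x2() for _ in range(L)]
        self.ups: list[nn.Sequential] = []
        self.dec: list[nn.Sequential] = []
        for l in range(L - 1, -1, -1):
            self.ups.append(nn.Sequential(
                nn.UpsampleNearest2x(),
                *_conv_block(LayerSpec("conv", 3, 1, ch[l + 1], ch[l], True,
                                       "relu"), rng, f"up{l}").modules))
            self.dec.append(nn.Sequential(*[
                _conv_block(LayerSpec("conv", 3, 1, ch[l], ch[l], True,
                                      "relu"), rng, f"dec{l}.{i}")
                for i in range(n)]))
        self.final = _conv_block(LayerSpec("conv", 3, 1, c0, 1, False, "tanh"),
                                 rng, "final")

    def forward(self, x, training=True):
        skips = []
        for l in range(self.L):
            x = self.enc[l].forward(x, training)
            skips.append(x)
            x = self.pools[l].forward(x, training)
        x = self.enc[self.L].forward(x, training)
        for i, l in enumerate(range(self.L - 1, -1, -1)):
            x = self.ups[i].forward(x, training)
            x = x + skips[l]          # additive skip
            x = self.dec[i].forward(x, training)
        return self.final.forward(x, training)

    def backward(self, dy):
        d = self.final.backward(dy)
        dskip_acc = [None] * self.L
        # decoder stages in reverse build order (build order runs l = L-1..0)
        for i in range(len(self.dec) - 1, -1, -1):
            l = self.L - 1 - i
            d = self.dec[i].backward(d)
            dskip_acc[l] = d          # addition: same grad to both branches
            d = self.ups[i].backward(d)
        d = self.enc[self.L].backward(d)
        for l in range(self.L - 1, -1, -1):
            d = self.pools[l].backward(d)
            d = d + dskip_acc[l]
            d = self.enc[l].backward(d)
        return d

    def params(self):
        out = []
        for m in self.enc + self.ups + self.dec + [self.final]:
            out.extend(m.params())
        for l in range(self.L):
            out.extend(self.pools[l].params())
        return out


class Network:
    """Runtime model bound to a :class:`NetworkSpec`.

    ``predict`` applies the learned post-processing map to one 2D image:
    F(y) in direct mode, y + R(y) in residual mode (the residual is added in
    the input's dtype, so a zero residual returns the input unchanged).

    ``inference_stats`` selects the batch-norm statistics used at
    inference: ``"running"`` (default) uses the stored statistics — after
    training these are precise population statistics over the training
    set, not the lagging exponential averages (see
    :func:`sparsect.training.recalibrate_bn`); ``"image"`` normalizes with
    the input's own spatial statistics, which suits scale-invariant
    residual correction but discards the absolute-intensity information a
    direct map needs.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0,
                 inference_stats: str = "running"):
        if inference_stats not in ("image", "running"):
            raise ValueError(f"unknown inference_stats {inference_stats!r}")
        self.inference_stats = inference_stats
        self.spec = spec
        rng = np.random.default_rng(seed)
        if spec.topology == "sequential":
            self.core = nn.Sequential(*[
                _conv_block(l, rng, f"layer{i}", first=(i == 0))
                for i, l in enumerate(spec.layers)])
        elif spec.topology == "encoder-decoder":
            self.core = _UNetCore(spec, rng)
        else:
            raise ValueError(f"unknown topology {spec.topology!r}")
        # Near-identity start (standard for restoration nets): a small final
        # conv makes the fresh residual net reproduce its input and the
        # fresh direct net start near zero output instead of random noise.
        self._final_conv().weight.value *= np.float32(0.01)
        self.trained = bool(spec.params)
        if spec.params:
            self.load_state(spec.params)

    # -- parameter plumbing ----------------------------------------------
    def _final_conv(self) -> nn.Conv2d:
        if isinstance(self.core, _UNetCore):
            return self.core.final.modules[0]
        return self.core.modules[-1].modules[0]

    def params(self) -> list[nn.Param]:
        return self.core.params()

    def state_dict(self) -> dict:
        """Trainable parameters plus batch-norm running statistics."""
        state = {p.name: p.value.copy() for p in self.params()}
        for b in self._bn_modules():
            state[f"{b.name}.running_mean"] = b.running_mean.copy()
            state[f"{b.name}.running_var"] = b.running_var.copy()
        return state

    def load_state(self, state: dict) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for b in self._bn_modules():
            if f"{b.name}.running_mean" in state:
                b.running_mean = state[f"{b.name}.running_mean"].copy()
                b.running_var = state[f"{b.name}.running_var"].copy()

    def sync_spec(self) -> None:
        """Copy current weights into the spec's parameter container."""
        self.spec.params = self.state_dict()

    # -- forward/backward -------------------------------------------------
    def _check_dims(self, h: int, w: int) -> None:
        if self.spec.topology == "encoder-decoder":
            d = 2 ** self.spec.levels
            if h % d or w % d:
                raise ValueError(
                    f"input {h}x{w} not divisible by 2^L = {d}, required by "
                    f"the {self.spec.levels}-level encoder-decoder")

    def forward_batch(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """NHWC batch through the core subnet plus the residual link."""
        self._check_dims(x.shape[1], x.shape[2])
        out = self.core.forward(x.astype(np.float32, copy=False), training)
        if self.spec.residual_mode:
            out = x + out
        return out

    def backward_batch(self, dy: np.ndarray) -> None:
        # The global residual link passes dy to the subnet unchanged; the
        # gradient w.r.t. the input image is not needed.
        self.core.backward(dy.astype(np.float32, copy=False))

    def _bn_modules(self):
        out = []

        def rec(mod):
            for m in getattr(mod, "modules", []):
                if isinstance(m, nn.BatchNorm2d):
                    out.append(m)
                rec(m)

        if isinstance(self.core, _UNetCore):
            for s in [*self.core.enc, *self.core.ups, *self.core.dec,
                      self.core.final]:
                rec(s)
        else:
            rec(self.core)
        return out

    def predict(self, y: np.ndarray) -> np.ndarray:
        """Post-process a single 2D image (inference; see class docstring
        for the normalization-statistics convention)."""
        y = np.asarray(y)
        if y.ndim != 2:
            raise ValueError("predict expects a single 2D image")
        self._check_dims(*y.shape)
        x = y.astype(np.float32)[None, :, :, None]
        if self.inference_stats == "image":
            bns = self._bn_modules()
            for b in bns:
                b.track_running = False
            try:
                out = self.core.forward(x, training=True)[0, :, :, 0]
            finally:
                for b in bns:
                    b.track_running = True
        else:
            out = self.core.forward(x, training=False)[0, :, :, 0]
        if self.spec.residual_mode:
            return y + out.astype(y.dtype)
        return out.astype(y.dtype)


def forward(spec: NetworkSpec, y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Apply a (possibly trained) spec to an image y.

    Materializes the runtime network from the spec's parameter container
    (fresh random init if empty) and evaluates Eq-style x̄ = F(y) or
    x̄ = y + R(y) per ``spec.residual_mode``.
    """
    return Network(spec, seed=seed).predict(y)
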