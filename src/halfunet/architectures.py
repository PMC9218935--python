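"""Framework-independent network graphs and builders.

A :class:`NetworkSpec` is an ordered, acyclic graph of :class:`LayerSpec`
nodes. Builders assemble the segmentation architectures compared in this
package:

* ``half-unet`` — five encoder stages of two Ghost modules each at a
  unified channel width, additive full-scale fusion, two Ghost modules and
  a 1x1 head (0.21 M parameters at the default width).
* ``half-unet-dagger`` — the same topology with every Ghost module replaced
  by a plain 3x3 convolution block (0.41 M).
* ``half-unet-star-u`` / ``half-unet-star-d`` — channel-doubling encoders
  whose decoders unify channels by upsample+conv or by deconvolution.
* ``unet`` — the canonical 2-D U-Net baseline (31.04 M).
* ``unet3plus`` — a U-Net encoder with full-scale aggregation decoder
  layers (64 channels per scale, 320 aggregated).
* ``encoder-a`` / ``encoder-b`` / ``encoder-c`` — ablation encoders derived
  from U-Net's encoder, decoder, and full structure, each feeding the same
  full-scale aggregation head.

All spatial bookkeeping assumes square power-of-two-friendly inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .engine import ShapeError, UnsupportedConfigError

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "ArchitectureConfig",
    "build_half_unet",
    "build_half_unet_dagger",
    "build_half_unet_star",
    "build_unet",
    "build_unet3plus",
    "build_ablation_encoder",
    "build",
    "builder_names",
    "extract_last_fusion",
]


@dataclass(frozen=True)
class LayerSpec:
    """One node of a network graph.

    ``kind`` is one of: input, conv, ghost, deconv, maxpool, bilinear, add,
    concat, sigmoid. ``cfg`` holds the kind-specific shape parameters and
    ``role`` tags nodes for structural analyses (e.g. the last-fusion split)
    or marks auxiliary sinks.
    """

    name: str
    kind: str
    inputs: tuple = ()
    cfg: dict = field(default_factory=dict)
    role: str = ""


@dataclass
class NetworkSpec:
    name: str
    input_shape: tuple  # (channels, height, width)
    nodes: list = field(default_factory=list)
    output_channels: int = 1

    # -- construction -------------------------------------------------
    def add(self, name, kind, inputs=(), role="", **cfg) -> str:
        if any(n.name == name for n in self.nodes):
            raise ValueError(f"duplicate node name {name!r}")
        if isinstance(inputs, str):
            inputs = (inputs,)
        self.nodes.append(LayerSpec(name, kind, tuple(inputs), cfg, role))
        return name

    def node(self, name) -> LayerSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def output_name(self) -> str:
        return self.nodes[-1].name

    @property
    def input_names(self) -> list:
        return [n.name for n in self.nodes if n.kind == "input"]

    # -- analysis -----------------------------------------------------
    def infer_shapes(self, input_shape=None) -> dict:
        """Propagate (channels, height, width) through the graph."""
        cin, h0, w0 = input_shape or self.input_shape
        shapes: dict[str, tuple] = {}
        for n in self.nodes:
            c = n.cfg
            if n.kind == "input":
                s = int(c.get("scale", 1))
                if h0 % s or w0 % s:
                    raise ShapeError(f"{n.name}: input {h0}x{w0} not divisible by {s}")
                shapes[n.name] = (int(c.get("channels", cin)), h0 // s, w0 // s)
                continue
            ins = [shapes[i] for i in n.inputs]
            if n.kind in ("conv", "ghost"):
                ci, hh, ww = ins[0]
                if ci != c["cin"]:
                    raise ShapeError(
                        f"{n.name}: expected {c['cin']} channels, got {ci}"
                    )
                shapes[n.name] = (c["cout"], hh, ww)
            elif n.kind == "deconv":
                ci, hh, ww = ins[0]
                if ci != c["cin"]:
                    raise ShapeError(
                        f"{n.name}: expected {c['cin']} channels, got {ci}"
                    )
                k = c["k"]
                shapes[n.name] = (c["cout"], hh * k, ww * k)
            elif n.kind == "maxpool":
                ci, hh, ww = ins[0]
                if hh % 2 or ww % 2:
                    raise ShapeError(f"{n.name}: {hh}x{ww} not divisible by 2")
                shapes[n.name] = (ci, hh // 2, ww // 2)
            elif n.kind == "bilinear":
                ci, hh, ww = ins[0]
                f = int(c["factor"])
                shapes[n.name] = (ci, hh * f, ww * f)
            elif n.kind == "add":
                if len(set(ins)) != 1:
                    raise ShapeError(f"{n.name}: additive fusion of shapes {ins}")
                shapes[n.name] = ins[0]
            elif n.kind == "concat":
                hw = {(s[1], s[2]) for s in ins}
                if len(hw) != 1:
                    raise ShapeError(f"{n.name}: concat of spatial sizes {hw}")
                shapes[n.name] = (sum(s[0] for s in ins), ins[0][1], ins[0][2])
            elif n.kind == "sigmoid":
                shapes[n.name] = ins[0]
            else:
                raise UnsupportedConfigError(f"unknown layer kind {n.kind!r}")
        return shapes

    def validate(self) -> None:
        """Check the graph is well-formed: unique names, edges point to
        earlier nodes (hence acyclic), shapes propagate, and there is
        exactly one network output (non-auxiliary sink)."""
        seen: set[str] = set()
        for n in self.nodes:
            for i in n.inputs:
                if i not in seen:
                    raise ValueError(f"{n.name}: input {i!r} not defined earlier")
            seen.add(n.name)
        self.infer_shapes()
        consumed = {i for n in self.nodes for i in n.inputs}
        sinks = [n for n in self.nodes if n.name not in consumed]
        primary = [n for n in sinks if n.role != "auxiliary"]
        if len(primary) != 1 or primary[0].name != self.output_name:
            raise ValueError(
                f"{self.name}: expected the last node as single output, "
                f"got sinks {[n.name for n in primary]}"
            )


@dataclass(frozen=True)
class ArchitectureConfig:
    """Knobs shared by all builders.

    ``base_channels``/``depth`` set the unified width and number of scales;
    reduced values give faithful miniatures for exhaustive testing.
    """

    base_channels: int = 64
    depth: int = 5
    use_ghost: bool = True
    double_channels: bool = False
    decoder_upsample: str = "bilinear_add"  # bilinear_add | upsample_conv | deconv
    input_shape: tuple = (1, 128, 128)
    output_channels: int = 1

    def __post_init__(self):
        if self.depth < 2:
            raise UnsupportedConfigError("depth must be >= 2")
        if self.base_channels < 1:
            raise UnsupportedConfigError("base_channels must be >= 1")


def _conv(net, name, src, cin, cout, k=3, bn=True, relu=True, role=""):
    return net.add(
        name, "conv", src, role=role, k=k, cin=cin, cout=cout, bias=True,
        batchnorm=bn, relu=relu,
    )


def _block(net, name, src, cin, cout, ghost, role=""):
    """One encoder/decoder unit: Ghost module or plain 3x3 conv block."""
    if ghost:
        return net.add(
            name, "ghost", src, role=role, k=3, cin=cin, cout=cout, s=2, d=3,
            batchnorm=True, relu=True,
        )
    return _conv(net, name, src, cin, cout, role=role)


def _head(net, src, cin, out_channels):
    c = net.add("head", "conv", src, k=1, cin=cin, cout=out_channels,
                bias=True, batchnorm=False, relu=False)
    return net.add("out", "sigmoid", c)


# ---------------------------------------------------------------------------
# Half-UNet family


def build_half_unet(config: ArchitectureConfig | None = None) -> NetworkSpec:
    """Canonical Half-UNet: unified channels, full-scale additive fusion,
    Ghost modules (or plain convs for the dagger variant)."""
    cfg = config or ArchitectureConfig()
    c = cfg.base_channels
    cin0 = cfg.input_shape[0]
    name = "half-unet" if cfg.use_ghost else "half-unet-dagger"
    net = NetworkSpec(name, cfg.input_shape, output_channels=cfg.output_channels)
    net.add("in", "input", channels=cin0)
    taps = []
    src = "in"
    for i in range(1, cfg.depth + 1):
        if i > 1:
            src = net.add(f"enc{i}_pool", "maxpool", src)
        src = _block(net, f"enc{i}_b1", src, cin0 if i == 1 else c, c, cfg.use_ghost)
        src = _block(net, f"enc{i}_b2", src, c, c, cfg.use_ghost)
        taps.append(src)
    fused_in = [taps[0]]
    for i in range(2, cfg.depth + 1):
        fused_in.append(
            net.add(f"fuse_up{i}", "bilinear", taps[i - 1],
                    role="last_fusion_left", factor=2 ** (i - 1))
        )
    fused = net.add("fuse_add", "add", tuple(fused_in), role="last_fusion_left")
    d = _block(net, "dec_b1", fused, c, c, cfg.use_ghost, role="last_fusion_right")
    d = _block(net, "dec_b2", d, c, c, cfg.use_ghost)
    _head(net, d, c, cfg.output_channels)
    net.validate()
    return net


def build_half_unet_dagger(config: ArchitectureConfig | None = None) -> NetworkSpec:
    cfg = replace(config or ArchitectureConfig(), use_ghost=False)
    return build_half_unet(cfg)


def build_half_unet_star(
    config: ArchitectureConfig | None = None, fusion_strategy: str = "upsample_conv"
) -> NetworkSpec:
    """Half-UNet*† variants: no Ghost modules, channels double after each
    downsampling (64..1024), and the decoder unifies channels before the
    additive fusion either by bilinear upsampling + 3x3 conv (``_u``) or by
    deconvolution (``_d``)."""
    if fusion_strategy not in ("upsample_conv", "deconv"):
        raise UnsupportedConfigError(f"unknown fusion strategy {fusion_strategy!r}")
    cfg = config or ArchitectureConfig()
    base = cfg.base_channels
    cin0 = cfg.input_shape[0]
    suffix = "u" if fusion_strategy == "upsample_conv" else "d"
    net = NetworkSpec(f"half-unet-star-{suffix}", cfg.input_shape,
                      output_channels=cfg.output_channels)
    net.add("in", "input", channels=cin0)
    taps, widths = [], []
    src = "in"
    for i in range(1, cfg.depth + 1):
        ci = base * 2 ** (i - 1)
        prev = cin0 if i == 1 else widths[-1]
        if i > 1:
            src = net.add(f"enc{i}_pool", "maxpool", src)
        src = _conv(net, f"enc{i}_c1", src, prev, ci)
        src = _conv(net, f"enc{i}_c2", src, ci, ci)
        taps.append(src)
        widths.append(ci)
    fused_in = [taps[0]]  # stage 1 is already at base width and full size
    for i in range(2, cfg.depth + 1):
        rate = 2 ** (i - 1)
        if fusion_strategy == "upsample_conv":
            up = net.add(f"fuse_up{i}", "bilinear", taps[i - 1],
                         role="last_fusion_left", factor=rate)
            fused_in.append(
                _conv(net, f"fuse_conv{i}", up, widths[i - 1], base,
                      role="last_fusion_left")
            )
        else:
            fused_in.append(
                net.add(f"fuse_deconv{i}", "deconv", taps[i - 1],
                        role="last_fusion_left", k=rate, cin=widths[i - 1],
                        cout=base)
            )
    fused = net.add("fuse_add", "add", tuple(fused_in), role="last_fusion_left")
    d = _conv(net, "dec_c1", fused, base, base, role="last_fusion_right")
    d = _conv(net, "dec_c2", d, base, base)
    _head(net, d, base, cfg.output_channels)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# baselines


def _unet_encoder(net, cfg, cin0):
    """Contracting path shared by U-Net, UNet3+, and encoder variants A/C:
    double 3x3 conv (+BN+ReLU) per stage, 2x2 max pools, channels doubling
    from ``base_channels``."""
    taps, widths = [], []
    src = "in"
    for i in range(1, cfg.depth + 1):
        ci = cfg.base_channels * 2 ** (i - 1)
        prev = cin0 if i == 1 else widths[-1]
        if i > 1:
            src = net.add(f"enc{i}_pool", "maxpool", src)
        src = _conv(net, f"enc{i}_c1", src, prev, ci)
        src = _conv(net, f"enc{i}_c2", src, ci, ci)
        taps.append(src)
        widths.append(ci)
    return taps, widths


def build_unet(config: ArchitectureConfig | None = None) -> NetworkSpec:
    """Canonical 2-D U-Net: channel-doubling encoder, 2x2 deconvolution
    upsampling, skip concatenation, double conv per decoder stage."""
    cfg = config or ArchitectureConfig()
    cin0 = cfg.input_shape[0]
    net = NetworkSpec("unet", cfg.input_shape, output_channels=cfg.output_channels)
    net.add("in", "input", channels=cin0)
    taps, widths = _unet_encoder(net, cfg, cin0)
    src = taps[-1]
    for i in range(cfg.depth - 1, 0, -1):
        ci = widths[i - 1]
        last = i == 1
        role = "last_fusion_left" if last else ""
        up = net.add(f"dec{i}_up", "deconv", src, role=role,
                     k=2, cin=widths[i], cout=ci)
        cat = net.add(f"dec{i}_cat", "concat", (up, taps[i - 1]), role=role)
        src = _conv(net, f"dec{i}_c1", cat, 2 * ci, ci,
                    role="last_fusion_right" if last else "")
        src = _conv(net, f"dec{i}_c2", src, ci, ci)
    _head(net, src, widths[0], cfg.output_channels)
    net.validate()
    return net


def _aggregation_layer(net, prefix, taps, widths, rate, width, tag=False, role=""):
    """UNet3+-style full-scale aggregation at a given downsample rate: every
    tap is resized to the rate, unified to ``width`` channels by a 3x3 conv,
    concatenated, and mixed by one 3x3 conv at the aggregated width."""
    left = "last_fusion_left" if tag else role
    branches = []
    for j, (tap, cj) in enumerate(zip(taps, widths), start=1):
        tap_rate = 2 ** (j - 1)
        src = tap
        while tap_rate > rate:  # deeper tap: bilinear upsample
            src = net.add(f"{prefix}_up{j}", "bilinear", src, role=left,
                          factor=tap_rate // rate)
            tap_rate = rate
        while tap_rate < rate:  # shallower tap: max pool down
            src = net.add(f"{prefix}_pool{j}_{tap_rate}", "maxpool", src, role=left)
            tap_rate *= 2
        branches.append(
            _conv(net, f"{prefix}_unify{j}", src, cj, width, role=left)
        )
    cat = net.add(f"{prefix}_cat", "concat", tuple(branches), role=left)
    agg_width = width * len(taps)
    return _conv(
        net, f"{prefix}_agg", cat, agg_width, agg_width,
        role="last_fusion_right" if tag else role,
    ), agg_width


def build_unet3plus(config: ArchitectureConfig | None = None) -> NetworkSpec:
    """UNet3+ reconstruction: U-Net encoder plus one full-scale aggregation
    decoder layer per scale, each aggregating all encoder taps (the
    full-resolution layer's inputs therefore total 64+128+256+512+1024 =
    1,984 channels at the default width). Layers above full resolution are
    auxiliary (deep supervision is out of scope)."""
    cfg = config or ArchitectureConfig()
    cin0 = cfg.input_shape[0]
    net = NetworkSpec("unet3plus", cfg.input_shape, output_channels=cfg.output_channels)
    net.add("in", "input", channels=cin0)
    taps, widths = _unet_encoder(net, cfg, cin0)
    out = None
    for j in range(cfg.depth - 2, -1, -1):
        rate = 2 ** j
        last = rate == 1
        node, agg_width = _aggregation_layer(
            net, f"dec_r{rate}", taps, widths, rate, cfg.base_channels,
            tag=last, role="" if last else "auxiliary",
        )
        if last:
            out = node
    _head(net, out, cfg.base_channels * cfg.depth, cfg.output_channels)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# ablation encoders (A: U-Net encoder, B: decoder-as-encoder, C: full U-Net)


def build_ablation_encoder(
    variant: str, config: ArchitectureConfig | None = None
) -> NetworkSpec:
    cfg = config or ArchitectureConfig()
    variant = variant.upper()
    if variant not in ("A", "B", "C"):
        raise UnsupportedConfigError(f"unknown encoder variant {variant!r}")
    cin0 = cfg.input_shape[0]
    net = NetworkSpec(f"encoder-{variant.lower()}", cfg.input_shape,
                      output_channels=cfg.output_channels)
    net.add("in", "input", channels=cin0)

    if variant in ("A", "C"):
        taps, widths = _unet_encoder(net, cfg, cin0)
        if variant == "C":
            # complete U-Net as the encoder: taps become the bottleneck plus
            # each expanding-stage output (rates 16,8,4,2,1 at depth 5)
            src = taps[-1]
            c_taps, c_widths = [taps[-1]], [widths[-1]]
            for i in range(cfg.depth - 1, 0, -1):
                ci = widths[i - 1]
                up = net.add(f"dec{i}_up", "deconv", src, k=2,
                             cin=widths[i], cout=ci)
                cat = net.add(f"dec{i}_cat", "concat", (up, taps[i - 1]))
                src = _conv(net, f"dec{i}_c1", cat, 2 * ci, ci)
                src = _conv(net, f"dec{i}_c2", src, ci, ci)
                c_taps.append(src)
                c_widths.append(ci)
            # reorder shallow -> deep (rates 1,2,4,8,16)
            taps, widths = c_taps[::-1], c_widths[::-1]
    else:
        # B: the expanding path used as an encoder (best-effort
        # reconstruction): pool the input to the coarsest rate without
        # parameters, then run decoder-style stages (deconv + double conv)
        # back to full resolution, tapping every scale on the way.
        top = cfg.base_channels * 2 ** (cfg.depth - 1)
        src = "in"
        for j in range(cfg.depth - 1):
            src = net.add(f"down{j + 1}", "maxpool", src)
        src = _conv(net, "stem", src, cin0, top)
        taps, widths = [src], [top]
        for i in range(cfg.depth - 1, 0, -1):
            ci = cfg.base_channels * 2 ** (i - 1)
            up = net.add(f"up{i}", "deconv", src, k=2, cin=widths[-1], cout=ci)
            src = _conv(net, f"up{i}_c1", up, ci, ci)
            src = _conv(net, f"up{i}_c2", src, ci, ci)
            taps.append(src)
            widths.append(ci)
        taps, widths = taps[::-1], widths[::-1]

    out, agg_width = _aggregation_layer(
        net, "head_agg", taps, widths, 1, cfg.base_channels, tag=True
    )
    _head(net, out, agg_width, cfg.output_channels)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# registry


_BUILDERS = {
    "half-unet": build_half_unet,
    "half-unet-dagger": build_half_unet_dagger,
    "half-unet-star-u": lambda cfg=None: build_half_unet_star(cfg, "upsample_conv"),
    "half-unet-star-d": lambda cfg=None: build_half_unet_star(cfg, "deconv"),
    "unet": build_unet,
    "unet3plus": build_unet3plus,
    "encoder-a": lambda cfg=None: build_ablation_encoder("A", cfg),
    "encoder-b": lambda cfg=None: build_ablation_encoder("B", cfg),
    "encoder-c": lambda cfg=None: build_ablation_encoder("C", cfg),
}


def builder_names() -> list:
    return sorted(_BUILDERS)


def build(name: str, config: ArchitectureConfig | None = None) -> NetworkSpec:
    key = name.lower().replace("_", "-")
    if key not in _BUILDERS:
        raise KeyError(
            f"unknown architecture {name!r}; known: {', '.join(builder_names())}"
        )
    return _BUILDERS[key](config)


# ---------------------------------------------------------------------------
# last-fusion sub-networks


def extract_last_fusion(network: NetworkSpec):
    """Split a network's final feature-fusion stage into its fusion part
    (``left``: upsampling / deconvolution / channel-unifying convolutions
    plus the add or concat node) and its convolution part (``right``: the
    convolution that consumes the fused tensor), following the builders'
    role tags. Returns two standalone :class:`NetworkSpec` sub-networks
    whose input nodes record the channel count and downsample rate of each
    externally produced feature map."""
    left_nodes = [n for n in network.nodes if n.role == "last_fusion_left"]
    right_nodes = [n for n in network.nodes if n.role == "last_fusion_right"]
    if not left_nodes or len(right_nodes) != 1:
        raise ValueError(f"{network.name} has no tagged last-fusion stage")
    shapes = network.infer_shapes()
    full_h = network.input_shape[1]

    def _subnet(label, members):
        sub = NetworkSpec(f"{network.name}_{label}", network.input_shape)
        names = {n.name for n in members}
        external = []
        for n in members:
            for i in n.inputs:
                if i not in names and i not in external:
                    external.append(i)
        for i in external:
            c, h, _ = shapes[i]
            sub.add(f"in_{i}", "input", channels=c, scale=full_h // h)
        for n in members:
            mapped = tuple(i if i in names else f"in_{i}" for i in n.inputs)
            sub.nodes.append(LayerSpec(n.name, n.kind, mapped, dict(n.cfg)))
        return sub

    return _subnet("left", left_nodes), _subnet("right", right_nodes)
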