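"""Layer-chain specification and valid-convolution shape algebra.

The network architecture is data, not code: a :class:`TopologySpec` lists
the layers, and :func:`trace_shapes` folds the output-shape recurrence

    h' = floor((h - f + s) / s),    w' = floor((w - f + s) / s)

over them, yielding the full feature-map trace before any weights exist.
Convolutions are "valid" (no padding) with square ``f x f`` kernels; average
pooling uses the same recurrence and preserves depth.  The floor is required:
a 43-row map pooled with f=2, s=2 must give 21 rows, not 21.5.

The reference nine-layer classifier (:func:`build_reference_topology`) is five
convolutions, an average pooling, a sixth convolution, a second pooling, and
a softmax fully-connected readout; every convolution is followed by batch
normalization and ReLU.  On a 63 x 1000 input its trace runs
59x996x6, 55x992x6, 51x988x6, 47x984x6, 43x980x6, 21x490x6, 17x486x6,
8x243x6, and a 2-logit output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ShapeError

CONV = "convolution"
POOL = "average_pool"
DENSE = "fully_connected"


@dataclass(frozen=True)
class FeatureMapShape:
    """Height (channel axis) x width (time axis) x depth (filter axis)."""

    h: int
    w: int
    l: int = 1

    def __post_init__(self):
        if self.h < 1 or self.w < 1 or self.l < 1:
            raise ShapeError(f"feature map dimensions must be >= 1, got {self}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.h, self.w, self.l)

    @property
    def size(self) -> int:
        return self.h * self.w * self.l

    def __str__(self) -> str:
        return f"{self.h} x {self.w} x {self.l}"


@dataclass(frozen=True)
class LayerSpec:
    """One layer: a convolution, an average pooling, or the dense readout.

    ``f`` is the (square) kernel or window size, ``s`` the stride,
    ``filters`` the number of kernels (convolution only).  ``post_ops`` are
    applied in order after the linear map; ``activation`` applies to the
    dense readout.
    """

    kind: str
    f: int = 1
    s: int = 1
    filters: int | None = None
    post_ops: tuple[str, ...] = ()
    activation: str = "none"

    def __post_init__(self):
        if self.kind not in (CONV, POOL, DENSE):
            raise ShapeError(f"unknown layer kind {self.kind!r}")
        if self.kind != DENSE and (self.f < 1 or self.s < 1):
            raise ShapeError("filter size and stride must be >= 1")
        if self.kind == CONV and (self.filters is None or self.filters < 1):
            raise ShapeError("convolution layers need filters >= 1")
        for op in self.post_ops:
            if op not in ("batch_norm", "relu"):
                raise ShapeError(f"unknown post-op {op!r}")
        if self.activation not in ("softmax", "none"):
            raise ShapeError(f"unknown activation {self.activation!r}")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind != DENSE:
            d["f"] = self.f
            d["s"] = self.s
        if self.kind == CONV:
            d["filters"] = self.filters
        if self.post_ops:
            d["post_ops"] = list(self.post_ops)
        if self.activation != "none":
            d["activation"] = self.activation
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSpec":
        return cls(
            kind=d["kind"],
            f=d.get("f", 1),
            s=d.get("s", 1),
            filters=d.get("filters"),
            post_ops=tuple(d.get("post_ops", ())),
            activation=d.get("activation", "none"),
        )


def conv_output_shape(
    shape: FeatureMapShape, f: int, s: int, filters: int
) -> FeatureMapShape:
    """Valid-convolution output shape: floor((dim - f + s) / s), depth=filters."""
    if shape.h < f or shape.w < f:
        raise ShapeError(
            f"input {shape} smaller than {f} x {f} kernel"
        )
    return FeatureMapShape(
        h=(shape.h - f + s) // s,
        w=(shape.w - f + s) // s,
        l=filters,
    )


def pool_output_shape(shape: FeatureMapShape, f: int, s: int) -> FeatureMapShape:
    """Average-pooling output shape: same recurrence, depth preserved."""
    if shape.h < f or shape.w < f:
        raise ShapeError(f"input {shape} smaller than {f} x {f} pooling window")
    return FeatureMapShape(
        h=(shape.h - f + s) // s,
        w=(shape.w - f + s) // s,
        l=shape.l,
    )


@dataclass(frozen=True)
class TopologySpec:
    """An input shape, an ordered layer list, and the number of classes."""

    input_shape: FeatureMapShape
    layers: tuple[LayerSpec, ...]
    num_classes: int = 2

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.num_classes < 2:
            raise ShapeError("need at least two classes")
        if not self.layers or self.layers[-1].kind != DENSE:
            raise ShapeError("final layer must be fully connected")
        if self.layers[-1].activation != "softmax":
            raise ShapeError("final layer must use softmax")
        trace_shapes(self)  # validates positivity at every layer

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def flattened_size(self) -> int:
        """Number of elements entering the fully connected readout."""
        return trace_shapes(self)[-2].size if self.n_layers > 1 \
            else self.input_shape.size

    def parameter_count(self) -> int:
        """Learnable parameter count: kernels+biases, batch-norm gains/offsets,
        and the dense weight matrix.  A pure function of the spec."""
        count = 0
        shape = self.input_shape
        for layer in self.layers:
            if layer.kind == CONV:
                count += layer.filters * (shape.l * layer.f * layer.f) + layer.filters
                if "batch_norm" in layer.post_ops:
                    count += 2 * layer.filters
                shape = conv_output_shape(shape, layer.f, layer.s, layer.filters)
            elif layer.kind == POOL:
                shape = pool_output_shape(shape, layer.f, layer.s)
            else:
                count += shape.size * self.num_classes + self.num_classes
                shape = FeatureMapShape(1, 1, self.num_classes)
        return count

    def to_dict(self) -> dict:
        return {
            "input_shape": list(self.input_shape.as_tuple()),
            "num_classes": self.num_classes,
            "layers": [layer.to_dict() for layer in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TopologySpec":
        h, w, l = d["input_shape"]
        return cls(
            input_shape=FeatureMapShape(h, w, l),
            layers=tuple(LayerSpec.from_dict(x) for x in d["layers"]),
            num_classes=d.get("num_classes", 2),
        )


def save_topology(spec: TopologySpec, path) -> None:
    """Write a topology as a YAML layer list (the architecture is data)."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def load_topology(path) -> TopologySpec:
    import yaml

    with open(path) as fh:
        return TopologySpec.from_dict(yaml.safe_load(fh))


def trace_shapes(spec: TopologySpec) -> list[FeatureMapShape]:
    """Fold the shape recurrence over the layer list, one shape per layer.

    Raises :class:`ShapeError` naming the layer index if any layer would
    produce a nonpositive dimension.
    """
    shapes: list[FeatureMapShape] = []
    shape = spec.input_shape
    for i, layer in enumerate(spec.layers):
        try:
            if layer.kind == CONV:
                shape = conv_output_shape(shape, layer.f, layer.s, layer.filters)
            elif layer.kind == POOL:
                shape = pool_output_shape(shape, layer.f, layer.s)
            else:
                shape = FeatureMapShape(1, 1, spec.num_classes)
        except ShapeError as exc:
            raise ShapeError(f"layer {i} ({layer.kind}): {exc}") from exc
        shapes.append(shape)
    return shapes


def _conv(filters: int = 6, f: int = 5) -> LayerSpec:
    return LayerSpec(kind=CONV, f=f, s=1, filters=filters,
                     post_ops=("batch_norm", "relu"))


def _pool() -> LayerSpec:
    return LayerSpec(kind=POOL, f=2, s=2)


def build_reference_topology() -> TopologySpec:
    """The reference nine-layer classifier for 63 x 1000 one-second segments."""
    return TopologySpec(
        input_shape=FeatureMapShape(63, 1000, 1),
        layers=(
            _conv(), _conv(), _conv(), _conv(), _conv(),
            _pool(),
            _conv(),
            _pool(),
            LayerSpec(kind=DENSE, activation="softmax"),
        ),
        num_classes=2,
    )


def build_compact_topology(
    input_shape: tuple[int, int], filters: int = 3, num_classes: int = 2
) -> TopologySpec:
    """A reduced variant of the reference topology for small inputs.

    Mirrors the conv-stack / pool / conv / pool / dense design but with two
    5x5 convolutions, a 3x3 final convolution, and ``filters`` kernels per
    layer, so it fits desk-scale synthetic segments (e.g. 19 channels at
    128 Hz).  Raises :class:`ShapeError` if the input is still too small.
    """
    h, w = input_shape
    return TopologySpec(
        input_shape=FeatureMapShape(h, w, 1),
        layers=(
            _conv(filters), _conv(filters),
            _pool(),
            _conv(filters, f=3),
            _pool(),
            LayerSpec(kind=DENSE, activation="softmax"),
        ),
        num_classes=num_classes,
    )


def format_trace(spec: TopologySpec) -> str:
    """Human-readable layer-by-layer shape trace."""
    lines = [f"input: {spec.input_shape}"]
    for i, (layer, shape) in enumerate(zip(spec.layers, trace_shapes(spec)), 1):
        extra = ""
        if layer.kind == CONV:
            extra = f" f={layer.f} s={layer.s} filters={layer.filters}"
        elif layer.kind == POOL:
            extra = f" f={layer.f} s={layer.s}"
        lines.append(f"layer {i} ({layer.kind}{extra}): {shape}")
    return "\n".join(lines)
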