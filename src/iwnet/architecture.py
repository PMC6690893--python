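"""Two-block encoder--decoder segmentation network.

The model is a pair of compact volumetric auto-encoders.  The first block
maps the intensity cube to an initial soft segmentation.  The second block
consumes the channel concatenation ``[image, initial prediction, M]`` --
with ``M`` the two-point attraction map -- and outputs the corrected
segmentation; through its skip connections the guidance map reaches the
final layers directly.  Feeding ``M`` at the second block's input (rather
than only in the decoder) lets every weight of the correction block react
to the user's points.

Each encoder level applies a 3x3x3 conv + batch norm + ReLU followed by a
stride-2 conv of the same kind; the bottleneck applies two convs; each
decoder level applies 2x nearest-neighbour upsampling, a conv, a skip
concatenation with the matching encoder level, and another conv; a final
biased 3x3x3 conv with a sigmoid produces the probability map.  With the
default stage filters ``(12, 24, 68, 110)`` and convolution biases omitted
under batch norm, the first block has exactly 1,592,093 trainable
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .field_map import weight_map
from .geometry import GridGeometry, PointPair

__all__ = [
    "BlockSpec",
    "UNetBlock",
    "IWNetModel",
    "build_first_block",
    "build_iwnet",
    "predict_automatic",
    "predict_guided",
    "count_parameters",
]

#: Stage filter counts of the reference configuration.
DEFAULT_FILTERS: Tuple[int, ...] = (12, 24, 68, 110)


@dataclass(frozen=True)
class BlockSpec:
    """Structural description of one segmentation block.

    ``stage_filters`` lists the channel width at each resolution level, the
    last entry being the bottleneck width; the number of stride-2 halvings is
    ``len(stage_filters) - 1``.  Convolutions followed by batch normalization
    carry no bias; the sigmoid output head does.
    """

    stage_filters: Tuple[int, ...] = DEFAULT_FILTERS
    input_channels: int = 1
    n_bottleneck: int = 2

    def __post_init__(self):
        object.__setattr__(self, "stage_filters", tuple(int(f) for f in self.stage_filters))
        if len(self.stage_filters) < 2 or any(f < 1 for f in self.stage_filters):
            raise ValueError("stage_filters must be >= 2 positive entries")
        if self.input_channels < 1:
            raise ValueError("input_channels must be positive")

    @property
    def depth(self) -> int:
        return len(self.stage_filters) - 1

    def validate_shape(self, shape) -> None:
        f = 2 ** self.depth
        if any(int(s) % f for s in shape):
            raise ValueError(
                f"spatial shape {tuple(shape)} not divisible by the "
                f"downsampling factor {f}"
            )


class _ConvBNReLU:
    def __init__(self, cin, cout, stride, rng):
        self.conv = nn.Conv3d(cin, cout, stride=stride, bias=False, rng=rng)
        self.bn = nn.BatchNorm3d(cout)
        self.relu = nn.ReLU()
        self.layers = [self.conv, self.bn, self.relu]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy, need_dx: bool = True):
        dy = self.bn.backward(self.relu.backward(dy))
        return self.conv.backward(dy, need_dx=need_dx)


class UNetBlock:
    """One encoder--decoder block with skip connections by concatenation."""

    def __init__(self, spec: BlockSpec, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        fs = spec.stage_filters
        L = spec.depth
        self.enc = []
        self.down = []
        c = spec.input_channels
        for i in range(L):
            self.enc.append(_ConvBNReLU(c, fs[i], 1, rng))
            self.down.append(_ConvBNReLU(fs[i], fs[i + 1], 2, rng))
            c = fs[i + 1]
        self.bottleneck = [_ConvBNReLU(fs[L], fs[L], 1, rng) for _ in range(spec.n_bottleneck)]
        self.up = [nn.NearestUpsample3d() for _ in range(L)]
        self.upconv = []
        self.dec = []
        for i in range(L - 1, -1, -1):
            self.upconv.append(_ConvBNReLU(fs[i + 1], fs[i], 1, rng))
            self.dec.append(_ConvBNReLU(2 * fs[i], fs[i], 1, rng))
        self.head = nn.Conv3d(fs[0], 1, stride=1, bias=True, rng=rng)
        # foreground-prior head bias: nodules occupy a few percent of the
        # cube, so start the sigmoid near that prior instead of at 0.5 --
        # otherwise the early overlap-loss gradients are diluted by a huge
        # union term and training can stall on inflated predictions
        self.head.b[...] = np.log(0.01 / 0.99)
        self.sigmoid = nn.Sigmoid()
        self.frozen = False

    # -- plumbing -----------------------------------------------------------
    def layers(self) -> List[nn.Layer]:
        out = []
        for unit in self.enc + self.down + self.bottleneck + self.upconv + self.dec:
            out.extend(unit.layers)
        out.extend(self.up)
        out.append(self.head)
        out.append(self.sigmoid)
        return out

    def set_training(self, training: bool):
        for l in self.layers():
            l.training = training

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 5:
            raise ValueError("expected a (batch, channels, x, y, z) tensor")
        self.spec.validate_shape(x.shape[2:])
        self.set_training(training)
        x = np.ascontiguousarray(x, dtype=np.float32)
        L = self.spec.depth
        skips = []
        c = x
        for i in range(L):
            c = self.enc[i].forward(c)
            skips.append(c)
            c = self.down[i].forward(c)
        for b in self.bottleneck:
            c = b.forward(c)
        for d, i in enumerate(range(L - 1, -1, -1)):
            c = self.up[d].forward(c)
            c = self.upconv[d].forward(c)
            c = np.concatenate([c, skips[i]], axis=1)
            c = self.dec[d].forward(c)
        self._skip_channels = [s.shape[1] for s in skips]
        y = self.sigmoid.forward(self.head.forward(c))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        L = self.spec.depth
        d = self.head.backward(self.sigmoid.backward(dy))
        skip_grads = [None] * L
        # walk decoder units in reverse of application order
        for j in range(L - 1, -1, -1):
            i = L - 1 - j  # resolution level of decoder unit j
            d = self.dec[j].backward(d)
            fi = self.spec.stage_filters[i]
            d_up, d_skip = d[:, :fi], d[:, fi:]
            skip_grads[i] = d_skip
            d = self.upconv[j].backward(d_up)
            d = self.up[j].backward(d)
        for b in reversed(self.bottleneck):
            d = b.backward(d)
        for i in range(L - 1, -1, -1):
            d = self.down[i].backward(d)
            d = d + skip_grads[i]
            # the gradient w.r.t. the raw input is never consumed
            d = self.enc[i].backward(d, need_dx=i > 0)
        return d

    # -- persistence --------------------------------------------------------
    def state_arrays(self) -> List[np.ndarray]:
        out = []
        for l in self.layers():
            out.extend(l.state())
        return out

    def load_state_arrays(self, arrays: List[np.ndarray]):
        it = iter(arrays)
        for l in self.layers():
            for s in l.state():
                s[...] = next(it)


class IWNetModel:
    """Two-block model: automatic segmentation plus interactive correction.

    The blocks share no weights; the automatic path is identical whether or
    not the second block exists.
    """

    def __init__(self, block1: UNetBlock, block2: Optional[UNetBlock] = None):
        if block1.spec.input_channels != 1:
            raise ValueError("first block must take a single-channel image")
        if block2 is not None and block2.spec.input_channels != 3:
            raise ValueError(
                "second block consumes [image, initial prediction, M] and "
                "must take 3 input channels"
            )
        self.block1 = block1
        self.block2 = block2

    @property
    def interactive(self) -> bool:
        return self.block2 is not None

    def n_params(self) -> int:
        n = self.block1.n_params()
        if self.block2 is not None:
            n += self.block2.n_params()
        return n

    def forward_guided(self, images: np.ndarray, maps: np.ndarray,
                       training: bool = False):
        """Run both blocks; block 1 always runs in inference mode here.

        Returns ``(initial, corrected)`` soft predictions.  ``training``
        affects only the second block (the first is frozen once the full
        model is being trained).
        """
        if self.block2 is None:
            raise ValueError("model has no correction block")
        initial = self.block1.forward(images, training=False)
        x2 = np.concatenate([images, initial, maps], axis=1).astype(np.float32)
        corrected = self.block2.forward(x2, training=training)
        return initial, corrected

    def save(self, path):
        """Write weights (npz) plus a JSON sidecar describing the specs."""
        import os

        arrays = {f"b1_{i}": a for i, a in enumerate(self.block1.state_arrays())}
        meta = {
            "block1": {"stage_filters": list(self.block1.spec.stage_filters),
                       "input_channels": self.block1.spec.input_channels,
                       "n_bottleneck": self.block1.spec.n_bottleneck},
            "n_params": self.n_params(),
        }
        if self.block2 is not None:
            arrays.update({f"b2_{i}": a for i, a in enumerate(self.block2.state_arrays())})
            meta["block2"] = {"stage_filters": list(self.block2.spec.stage_filters),
                              "input_channels": self.block2.spec.input_channels,
                              "n_bottleneck": self.block2.spec.n_bottleneck}
        np.savez(path, **arrays)
        base = str(path)
        if base.endswith(".npz"):
            base = base[:-4]
        with open(base + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "IWNetModel":
        base = str(path)
        if base.endswith(".npz"):
            base = base[:-4]
        with open(base + ".json") as fh:
            meta = json.load(fh)
        data = np.load(base + ".npz")

        def rebuild(key, spec_meta):
            spec = BlockSpec(tuple(spec_meta["stage_filters"]),
                             spec_meta["input_channels"], spec_meta["n_bottleneck"])
            block = UNetBlock(spec)
            arrays = [data[f"{key}_{i}"] for i in range(len(block.state_arrays()))]
            block.load_state_arrays(arrays)
            return block

        block1 = rebuild("b1", meta["block1"])
        block2 = rebuild("b2", meta["block2"]) if "block2" in meta else None
        return cls(block1, block2)


# -- module-level operation surface ----------------------------------------

def build_first_block(spec: Optional[BlockSpec] = None,
                      seed: int = 0) -> IWNetModel:
    """Build the automatic-segmentation block alone."""
    spec = spec or BlockSpec()
    rng = np.random.default_rng(seed)
    return IWNetModel(UNetBlock(spec, rng))


def build_iwnet(spec1: Optional[BlockSpec] = None,
                spec2: Optional[BlockSpec] = None,
                seed: int = 0) -> IWNetModel:
    """Build the full two-block model."""
    spec1 = spec1 or BlockSpec()
    spec2 = spec2 or BlockSpec(stage_filters=spec1.stage_filters, input_channels=3,
                               n_bottleneck=spec1.n_bottleneck)
    if spec2.input_channels != 3:
        raise ValueError("second block spec must declare 3 input channels")
    rng = np.random.default_rng(seed)
    return IWNetModel(UNetBlock(spec1, rng), UNetBlock(spec2, rng))


def _validate_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[None]
    if image.ndim != 4:
        raise ValueError("image must be one cube or a batch of cubes")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError("image must be normalized to [0, 1]")
    return image


def predict_automatic(model: IWNetModel, image: np.ndarray) -> np.ndarray:
    """First-block soft prediction; the correction block is not consulted."""
    image = _validate_image(image)
    out = model.block1.forward(image[:, None], training=False)
    return out[:, 0] if out.shape[0] > 1 else out[0, 0]


def predict_guided(model: IWNetModel, image: np.ndarray,
                   points: Optional[PointPair], p: float = 0.44):
    """Run the interactive path: build ``M`` from the points, run both blocks.

    Returns ``(initial, corrected)``.  With no points the map is identically
    zero and a warning is issued (automatic fallback semantics).
    """
    import warnings

    image = _validate_image(image)
    shape = image.shape[1:]
    geometry = GridGeometry(shape)
    if points is None:
        warnings.warn("no interaction points given; using a zero weight map",
                      RuntimeWarning, stacklevel=2)
    m = weight_map(points, p, geometry).values.astype(np.float32)
    maps = np.broadcast_to(m[None, None], (image.shape[0], 1) + shape)
    initial, corrected = model.forward_guided(image[:, None], maps, training=False)
    if image.shape[0] == 1:
        return initial[0, 0], corrected[0, 0]
    return initial[:, 0], corrected[:, 0]


def count_parameters(model) -> int:
    """Total trainable parameters: conv kernels and biases, BN scale/shift."""
    if isinstance(model, (IWNetModel, UNetBlock)):
        return model.n_params()
    if isinstance(model, nn.Layer):
        return model.n_params()
    raise TypeError(f"cannot count parameters of {type(model)!r}")
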