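"""Slice-wise U-net segmentation model with whole-cube prediction.

The network is the classic 4-level encoder/decoder U-net with skip
connections, batch normalisation and a single-channel sigmoid output.  Its
parameter names follow the public brain-MRI U-net of Buda et al.
(``encoder1.enc1conv1.weight`` ... ``conv.bias``), so a state dict of that
model exported to ``.npz`` loads name-for-name into a ``base_width=32``
build — the transfer-learning entry point.  Narrower models (e.g.
``base_width=8``) use the same topology with seeded He initialisation.

Input contract: 3-channel square slices (grayscale replicated to 3 channels
to satisfy the pretrained input layer).  Models built with a fixed
``input_size`` resize every slice to that size (256 for the pretrained
layout); ``input_size=None`` builds a fully-convolutional model that runs at
native slice resolution (padded to a multiple of 16).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn

#: Pointer to the public pretrained weights (PyTorch hub: mateuszbuda/brain-segmentation-pytorch,
#: model "unet", init_features=32).  Export its ``state_dict()`` tensors to a
#: ``.npz`` (same key names) to use with :func:`load_pretrained`.
PRETRAINED_POINTER = "https://github.com/mateuszbuda/brain-segmentation-pytorch"

PRETRAINED_BASE_WIDTH = 32
PRETRAINED_INPUT_SIZE = 256


class _ConvBlock:
    """(conv3x3 -> BN -> ReLU) x 2, the repeated U-net unit."""

    def __init__(self, prefix: str, short: str, in_ch: int, out_ch: int,
                 rng: np.random.Generator):
        self.names = {
            "conv1": f"{prefix}.{short}conv1",
            "norm1": f"{prefix}.{short}norm1",
            "conv2": f"{prefix}.{short}conv2",
            "norm2": f"{prefix}.{short}norm2",
        }
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, 1, bias=False, rng=rng)
        self.norm1 = nn.BatchNorm2d(out_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, 1, bias=False, rng=rng)
        self.norm2 = nn.BatchNorm2d(out_ch)
        self.relu2 = nn.ReLU()

    def forward(self, x, training=False):
        x = self.relu1.forward(self.norm1.forward(
            self.conv1.forward(x, training), training), training)
        return self.relu2.forward(self.norm2.forward(
            self.conv2.forward(x, training), training), training)

    def backward(self, dout):
        dout = self.conv2.backward(self.norm2.backward(self.relu2.backward(dout)))
        return self.conv1.backward(self.norm1.backward(self.relu1.backward(dout)))

    def tensors(self):
        yield self.names["conv1"] + ".weight", self.conv1, "weight", "param"
        for key, layer in (("norm1", self.norm1), ("norm2", self.norm2)):
            yield self.names[key] + ".weight", layer, "weight", "param"
            yield self.names[key] + ".bias", layer, "bias", "param"
            yield self.names[key] + ".running_mean", layer, "running_mean", "buffer"
            yield self.names[key] + ".running_var", layer, "running_var", "buffer"
            if key == "norm1":
                yield self.names["conv2"] + ".weight", self.conv2, "weight", "param"


class UNet:
    """4-level U-net; see module docstring for the layout contract."""

    def __init__(self, base_width: int = 32, input_size: int | None = 256, seed: int = 0):
        if base_width < 4:
            raise ValueError("base_width must be >= 4")
        self.base_width = base_width
        self.input_size = input_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        f = base_width
        self.encoders = [
            _ConvBlock(f"encoder{i}", f"enc{i}", cin, cout, rng)
            for i, (cin, cout) in enumerate(
                [(3, f), (f, 2 * f), (2 * f, 4 * f), (4 * f, 8 * f)], start=1)
        ]
        self.pools = [nn.MaxPool2d() for _ in range(4)]
        self.bottleneck = _ConvBlock("bottleneck", "bottleneck", 8 * f, 16 * f, rng)
        self.upconvs = {i: nn.ConvTranspose2d(2 ** i * f, 2 ** (i - 1) * f, rng)
                        for i in (4, 3, 2, 1)}
        self.decoders = {i: _ConvBlock(f"decoder{i}", f"dec{i}",
                                       2 ** i * f, 2 ** (i - 1) * f, rng)
                         for i in (4, 3, 2, 1)}
        self.final_conv = nn.Conv2d(f, 1, 1, 0, bias=True, rng=rng)
        # start near "no fluid": the foreground is rare, so a negative output
        # bias puts the initial sigmoid in a well-scaled gradient regime
        self.final_conv.params["bias"][:] = -2.0
        self._prob: np.ndarray | None = None

    # -- parameter bookkeeping -------------------------------------------------

    def _tensor_entries(self):
        for enc in self.encoders:
            yield from enc.tensors()
        yield from self.bottleneck.tensors()
        for i in (4, 3, 2, 1):
            up = self.upconvs[i]
            yield f"upconv{i}.weight", up, "weight", "param"
            yield f"upconv{i}.bias", up, "bias", "param"
            yield from self.decoders[i].tensors()
        yield "conv.weight", self.final_conv, "weight", "param"
        yield "conv.bias", self.final_conv, "bias", "param"

    def state_dict(self) -> dict[str, np.ndarray]:
        """All tensors (parameters and running statistics) by canonical name."""
        out = {}
        for name, layer, key, kind in self._tensor_entries():
            store = layer.params if kind == "param" else layer.buffers
            out[name] = store[key]
        return out

    def parameters(self) -> dict[str, np.ndarray]:
        """Trainable tensors only (running statistics excluded)."""
        return {name: (layer.params[key])
                for name, layer, key, kind in self._tensor_entries() if kind == "param"}

    def gradients(self) -> dict[str, np.ndarray]:
        return {name: layer.grads[key]
                for name, layer, key, kind in self._tensor_entries() if kind == "param"}

    def load_state_dict(self, tensors: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        for name, value in tensors.items():
            if name not in own:
                raise KeyError(f"unknown tensor {name!r}")
            if own[name].shape != value.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: model {own[name].shape}, "
                    f"given {value.shape}")
            own[name][...] = value

    # -- forward / backward ----------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Probability maps for a (N, 3, H, W) float batch; H, W divisible by 16."""
        x = np.ascontiguousarray(x, dtype=nn._F32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("spatial size must be divisible by 16; pad first")
        skips = []
        for enc, pool in zip(self.encoders, self.pools):
            x = enc.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        for i in (4, 3, 2, 1):
            x = self.upconvs[i].forward(x, training)
            x = np.concatenate([x, skips[i - 1]], axis=1)
            x = self.decoders[i].forward(x, training)
        logits = self.final_conv.forward(x, training)
        prob = nn.sigmoid(logits)
        if training:
            self._prob = prob
        return prob[:, 0]

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate d(loss)/d(prob) from a training-mode forward pass."""
        prob, self._prob = self._prob, None
        if prob is None:
            raise RuntimeError("backward() requires a training=True forward pass")
        dlogits = (dprob[:, None] * prob * (1.0 - prob)).astype(prob.dtype)
        dx = self.final_conv.backward(dlogits)
        dskips = {}
        for i in (1, 2, 3, 4):
            dx = self.decoders[i].backward(dx)
            half = dx.shape[1] // 2
            dskips[i] = dx[:, half:]
            dx = self.upconvs[i].backward(np.ascontiguousarray(dx[:, :half]))
        dx = self.bottleneck.backward(dx)
        for i in (4, 3, 2, 1):
            dx = self.pools[i - 1].backward(dx)
            dx = dx + dskips[i]
            dx = self.encoders[i - 1].backward(dx)


def build_unet(base_width: int = 32, input_size: int | None = None,
               seed: int = 0) -> UNet:
    """Build a U-net; ``base_width=32`` matches the public pretrained layout.

    ``input_size`` defaults to 256 for the pretrained-compatible width and to
    native-resolution (fully-convolutional) operation otherwise.
    """
    if input_size is None and base_width == PRETRAINED_BASE_WIDTH:
        input_size = PRETRAINED_INPUT_SIZE
    return UNet(base_width=base_width, input_size=input_size, seed=seed)


def load_pretrained(model: UNet, weights_source: str | Path) -> dict[str, list[str]]:
    """Load pretrained tensors (a ``.npz`` of the public state dict) into ``model``.

    Every file tensor whose name matches a model tensor is copied; a shape
    mismatch on any matching name is an error naming the tensor.  Returns a
    report ``{"matched": [...], "missing_in_file": [...], "unused_in_file": [...]}``.
    """
    with np.load(weights_source) as data:
        file_tensors = {k: np.asarray(data[k]) for k in data.files}
    own = model.state_dict()
    matched, unused = [], []
    mismatched = []
    for name, value in file_tensors.items():
        if name.endswith("num_batches_tracked"):
            continue
        if name in own:
            if own[name].shape != tuple(value.shape):
                mismatched.append(f"{name}: model {own[name].shape} vs file {tuple(value.shape)}")
            else:
                matched.append(name)
        else:
            unused.append(name)
    if mismatched:
        raise ValueError(
            "pretrained weight shape mismatch (wrong base_width?): "
            + "; ".join(mismatched))
    for name in matched:
        own[name][...] = file_tensors[name]
    missing = [n for n in own if n not in file_tensors]
    return {"matched": matched, "missing_in_file": missing, "unused_in_file": unused}


def save_model(model: UNet, path: str | Path) -> Path:
    """Serialize a model checkpoint (tensors + architecture meta) to ``.npz``."""
    path = Path(path)
    meta = {"base_width": model.base_width, "input_size": model.input_size,
            "seed": model.seed}
    np.savez(path, __meta__=json.dumps(meta), **model.state_dict())
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        tensors = {k: np.asarray(data[k]) for k in data.files if k != "__meta__"}
    input_size = meta["input_size"]
    model = UNet(base_width=meta["base_width"],
                 input_size=int(input_size) if input_size is not None else None,
                 seed=meta["seed"])
    model.load_state_dict(tensors)
    return model


# -- slice preparation ---------------------------------------------------------

def resize2d(image: np.ndarray, shape: tuple[int, int], order: int = 1) -> np.ndarray:
    """Bilinear (order=1) or nearest (order=0) resize preserving value range."""
    if tuple(image.shape) == tuple(shape):
        return np.asarray(image, dtype=np.float32)
    out = _sk_resize(np.asarray(image, dtype=np.float32), shape, order=order,
                     preserve_range=True, anti_aliasing=False)
    return out.astype(np.float32)


def _pad16(h: int, w: int) -> tuple[int, int]:
    return (-h) % 16, (-w) % 16


def prepare_batch(slices: np.ndarray, input_size: int | None) -> tuple[np.ndarray, tuple[int, int]]:
    """Normalize [0,255] grayscale slices to a (N, 3, H', W') float batch.

    Intensities are divided by the fixed constant 255 (not per-slice min-max)
    so inter-slice brightness relations are preserved, then replicated to 3
    channels.  Returns the batch and the native (H, W) for un-resizing.
    """
    arr = np.asarray(slices, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    native = arr.shape[1:]
    if input_size is not None:
        arr = np.stack([resize2d(s, (input_size, input_size)) for s in arr])
    else:
        ph, pw = _pad16(*arr.shape[1:])
        if ph or pw:
            arr = np.pad(arr, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    arr = arr / np.float32(255.0)
    return np.repeat(arr[:, None], 3, axis=1), native


def predict_volume(model: UNet, cube: np.ndarray, threshold: float = 0.5,
                   batch_size: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Segment a whole cube slice-by-slice.

    Each slice is normalized, replicated to 3 channels, resized to the
    model's input size (or padded when fully-convolutional), passed through
    the network in inference mode, and the probability map is resized back to
    native resolution.  Returns ``(probabilities, mask)`` with the cube's
    geometry; ``mask = probabilities >= threshold``.
    """
    cube = np.asarray(cube)
    if cube.ndim != 3 or cube.size == 0:
        raise ValueError(f"expected a non-empty (z, y, x) cube, got shape {cube.shape}")
    nz, h, w = cube.shape
    probs = np.empty((nz, h, w), dtype=np.float32)
    for start in range(0, nz, batch_size):
        chunk = cube[start:start + batch_size]
        x, native = prepare_batch(chunk, model.input_size)
        p = model.forward(x, training=False)
        if model.input_size is not None:
            p = np.stack([resize2d(pm, (h, w)) for pm in p])
        else:
            p = p[:, :h, :w]
        probs[start:start + len(chunk)] = p
    return probs, probs >= threshold
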