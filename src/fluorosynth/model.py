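"""Residual U-Net for SE -> DES image synthesis, in pure NumPy.

The network is a U-shaped encoder–decoder with skip connections between
matching resolutions; every convolutional block is residual (two 3x3
convolutions with an additive shortcut, a 1x1 projection bridging channel
mismatches).  Downsampling is 2x2 max-pooling, upsampling is nearest-
neighbour followed by a 1x1 channel-halving convolution before the skip
concatenation.  Convolutions are followed by instance normalization and a
leaky rectifier, and a global identity shortcut connects the input to the
output, so the convolutional path learns only the bone-suppression
residual — the component the subtraction removes.

Images enter the model in the optical-depth (line-integral) domain,
u = -ln(I / I0), min-max normalized to [0, 1] per image.  Optical depth is
the natural domain for this task: projections, the weighted subtraction
and the compositing of overlapping structures are all additive there, so
the residual the network must learn is itself an additive bone image.

Training minimizes the mean squared error between the predicted and
reference DES images with Adam, the learning rate decaying linearly from
``initial_lr`` to ``final_lr`` over the epochs.

Forward and backward passes are hand-written: convolutions run as
``sliding_window_view`` + ``tensordot`` (BLAS matmuls), and the gradient of
a convolution w.r.t. its input is the correlation with the flipped,
channel-transposed kernel.  Everything is float32 and seeded, so identical
configurations yield bit-identical weights on one machine.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .projection import RadiographImage

__all__ = [
    "ModelConfig",
    "TrainedSynthesizer",
    "build_model",
    "mse_loss",
    "linear_lr",
    "train",
    "synthesize",
    "minmax01",
    "optical_depth",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyper-parameters."""

    depth: int = 3  # number of 2x downsamplings
    base_filters: int = 8
    blocks_per_level: int = 1
    input_shape: tuple[int, int] = (64, 64)
    norm: str = "instance"  # "instance" or "none"
    global_skip: bool = True  # identity shortcut input -> output
    initial_lr: float = 0.02
    final_lr: float = 1e-4
    epochs: int = 20
    batch_size: int = 1
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if not self.initial_lr > self.final_lr > 0:
            raise ValueError("require initial_lr > final_lr > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        m = 2**self.depth
        if any(s % m for s in self.input_shape):
            raise ValueError(f"input shape must be divisible by 2^depth = {m}")


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error (1/(mn)) * sum (target - pred)^2."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError("pred and target must have the same shape")
    d = target.astype(np.float64) - pred.astype(np.float64)
    return float(np.mean(d * d))


def linear_lr(initial: float, final: float, epoch: float, total_epochs: int) -> float:
    """Linearly decayed learning rate at a (possibly fractional) epoch."""
    if total_epochs <= 1:
        return initial
    f = np.clip(epoch / (total_epochs - 1), 0.0, 1.0)
    return initial + (final - initial) * float(f)


def minmax01(img: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 1] (constant images -> 0)."""
    img = np.asarray(img, dtype=np.float32)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo == 0:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def optical_depth(intensity: np.ndarray, i0: float = 1.0) -> np.ndarray:
    """Line-integral (radiograph display) representation -ln(I / I0)."""
    from .des import LOG_FLOOR

    return -np.log(np.maximum(np.asarray(intensity, dtype=np.float64), LOG_FLOOR) / i0)


# ---------------------------------------------------------------------------
# layers


def _corr(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'Same' cross-correlation of NCHW input with (Cout, Cin, k, k) kernels."""
    k = w.shape[2]
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2))


class _Conv:
    """k x k convolution, stride 1, 'same' zero padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.dw = self.db = None
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return _corr(x, self.w) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        x = self._x
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        self.dw = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3])).astype(np.float32)
        self.db = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        w_flip = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        return _corr(dy, w_flip)

    def param_slots(self):
        return [(self, "w", "dw"), (self, "b", "db")]

    def n_parameters(self) -> int:
        return self.w.size + self.b.size


class _InstanceNorm:
    """Per-sample, per-channel normalization over (H, W) with affine params.

    Keeps activations O(1) at any weight scale, which is what lets Adam
    survive the large prescribed initial learning rate; inference is
    deterministic and batch-independent (no running statistics).
    """

    def __init__(self, c: int, eps: float = 1e-5):
        self.g = np.ones(c, dtype=np.float32)
        self.b = np.zeros(c, dtype=np.float32)
        self.eps = eps
        self.dg = self.db = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xh = xc * self._istd
        return self.g[None, :, None, None] * self._xh + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dg = (dy * self._xh).sum(axis=(0, 2, 3)).astype(np.float32)
        self.db = dy.sum(axis=(0, 2, 3)).astype(np.float32)
        dxh = dy * self.g[None, :, None, None]
        return self._istd * (
            dxh
            - dxh.mean(axis=(2, 3), keepdims=True)
            - self._xh * (dxh * self._xh).mean(axis=(2, 3), keepdims=True)
        )

    def param_slots(self):
        return [(self, "g", "dg"), (self, "b", "db")]

    def n_parameters(self) -> int:
        return self.g.size + self.b.size


class _Identity:
    def forward(self, x):
        return x

    def backward(self, dy):
        return dy

    def param_slots(self):
        return []

    def n_parameters(self) -> int:
        return 0


class _ReLU:
    """Leaky rectifier; a nonzero negative slope keeps units recoverable
    through the aggressive early phase of the prescribed lr schedule."""

    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x):
        self._m = x > 0
        return np.where(self._m, x, self.slope * x)

    def backward(self, dy):
        return dy * np.where(self._m, 1.0, self.slope).astype(dy.dtype)

    def param_slots(self):
        return []

    def n_parameters(self) -> int:
        return 0


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = np.ascontiguousarray(xr).reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, h, w = self._shape
        dz = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dz, self._idx[..., None], dy[..., None], axis=-1)
        dz = dz.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dz).reshape(n, c, h, w)


class _Upsample2:
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class _ResBlock:
    """conv-norm-relu-conv-norm plus an additive shortcut, ReLU on the sum."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, norm: str):
        def make_norm():
            return _InstanceNorm(cout) if norm == "instance" else _Identity()

        self.conv1 = _Conv(cin, cout, 3, rng)
        self.norm1 = make_norm()
        self.conv2 = _Conv(cout, cout, 3, rng)
        self.norm2 = make_norm()
        self.proj = _Conv(cin, cout, 1, rng) if cin != cout else None
        self.relu1, self.relu2 = _ReLU(), _ReLU()

    def forward(self, x):
        h = self.relu1.forward(self.norm1.forward(self.conv1.forward(x)))
        h = self.norm2.forward(self.conv2.forward(h))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.relu2.forward(h + s)

    def backward(self, dy):
        d = self.relu2.backward(dy)
        dh = self.norm2.backward(d)
        dx = self.conv1.backward(
            self.norm1.backward(self.relu1.backward(self.conv2.backward(dh)))
        )
        dx = dx + (self.proj.backward(d) if self.proj is not None else d)
        return dx

    def layers(self):
        out = [self.conv1, self.norm1, self.conv2, self.norm2]
        if self.proj is not None:
            out.append(self.proj)
        return out


class ResidualUNet:
    """Encoder–decoder with residual blocks and skip connections."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d, base, nb = config.depth, config.base_filters, config.blocks_per_level
        norm = config.norm
        ch = [base * 2**i for i in range(d + 1)]  # encoder levels + bottleneck

        def level(cin, cout):
            blocks = [_ResBlock(cin, cout, rng, norm)]
            blocks += [_ResBlock(cout, cout, rng, norm) for _ in range(nb - 1)]
            return blocks

        self.enc = [level(1 if i == 0 else ch[i - 1], ch[i]) for i in range(d)]
        self.pools = [_MaxPool2() for _ in range(d)]
        self.bottleneck = level(ch[d - 1], ch[d])
        self.ups = [_Upsample2() for _ in range(d)]
        self.upconvs = [_Conv(ch[i + 1], ch[i], 1, rng) for i in reversed(range(d))]
        self.dec = [level(2 * ch[i], ch[i]) for i in reversed(range(d))]
        self.final = _Conv(ch[0], 1, 1, rng)

    # -- plumbing ----------------------------------------------------------
    def layers(self):
        out = []
        for blocks in self.enc + [self.bottleneck] + self.dec:
            for b in blocks:
                out.extend(b.layers())
        out.extend(self.upconvs)
        out.append(self.final)
        return out

    def param_slots(self):
        return [s for layer in self.layers() for s in layer.param_slots()]

    def n_parameters(self) -> int:
        return sum(layer.n_parameters() for layer in self.layers())

    def get_weights(self) -> list[np.ndarray]:
        return [getattr(obj, attr).copy() for obj, attr, _ in self.param_slots()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (obj, attr, _), w in zip(self.param_slots(), weights, strict=True):
            cur = getattr(obj, attr)
            setattr(obj, attr, np.asarray(w, dtype=np.float32).reshape(cur.shape))

    # -- computation -------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x_in = x
        skips = []
        for blocks, pool in zip(self.enc, self.pools):
            for b in blocks:
                x = b.forward(x)
            skips.append(x)
            x = pool.forward(x)
        for b in self.bottleneck:
            x = b.forward(x)
        self._cat_ch = []
        for up, uc, blocks, skip in zip(self.ups, self.upconvs, self.dec, reversed(skips)):
            x = uc.forward(up.forward(x))
            self._cat_ch.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
            for b in blocks:
                x = b.forward(x)
        out = self.final.forward(x)
        if self.config.global_skip:
            # identity shortcut: the convolutional path models only the
            # residual (the suppressed bone component); parameter gradients
            # are unchanged, so backward() needs no counterpart
            out = out + x_in
        return out

    def backward(self, dy: np.ndarray) -> None:
        d = self.final.backward(dy)
        dskips = []
        for up, uc, blocks, cch in zip(
            reversed(self.ups), reversed(self.upconvs), reversed(self.dec), reversed(self._cat_ch)
        ):
            for b in reversed(blocks):
                d = b.backward(d)
            dskips.append(d[:, cch:])
            d = up.backward(uc.backward(d[:, :cch]))
        for b in reversed(self.bottleneck):
            d = b.backward(d)
        for blocks, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = pool.backward(d) + dskip
            for b in reversed(blocks):
                d = b.backward(d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference on (N, 1, H, W) input; deterministic."""
        return self.forward(x.astype(np.float32))


def build_model(config: ModelConfig) -> ResidualUNet:
    """Untrained residual U-Net with seeded He-normal initialization."""
    return ResidualUNet(config)


@dataclass
class TrainedSynthesizer:
    """A trained network plus its configuration and loss history."""

    net: ResidualUNet
    config: ModelConfig
    history: list[dict] = field(default_factory=list)

    def save(self, path) -> None:
        arrays = {f"w{i}": a for i, a in enumerate(self.net.get_weights())}
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with open(path, "wb") as f:
            cfg = json.dumps({"config": asdict(self.config), "history": self.history})
            f.write(len(cfg).to_bytes(8, "little"))
            f.write(cfg.encode())
            f.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "TrainedSynthesizer":
        with open(path, "rb") as f:
            n = int.from_bytes(f.read(8), "little")
            head = json.loads(f.read(n).decode())
            data = np.load(io.BytesIO(f.read()))
        cfg = head["config"]
        cfg["input_shape"] = tuple(cfg["input_shape"])
        config = ModelConfig(**cfg)
        net = build_model(config)
        net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return cls(net=net, config=config, history=head["history"])


class _Adam:
    def __init__(self, slots, beta1=0.9, beta2=0.999, eps=1e-8):
        self.slots = slots
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, a)) for o, a, _ in slots]
        self.v = [np.zeros_like(getattr(o, a)) for o, a, _ in slots]

    def step(self, lr: float) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for (obj, attr, gattr), m, v in zip(self.slots, self.m, self.v):
            p, g = getattr(obj, attr), getattr(obj, gattr)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _to_model_domain(img: RadiographImage) -> np.ndarray:
    """Radiograph -> normalized optical-depth array in [0, 1]."""
    if "log_pixels" in img.meta:
        od = -np.asarray(img.meta["log_pixels"], dtype=np.float64)
    else:
        od = optical_depth(img.pixels)
    return minmax01(od)


def _stack_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    """(SE, DES) pairs -> normalized optical-depth (N, 1, H, W) tensors."""
    xs = [_to_model_domain(p.se) for p in pairs]
    ys = [_to_model_domain(p.des) for p in pairs]
    x = np.stack(xs)[:, None].astype(np.float32)
    y = np.stack(ys)[:, None].astype(np.float32)
    return x, y


def train(net: ResidualUNet, pairs, config: ModelConfig | None = None) -> TrainedSynthesizer:
    """Adam on the MSE loss with linear learning-rate decay.

    ``pairs`` is a sequence of TrainingPair; a ``val_fraction`` split (by
    seeded shuffle) is held out and its loss recorded per epoch.  Raises on
    non-finite loss.
    """
    config = config or net.config
    if len(pairs) == 0:
        raise ValueError("training set is empty")
    x, y = _stack_pairs(pairs)
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(pairs))
    n_val = int(round(config.val_fraction * len(pairs)))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if len(train_idx) == 0:
        train_idx = idx
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    opt = _Adam(net.param_slots())
    history: list[dict] = []
    bs = config.batch_size
    for epoch in range(config.epochs):
        lr = linear_lr(config.initial_lr, config.final_lr, epoch, config.epochs)
        order = rng.permutation(len(xt))
        losses = []
        for s in range(0, len(xt), bs):
            sel = order[s : s + bs]
            xb, yb = xt[sel], yt[sel]
            pred = net.forward(xb)
            loss = mse_loss(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, step {s // bs}: {loss}"
                )
            losses.append(loss)
            net.backward((2.0 / pred.size) * (pred - yb))
            opt.step(lr)
        rec = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}
        if len(xv):
            rec["val_loss"] = _eval_loss(net, xv, yv, bs)
        history.append(rec)
    return TrainedSynthesizer(net=net, config=config, history=history)


def _eval_loss(net: ResidualUNet, x: np.ndarray, y: np.ndarray, bs: int) -> float:
    tot, n = 0.0, 0
    for s in range(0, len(x), bs):
        pred = net.predict(x[s : s + bs])
        tot += mse_loss(pred, y[s : s + bs]) * len(pred)
        n += len(pred)
    return tot / n


def _pad_to_multiple(img: np.ndarray, m: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape
    ph, pw = (-h) % m, (-w) % m
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)))
    return img, (h, w)


def synthesize(model: TrainedSynthesizer | ResidualUNet, se: RadiographImage) -> RadiographImage:
    """Predict the DES image for a single SE radiograph.

    The input is mapped to normalized optical depth, zero-padded to a shape
    the network accepts, run through the model and cropped back.  The
    returned image lives in the normalized optical-depth display domain
    (``meta["display"]``); deterministic at inference.
    """
    net = model.net if isinstance(model, TrainedSynthesizer) else model
    m = 2**net.config.depth
    x, orig = _pad_to_multiple(_to_model_domain(se), m)
    pred = net.predict(x[None, None])[0, 0]
    pred = pred[: orig[0], : orig[1]]
    meta = {k: v for k, v in se.meta.items() if k != "log_pixels"}
    meta["kind"] = "synthesized_DES"
    meta["display"] = "optical_depth_minmax"
    return RadiographImage(
        pixels=pred.astype(np.float64), pixel_spacing=se.pixel_spacing, meta=meta
    )
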