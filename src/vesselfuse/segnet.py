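"""Encoder–decoder pixel classifier, the four pixel-classification losses,
and a seeded patch-based training/prediction harness.

The network is a small U-net-family model implemented directly on NumPy:
``depth`` encoder stages of two 3x3 convolutions + ReLU followed by 2x2
max-pooling, a bottleneck, and a symmetric decoder with nearest-neighbor
upsampling and channel-concatenation skip connections, ending in a 1x1
convolution head (sigmoid for the binary losses, 2-way softmax for the
categorical ones). Gradients are hand-derived (im2col convolution) and
optimization is Adam. Everything is seeded and single-threaded-deterministic,
which is what the desk-scale tests rely on; this is a faithful miniature of
the architecture, not a benchmark-scale trainer.

Losses (pixel-mean reduction, predictions clipped to [eps, 1-eps], eps=1e-7):

* binary cross-entropy:        -[y log p + (1-y) log(1-p)]
* categorical cross-entropy:   -sum_c y_c log p_c  (2-class one-hot)
* binary focal:                -alpha (1-p)^gamma log p          for y=1
                               -(1-alpha) p^gamma log(1-p)       for y=0
* categorical focal:           -alpha_c (1-p_c)^gamma log p_c    at the true class

The focal modulator (1-p)^gamma down-weights easy pixels so training
emphasizes hard ones (thin vessels); alpha balances the vessel/background
class imbalance.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_core import BinaryMask, extract_patches, reassemble

EPS = 1e-7

LOSS_KINDS = ("binary_ce", "categorical_ce", "binary_focal", "categorical_focal")


@dataclasses.dataclass
class LossConfig:
    kind: str = "categorical_focal"
    alpha: float | tuple[float, float] = (0.75, 0.25)  # (background, vessel)
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in LOSS_KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}; expected {LOSS_KINDS}")
        if self.gamma < 0:
            raise ValueError("focusing parameter gamma must be >= 0")
        alphas = self.alpha if isinstance(self.alpha, (tuple, list)) else (self.alpha,)
        if not all(0 < a < 1 for a in alphas):
            raise ValueError("alpha entries must lie in (0, 1)")
        if self.kind == "categorical_focal" and not isinstance(self.alpha, (tuple, list)):
            # scalar alpha means the vessel-class weight; background gets 1-alpha
            self.alpha = (1.0 - float(self.alpha), float(self.alpha))

    @property
    def is_categorical(self) -> bool:
        return self.kind.startswith("categorical")


@dataclasses.dataclass
class ModelConfig:
    depth: int = 2
    base_filters: int = 8
    input_patch: int = 32
    skip_connections: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_patch % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_patch {self.input_patch} not divisible by 2^depth = {2 ** self.depth}")


@dataclasses.dataclass
class TrainState:
    seed: int = 0
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    patches_per_image: int = 200
    loss_history: list[float] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class ProbabilityMap:
    grid: np.ndarray
    channel: str = "original"  # original | thick | thin


@dataclasses.dataclass
class ProbabilityTriplet:
    p_original: ProbabilityMap
    p_thick: ProbabilityMap
    p_thin: ProbabilityMap


# ----------------------------------------------------------------- losses

def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def loss_value(y, y_hat, cfg: LossConfig) -> float:
    """Mean per-pixel loss of predicted vessel probabilities against {0,1} labels."""
    y = np.asarray(y, dtype=np.float64)
    p = _clip(np.asarray(y_hat, dtype=np.float64))
    g = cfg.gamma
    if cfg.kind == "binary_ce":
        per = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    elif cfg.kind == "binary_focal":
        a = float(cfg.alpha) if not isinstance(cfg.alpha, (tuple, list)) else float(cfg.alpha[-1])
        per = np.where(y == 1,
                       -a * (1 - p) ** g * np.log(p),
                       -(1 - a) * p ** g * np.log(1 - p))
    elif cfg.kind == "categorical_ce":
        # 2-class one-hot: p_true is p for vessels and 1-p for background
        p_true = np.where(y == 1, p, 1 - p)
        per = -np.log(p_true)
    else:  # categorical_focal
        a_bg, a_fg = cfg.alpha
        p_true = np.where(y == 1, p, 1 - p)
        a = np.where(y == 1, a_fg, a_bg)
        per = -a * (1 - p_true) ** g * np.log(p_true)
    return float(np.mean(per))


def _loss_grad_wrt_p(y: np.ndarray, p: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """d(mean loss)/dp, before the mean normalization (caller divides by n)."""
    g = cfg.gamma
    if cfg.kind == "binary_ce":
        return -(y / p) + (1 - y) / (1 - p)
    if cfg.kind == "binary_focal":
        a = float(cfg.alpha) if not isinstance(cfg.alpha, (tuple, list)) else float(cfg.alpha[-1])
        mod_pos = g * (1 - p) ** max(g - 1, 0.0) * np.log(p) if g > 0 else 0.0
        grad_pos = a * (mod_pos - (1 - p) ** g / p)
        mod_neg = g * p ** max(g - 1, 0.0) * np.log(1 - p) if g > 0 else 0.0
        grad_neg = -(1 - a) * (mod_neg - p ** g / (1 - p))
        return np.where(y == 1, grad_pos, grad_neg)
    if cfg.kind == "categorical_ce":
        return np.where(y == 1, -1.0 / p, 1.0 / (1 - p))
    # categorical_focal: chain rule through p_true = p or 1-p
    a_bg, a_fg = cfg.alpha
    p_true = np.where(y == 1, p, 1 - p)
    a = np.where(y == 1, a_fg, a_bg)
    d_ptrue = a * (g * (1 - p_true) ** max(g - 1, 0.0) * np.log(p_true)
                   - (1 - p_true) ** g / p_true) if g > 0 else -a / p_true
    return np.where(y == 1, d_ptrue, -d_ptrue)


# ------------------------------------------------------------------ layers

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    cols = np.empty((n, h, w, k * k * c), dtype=x.dtype)
    i = 0
    for di in range(k):
        for dj in range(k):
            cols[..., i * c : (i + 1) * c] = xp[:, di : di + h, dj : dj + w, :]
            i += 1
    return cols


def _col2im(dcols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    n, h, w, c = shape
    p = k // 2
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dcols.dtype)
    i = 0
    for di in range(k):
        for dj in range(k):
            dxp[:, di : di + h, dj : dj + w, :] += dcols[..., i * c : (i + 1) * c]
            i += 1
    return dxp[:, p : p + h, p : p + w, :]


class _Conv:
    """Same-padded kxk convolution with optional ReLU; He-initialized."""

    def __init__(self, rng: np.random.Generator, k: int, cin: int, cout: int, relu: bool = True):
        self.k, self.cin, self.cout, self.relu = k, cin, cout, relu
        self.w = rng.normal(0.0, np.sqrt(2.0 / (k * k * cin)), size=(k * k * cin, cout))
        self.b = np.zeros(cout)
        self._adam = [np.zeros_like(self.w), np.zeros_like(self.w),
                      np.zeros_like(self.b), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        self._cols = _im2col(x, self.k)
        z = self._cols @ self.w + self.b
        if self.relu:
            self._mask = z > 0
            z = z * self._mask
        return z

    def backward(self, dz: np.ndarray) -> np.ndarray:
        if self.relu:
            dz = dz * self._mask
        n, h, w, _ = dz.shape
        cols2 = self._cols.reshape(n * h * w, -1)
        dz2 = dz.reshape(n * h * w, -1)
        self.dw = cols2.T @ dz2
        self.db = dz2.sum(axis=0)
        return _col2im(dz @ self.w.T, self._xshape, self.k)

    def step(self, lr: float, t: int, b1: float = 0.9, b2: float = 0.999, e: float = 1e-8):
        mw, vw, mb, vb = self._adam
        for m, v, g, p in ((mw, vw, self.dw, self.w), (mb, vb, self.db, self.b)):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / (1 - b1 ** t)) / (np.sqrt(v / (1 - b2 ** t)) + e)


def _maxpool(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    flat = xr.reshape(n, h // 2, w // 2, 4, c)
    arg = flat.argmax(axis=3)
    out = np.take_along_axis(flat, arg[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return out, arg


def _maxpool_back(dout: np.ndarray, arg: np.ndarray, shape: tuple) -> np.ndarray:
    n, h, w, c = shape
    flat = np.zeros((n, h // 2, w // 2, 4, c), dtype=dout.dtype)
    np.put_along_axis(flat, arg[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
    return flat.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, h, w, c)


def _upsample(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample_back(d: np.ndarray) -> np.ndarray:
    n, h, w, c = d.shape
    return d.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class SegModel:
    """The miniature U-net: seeded construction, forward, backward, Adam step."""

    def __init__(self, mcfg: ModelConfig, lcfg: LossConfig, seed: int = 0):
        self.mcfg, self.lcfg, self.seed = mcfg, lcfg, seed
        self.channel: str | None = None
        rng = np.random.default_rng(seed)
        f, d = mcfg.base_filters, mcfg.depth
        self.enc: list[tuple[_Conv, _Conv]] = []
        cin = 1
        for i in range(d):
            cout = f * 2 ** i
            self.enc.append((_Conv(rng, 3, cin, cout), _Conv(rng, 3, cout, cout)))
            cin = cout
        self.bottleneck = (_Conv(rng, 3, cin, f * 2 ** d), _Conv(rng, 3, f * 2 ** d, f * 2 ** d))
        cin = f * 2 ** d
        self.dec: list[tuple[_Conv, _Conv]] = []
        for i in reversed(range(d)):
            cout = f * 2 ** i
            skip = cout if mcfg.skip_connections else 0
            self.dec.append((_Conv(rng, 3, cin + skip, cout), _Conv(rng, 3, cout, cout)))
            cin = cout
        self.n_out = 2 if lcfg.is_categorical else 1
        self.head = _Conv(rng, 1, cin, self.n_out, relu=False)
        self._t = 0  # Adam step counter

    def _layers(self) -> list[_Conv]:
        out = []
        for a, b in self.enc:
            out += [a, b]
        out += list(self.bottleneck)
        for a, b in self.dec:
            out += [a, b]
        return out + [self.head]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W) in [0,1] -> vessel probability (N, H, W)."""
        h = np.asarray(x, dtype=np.float64)[..., None]
        self._skips = []
        self._pool_args = []
        self._pool_shapes = []
        for a, b in self.enc:
            h = b.forward(a.forward(h))
            self._skips.append(h)
            self._pool_shapes.append(h.shape)
            h, arg = _maxpool(h)
            self._pool_args.append(arg)
        h = self.bottleneck[1].forward(self.bottleneck[0].forward(h))
        self._up_channels = []
        for (a, b), skip in zip(self.dec, reversed(self._skips)):
            h = _upsample(h)
            self._up_channels.append(h.shape[-1])
            if self.mcfg.skip_connections:
                h = np.concatenate([h, skip], axis=-1)
            h = b.forward(a.forward(h))
        z = self.head.forward(h)
        if self.n_out == 2:
            z = z - z.max(axis=-1, keepdims=True)
            ez = np.exp(z)
            self._probs = ez / ez.sum(axis=-1, keepdims=True)  # (N,H,W,2)
            return self._probs[..., 1]
        self._probs = 1.0 / (1.0 + np.exp(-z[..., 0]))
        return self._probs

    def backward(self, y: np.ndarray) -> None:
        """Backprop the configured loss for labels y (N, H, W) after forward."""
        y = np.asarray(y, dtype=np.float64)
        n_pix = y.size
        if self.n_out == 2:
            # 2-class softmax with p0 = 1 - p1: write the loss through the
            # vessel probability p1 only, then apply the softmax Jacobian
            p = self._probs
            p1 = _clip(p[..., 1])
            dLdp1 = _loss_grad_wrt_p(y, p1, self.lcfg) / n_pix
            dz = np.empty_like(p)
            dz[..., 1] = p[..., 1] * p[..., 0] * dLdp1
            dz[..., 0] = -dz[..., 1]
        else:
            p = _clip(self._probs)
            dLdp = _loss_grad_wrt_p(y, p, self.lcfg) / n_pix
            dz = (dLdp * p * (1 - p))[..., None]
        d = self.head.backward(dz)
        n_dec = len(self.dec)
        skip_grads: list[np.ndarray | None] = [None] * len(self.enc)
        for j, (a, b) in enumerate(reversed(self.dec)):
            d = a.backward(b.backward(d))
            cu = self._up_channels[n_dec - 1 - j]
            if self.mcfg.skip_connections:
                skip_grads[j] = d[..., cu:]  # gradient into encoder stage j via the skip
                d = d[..., :cu]
            d = _upsample_back(d)
        d = self.bottleneck[0].backward(self.bottleneck[1].backward(d))
        for i in reversed(range(len(self.enc))):
            d = _maxpool_back(d, self._pool_args[i], self._pool_shapes[i])
            if skip_grads[i] is not None:
                d = d + skip_grads[i]
            a, b = self.enc[i]
            d = a.backward(b.backward(d))

    def step(self, lr: float) -> None:
        self._t += 1
        for layer in self._layers():
            layer.step(lr, self._t)

    def state_checksum(self) -> float:
        return float(sum(np.abs(layer.w).sum() + np.abs(layer.b).sum()
                         for layer in self._layers()))


def build_model(mcfg: ModelConfig, lcfg: LossConfig | None = None, seed: int = 0) -> SegModel:
    """Construct a seeded model; same seed -> identical initial parameters."""
    return SegModel(mcfg, lcfg or LossConfig(), seed=seed)


# ---------------------------------------------------------------- training

def _sample_patches(rng: np.random.Generator, image: np.ndarray, target: np.ndarray,
                    fov: np.ndarray, n: int, patch: int) -> tuple[np.ndarray, np.ndarray]:
    h, w = image.shape
    if patch > h or patch > w:
        raise ValueError("patch size exceeds image size")
    half = patch // 2
    rows, cols = np.nonzero(fov)
    if len(rows) == 0:
        raise ValueError("no FOV-interior pixels available for patch sampling")
    pick = rng.integers(0, len(rows), size=n)
    xs = np.empty((n, patch, patch))
    ys = np.empty((n, patch, patch))
    for i, j in enumerate(pick):
        r, c = rows[j] - half, cols[j] - half
        r = min(max(r, 0), h - patch)
        c = min(max(c, 0), w - patch)
        xs[i] = image[r : r + patch, c : c + patch]
        ys[i] = target[r : r + patch, c : c + patch]
    return xs, ys


def train_channel(images: list[np.ndarray], targets: list[BinaryMask | np.ndarray],
                  fovs: list[BinaryMask | np.ndarray], mcfg: ModelConfig,
                  lcfg: LossConfig, tcfg: TrainState, channel: str = "original") -> SegModel:
    """Train one network on one objective channel. Fully seeded."""
    if len(images) < 1:
        raise ValueError("need at least one training image")
    model = build_model(mcfg, lcfg, seed=tcfg.seed)
    model.channel = channel
    rng = np.random.default_rng(tcfg.seed + 1)
    xs_all, ys_all = [], []
    per = max(tcfg.patches_per_image // len(images), 1)
    for img, tgt, fov in zip(images, targets, fovs):
        tgt = tgt.grid if isinstance(tgt, BinaryMask) else np.asarray(tgt)
        fovg = fov.grid if isinstance(fov, BinaryMask) else np.asarray(fov)
        x, y = _sample_patches(rng, np.asarray(img), tgt.astype(np.float64), fovg,
                               per, mcfg.input_patch)
        xs_all.append(x)
        ys_all.append(y)
    xs = np.concatenate(xs_all)
    ys = np.concatenate(ys_all)
    n = len(xs)
    for _ in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            p = model.forward(xs[idx])
            losses.append(loss_value(ys[idx], p, lcfg))
            model.backward(ys[idx])
            model.step(tcfg.learning_rate)
        tcfg.loss_history.append(float(np.mean(losses)))
    return model


def predict_map(model: SegModel, image: np.ndarray, fov: BinaryMask | np.ndarray,
                patch_size: int | None = None, stride: int | None = None) -> ProbabilityMap:
    """Patch-wise inference with overlap averaging; zero outside the FOV."""
    image = np.asarray(image, dtype=np.float64)
    fovg = fov.grid if isinstance(fov, BinaryMask) else np.asarray(fov)
    if fovg.shape != image.shape:
        raise ValueError("FOV mask shape does not match the image")
    patch_size = patch_size or model.mcfg.input_patch
    stride = stride or patch_size // 2
    pset = extract_patches(image, patch_size, stride)
    probs = []
    batch = 64
    stack = np.stack(pset.patches)
    for start in range(0, len(stack), batch):
        probs.append(model.forward(stack[start : start + batch]))
    pp = np.concatenate(probs)
    out_set = dataclasses.replace(pset, patches=[pp[i] for i in range(len(pp))])
    grid = reassemble(out_set)
    grid = np.clip(grid, 0.0, 1.0) * (fovg == 1)
    return ProbabilityMap(grid=grid, channel=model.channel or "original")
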