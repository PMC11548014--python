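"""Compact encoder-decoder segmentation network with skip connections.

The network follows the structural contract of the dual-image analysis
pipeline: repeated 3x3 downsampling convolutions each followed by ReLU and
batch normalization in the contracting path, transpose-convolution
upsampling with skip concatenations in the expansive path, a per-pixel
two-class SoftMax head, a categorical Jaccard loss summed over the batch,
and Adam optimization.  It is sized to train on a single CPU; the channel
widths, depth, batch size and epoch count are configurable, with the
full-scale settings (batch 32, 50 epochs) available through the same config.

Inference on full frames goes through the standard chain: background
estimation -> SBR -> 8-bit scaling -> 256x256 patching -> per-patch argmax
prediction -> stitching back to the original size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from dualev import nn
from dualev.background import preprocess_to_uint8
from dualev.patchwork import Patch, pad_and_patch, stitch

__all__ = [
    "SegNetConfig",
    "SegNet",
    "TrainingRun",
    "jaccard_loss",
    "jaccard_grad",
    "train",
    "predict_patch_image",
    "predict_image",
    "save_model",
    "load_model",
]

F32 = np.float32


@dataclass(frozen=True)
class SegNetConfig:
    """Architecture and training hyperparameters.

    Defaults are the full-scale contract (depth 4, base 16 channels,
    batch 32, 50 epochs); :meth:`small` returns the desk-scale preset used
    by the package's own experiments.
    """

    depth: int = 4
    base_channels: int = 16
    kernel: int = 3
    batch_size: int = 32
    epochs: int = 50
    learning_rate: float = 1e-3
    crop: int = 256  # training crop side; must be divisible by 2**depth
    jaccard_eps: float = 1.0
    # Input normalization: 8-bit counts are centered at the value-10
    # information cutoff and scaled so one quantization level is half a
    # network unit.  Centering puts the decisive intensity region at zero,
    # where small head weights already produce a sharp decision.
    input_center: float = 10.0
    input_scale: float = 0.5
    head_lr_factor: float = 100.0  # faster learning for the 1x1 head
    head_warmup_steps: int = 60  # linear warmup of the head rate (stability)
    cosine_decay: bool = True  # cosine learning-rate decay over the run
    seed: int = 0

    @classmethod
    def small(cls, **overrides) -> "SegNetConfig":
        base = dict(depth=3, base_channels=8, batch_size=16, epochs=8, crop=96)
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        if self.crop % (2**self.depth):
            raise ValueError("crop side must be divisible by 2**depth")
        if self.depth < 1 or self.base_channels < 1 or self.epochs < 1:
            raise ValueError("depth, base_channels and epochs must be >= 1")


@dataclass
class TrainingRun:
    losses: list[float]
    model: "SegNet"
    config: SegNetConfig
    seed: int


class SegNet:
    """U-shaped encoder-decoder over the nn primitives."""

    def __init__(self, cfg: SegNetConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = [cfg.base_channels * 2**i for i in range(cfg.depth + 1)]
        k = cfg.kernel
        self.enc = []
        cin = 1
        for i in range(cfg.depth):
            self.enc.append(
                {
                    "conv": nn.Conv2D(cin, ch[i], k=k, rng=rng),
                    "bn": nn.BatchNorm(ch[i]),
                    "relu": nn.ReLU(),
                    "down": nn.Conv2D(ch[i], ch[i + 1], k=k, stride=2, rng=rng),
                    "down_bn": nn.BatchNorm(ch[i + 1]),
                    "down_relu": nn.ReLU(),
                }
            )
            cin = ch[i + 1]
        self.mid = {
            "conv": nn.Conv2D(ch[-1], ch[-1], k=k, rng=rng),
            "bn": nn.BatchNorm(ch[-1]),
            "relu": nn.ReLU(),
        }
        self.dec = []
        for i in reversed(range(cfg.depth)):
            self.dec.append(
                {
                    "up": nn.ConvTranspose2D(ch[i + 1], ch[i], k=k, stride=2, rng=rng),
                    "up_bn": nn.BatchNorm(ch[i]),
                    "up_relu": nn.ReLU(),
                    "conv": nn.Conv2D(2 * ch[i], ch[i], k=k, rng=rng),
                    "bn": nn.BatchNorm(ch[i]),
                    "relu": nn.ReLU(),
                    "skip_channels": ch[i],
                }
            )
        # head sees the decoder features plus the raw input (an input-level
        # skip that bypasses every batch norm, so an absolute-intensity
        # decision rule does not get washed out by batch statistics)
        self.head = nn.Conv2D(ch[0] + 1, 2, k=1, rng=rng)

    # -- plumbing ---------------------------------------------------------
    def _layers(self):
        for blk in self.enc:
            yield from (blk["conv"], blk["bn"], blk["down"], blk["down_bn"])
        yield from (self.mid["conv"], self.mid["bn"])
        for blk in self.dec:
            yield from (blk["up"], blk["up_bn"], blk["conv"], blk["bn"])
        yield self.head

    def param_pairs(self):
        return nn.collect_params(self._layers())

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N,H,W,1) float32 in [0,1] -> per-pixel class probabilities (N,H,W,2)."""
        skips = []
        h = x
        for blk in self.enc:
            h = blk["relu"].forward(blk["bn"].forward(blk["conv"].forward(h, train), train), train)
            skips.append(h)
            h = blk["down_relu"].forward(
                blk["down_bn"].forward(blk["down"].forward(h, train), train), train
            )
        h = self.mid["relu"].forward(
            self.mid["bn"].forward(self.mid["conv"].forward(h, train), train), train
        )
        for blk in self.dec:
            h = blk["up_relu"].forward(
                blk["up_bn"].forward(blk["up"].forward(h, train), train), train
            )
            skip = skips.pop()
            h = np.concatenate([h, skip], axis=-1)
            h = blk["relu"].forward(blk["bn"].forward(blk["conv"].forward(h, train), train), train)
        h = np.concatenate([h, x], axis=-1)
        logits = self.head.forward(h, train)
        logits -= logits.max(axis=-1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=-1, keepdims=True)
        if train:
            self._probs = probs
        return probs

    def backward(self, dprobs: np.ndarray, prob_floor: float = 1e-3) -> None:
        # The chain rule through softmax multiplies by p, so a class whose
        # probability has saturated to ~0 stops learning and can never be
        # revived (the all-background collapse).  Flooring the probabilities
        # used in the backward pass keeps the gradient direction while
        # bounding it away from zero.
        p = self._probs
        if prob_floor > 0:
            k = p.shape[-1]
            p = (p + prob_floor) / (1.0 + k * prob_floor)
        dlogits = p * (dprobs - (dprobs * p).sum(axis=-1, keepdims=True))
        dh = self.head.backward(dlogits.astype(F32))
        dh = dh[..., :-1]  # grad w.r.t. the input skip is not needed
        dskips = []
        for blk in reversed(self.dec):
            dh = blk["conv"].backward(blk["bn"].backward(blk["relu"].backward(dh)))
            c = blk["skip_channels"]
            dskips.append(dh[..., c:])
            dh = dh[..., :c]
            dh = blk["up"].backward(blk["up_bn"].backward(blk["up_relu"].backward(dh)))
        dh = self.mid["conv"].backward(self.mid["bn"].backward(self.mid["relu"].backward(dh)))
        for blk in reversed(self.enc):
            dh = blk["down"].backward(blk["down_bn"].backward(blk["down_relu"].backward(dh)))
            dh = dh + dskips.pop()
            dh = blk["conv"].backward(blk["bn"].backward(blk["relu"].backward(dh)))

    # -- inference --------------------------------------------------------
    def predict_batch(self, images: np.ndarray) -> np.ndarray:
        """(N,H,W) in network units -> (N,H,W) bool foreground (argmax)."""
        probs = self.forward(images[..., None].astype(F32), train=False)
        return probs[..., 1] > probs[..., 0]


def jaccard_loss(pred: np.ndarray, truth: np.ndarray, eps: float = 1.0) -> float:
    """Categorical Jaccard loss, summed over the batch.

    ``pred``: per-pixel class probabilities (..., k); ``truth``: one-hot of
    the same shape.  Returns ``1 - mean_c (sum p*t + eps) / (sum p + sum t -
    sum p*t + eps)``, a scalar in [0, 1]; zero iff hard prediction equals
    truth exactly.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    axes = tuple(range(pred.ndim - 1))
    inter = (pred * truth).sum(axis=axes)
    union = pred.sum(axis=axes) + truth.sum(axis=axes) - inter
    return float(1.0 - np.mean((inter + eps) / (union + eps)))


def jaccard_grad(pred: np.ndarray, truth: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """d loss / d pred for :func:`jaccard_loss`."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    axes = tuple(range(pred.ndim - 1))
    inter = (pred * truth).sum(axis=axes)
    union = pred.sum(axis=axes) + truth.sum(axis=axes) - inter
    k = pred.shape[-1]
    num = truth * (union + eps) - (inter + eps) * (1.0 - truth)
    return (-num / (k * (union + eps) ** 2)).astype(F32)


def _scale_input(img8: np.ndarray, cfg: SegNetConfig) -> np.ndarray:
    return (np.asarray(img8).astype(F32) - cfg.input_center) * cfg.input_scale


def train(model_cfg: SegNetConfig, dataset: list[tuple[np.ndarray, np.ndarray]]) -> TrainingRun:
    """Train on (8-bit patch, binary map) pairs; seeded and reproducible.

    Each epoch draws one random crop (side ``cfg.crop``) per training pair,
    shuffles, and optimizes the batch-summed Jaccard loss with Adam.  The
    recorded per-epoch loss is the mean batch loss.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    cfg = model_cfg
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    model = SegNet(cfg)
    head_pairs = model.head.params()
    head_ids = {id(p) for p, _ in head_pairs}
    body_pairs = [pg for pg in model.param_pairs() if id(pg[0]) not in head_ids]
    opt = nn.Adam(body_pairs, lr=cfg.learning_rate)
    head_lr = cfg.learning_rate * cfg.head_lr_factor
    opt_head = nn.Adam(head_pairs, lr=head_lr)
    step = 0

    imgs = [_scale_input(img, cfg) for img, _ in dataset]
    maps = [np.asarray(m) > 0 for _, m in dataset]
    crop = min(cfg.crop, min(im.shape[0] for im in imgs), min(im.shape[1] for im in imgs))
    crop -= crop % (2**cfg.depth)
    if crop < 2**cfg.depth:
        raise ValueError("training patches too small for the network depth")

    losses = []
    n = len(imgs)
    total_steps = max(1, cfg.epochs * -(-n // cfg.batch_size))
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = np.empty((len(idx), crop, crop, 1), dtype=F32)
            tb = np.zeros((len(idx), crop, crop, 2), dtype=F32)
            for j, i in enumerate(idx):
                h, w = imgs[i].shape
                r = rng.integers(0, h - crop + 1)
                c = rng.integers(0, w - crop + 1)
                xb[j, :, :, 0] = imgs[i][r : r + crop, c : c + crop]
                fg = maps[i][r : r + crop, c : c + crop]
                tb[j, :, :, 1] = fg
                tb[j, :, :, 0] = ~fg
            probs = model.forward(xb, train=True)
            epoch_losses.append(jaccard_loss(probs, tb, cfg.jaccard_eps))
            model.backward(jaccard_grad(probs, tb, cfg.jaccard_eps))
            step += 1
            decay = 1.0
            if cfg.cosine_decay:
                decay = 0.5 * (1.0 + np.cos(np.pi * step / total_steps))
                decay = max(decay, 0.05)
            opt.lr = cfg.learning_rate * decay
            opt_head.lr = head_lr * decay
            if cfg.head_warmup_steps > 0:
                opt_head.lr *= min(1.0, step / cfg.head_warmup_steps)
            opt.step()
            opt_head.step()
        losses.append(float(np.mean(epoch_losses)))
    return TrainingRun(losses=losses, model=model, config=cfg, seed=cfg.seed)


def predict_patch_image(model: SegNet, img8: np.ndarray, patch: int = 256, batch: int = 2) -> np.ndarray:
    """Predict a binary map for an already-preprocessed 8-bit image of any size."""
    patches = pad_and_patch(np.asarray(img8), patch=patch)
    preds = []
    for start in range(0, len(patches), batch):
        chunk = patches[start : start + batch]
        x = np.stack([_scale_input(p.pixels, model.cfg) for p in chunk])
        out = model.predict_batch(x)
        for p, m in zip(chunk, out):
            preds.append(Patch(m, p.origin, p.parent_shape, p.pad_spec))
    return stitch(preds)


def predict_image(
    model: SegNet,
    raw: np.ndarray,
    iterations: int = 10,
    sigma_bg: float = 25.0,
    gain: float = 100.0,
    patch: int = 256,
) -> np.ndarray:
    """Full inference chain from raw counts: preprocess, patch, predict, stitch."""
    _, img8 = preprocess_to_uint8(raw, iterations=iterations, sigma_bg=sigma_bg, gain=gain)
    return predict_patch_image(model, img8, patch=patch)


def save_model(run_or_model, path) -> None:
    model = run_or_model.model if isinstance(run_or_model, TrainingRun) else run_or_model
    arrays = {}
    for i, layer in enumerate(model._layers()):
        state = {k: v for k, v in vars(layer).items() if isinstance(v, np.ndarray)}
        for k, v in state.items():
            if k.startswith("d") or k.startswith("_"):
                continue
            arrays[f"{i}.{k}"] = v
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> SegNet:
    data = np.load(path)
    cfg = SegNetConfig(**json.loads(bytes(data["__config__"]).decode()))
    model = SegNet(cfg)
    for i, layer in enumerate(model._layers()):
        for k in list(vars(layer)):
            key = f"{i}.{k}"
            if key in data:
                getattr(layer, k)[...] = data[key]
    return model
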