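"""Eye-region segmentation with a nested-skip (U-Net++) encoder-decoder.

The segmenter follows the training recipe used for ocular CT: Kaiming
weight initialization, the soft Dice loss, Adam, a learning rate of 1e-4
decayed by 0.99 per epoch, and 200 epochs for full-scale runs. The network
is built on the package's numpy autodiff engine (:mod:`exoct._nn`), so
training is single-CPU and bit-deterministic under a fixed seed.

An :class:`OracleSegmenter` that returns a known ground-truth mask is
provided so downstream geometry can be exercised independently of learning.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _nn as nn
from .types import CTSlice

logger = logging.getLogger(__name__)


@dataclass
class SegTrainConfig:
    """Training hyperparameters.

    ``learning_rate`` / ``lr_decay_per_epoch`` / ``epochs`` default to the
    full-scale recipe (1e-4, 0.99, 200). ``depth``/``base_channels`` default
    to a standard 5-level, 32-channel net; tests and the scaled benchmark
    use depth 3 / base 8.
    """

    learning_rate: float = 1e-4
    lr_decay_per_epoch: float = 0.99
    epochs: int = 200
    batch_size: int = 4
    base_channels: int = 32
    depth: int = 5
    seed: int = 0
    deep_supervision: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0 < self.lr_decay_per_epoch <= 1:
            raise ValueError("lr_decay_per_epoch must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")


@dataclass
class SegResult:
    """Per-pixel foreground probabilities and the thresholded mask."""

    probability_map: np.ndarray
    mask: np.ndarray
    source: str  # 'unetpp' | 'oracle' | 'threshold_fallback'


def dice_loss(prediction: np.ndarray, truth: np.ndarray) -> float:
    """Soft Dice loss ``1 - 2*|X  Y| / (|X| + |Y|)``.

    ``prediction`` is a probability map in [0, 1]; the soft relaxation uses
    the sum of elementwise products as the intersection and plain sums as
    the sizes. An empty-vs-empty pair is defined as a perfect match (0).
    """
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs truth {t.shape}")
    if p.min() < -1e-6 or p.max() > 1 + 1e-6:
        raise ValueError("prediction values must lie in [0, 1]")
    denom = p.sum() + t.sum()
    if denom == 0:
        logger.info("dice_loss: both masks empty; defining loss as 0")
        return 0.0
    return float(1.0 - 2.0 * (p * t).sum() / denom)


def _dice_loss_grad(p: np.ndarray, t: np.ndarray) -> Tuple[float, np.ndarray]:
    """Soft Dice loss and dL/dp for one sample (float64 accumulation)."""
    p64 = p.astype(np.float64)
    t64 = t.astype(np.float64)
    s = p64.sum() + t64.sum()
    if s == 0:
        return 0.0, np.zeros_like(p)
    inter = (p64 * t64).sum()
    loss = 1.0 - 2.0 * inter / s
    grad = (-2.0 * t64 / s + 2.0 * inter / (s * s)).astype(np.float32)
    return float(loss), grad


class UNetPP:
    """Nested-skip encoder-decoder with dense skip pathways.

    Node ``X[i][j]`` sits at resolution level ``i`` (feature width
    ``base * 2**i``); ``X[i][0]`` is the encoder backbone, and every
    ``X[i][j>0]`` re-convolves the concatenation of all same-level
    predecessors with the upsampled deeper node. The output head is a 1x1
    convolution plus sigmoid on ``X[0][depth-1]``.
    """

    def __init__(self, config: SegTrainConfig):
        self.config = config
        self.depth = config.depth
        self.base = config.base_channels
        rng = np.random.default_rng(config.seed)
        ch = [self.base * 2 ** i for i in range(self.depth)]
        self.params: List[nn.Tensor] = []
        self.blocks: Dict[Tuple[int, int], list] = {}
        for i in range(self.depth):
            for j in range(self.depth - i):
                if j == 0:
                    c_in = 1 if i == 0 else ch[i - 1]
                else:
                    c_in = j * ch[i] + ch[i + 1]
                self.blocks[(i, j)] = self._conv_block(rng, c_in, ch[i])
        w = nn.Tensor(nn.kaiming_conv(rng, 1, ch[0], 1), is_param=True)
        b = nn.Tensor(np.zeros(1, dtype=np.float32), is_param=True)
        self.head = (w, b)
        self.params += [w, b]

    def _conv_block(self, rng, c_in: int, c_out: int) -> list:
        layers = []
        for cin in (c_in, c_out):
            w = nn.Tensor(nn.kaiming_conv(rng, c_out, cin, 3), is_param=True)
            b = nn.Tensor(np.zeros(c_out, dtype=np.float32), is_param=True)
            layers.append((w, b))
            self.params += [w, b]
        return layers

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def summary(self) -> str:
        return (
            f"UNetPP(depth={self.depth}, base_channels={self.base}, "
            f"params={self.num_parameters()})"
        )

    def _apply_block(self, key, x: nn.Tensor) -> nn.Tensor:
        for w, b in self.blocks[key]:
            x = nn.relu(nn.conv3(x, w, b))
        return x

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """Probability map for a batch ``(N, 1, H, W)`` scaled to [0, 1]."""
        h, w = x.shape[2], x.shape[3]
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by {div}; pad the image first "
                "(predict() does this automatically)"
            )
        nodes: Dict[Tuple[int, int], nn.Tensor] = {}
        for i in range(self.depth):
            inp = x if i == 0 else nn.maxpool2(nodes[(i - 1, 0)])
            nodes[(i, 0)] = self._apply_block((i, 0), inp)
        for j in range(1, self.depth):
            for i in range(self.depth - j):
                skips = [nodes[(i, k)] for k in range(j)]
                up = nn.upsample2(nodes[(i + 1, j - 1)])
                nodes[(i, j)] = self._apply_block((i, j), nn.concat(skips + [up]))
        wh, bh = self.head
        return nn.sigmoid(nn.conv1(nodes[(0, self.depth - 1)], wh, bh))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Probability map for one 2D image on the canonical 8-bit scale.

        Intensities are normalized to [0, 1]; sizes not divisible by
        ``2**(depth-1)`` are reflection-padded and the output cropped back.
        """
        img = np.asarray(image, dtype=np.float32) / 255.0
        h, w = img.shape
        div = 2 ** (self.depth - 1)
        ph = (-h) % div
        pw = (-w) % div
        if ph or pw:
            img = np.pad(img, ((0, ph), (0, pw)), mode="reflect")
        out = self.forward(nn.Tensor(img[None, None]))
        return out.data[0, 0, :h, :w].astype(np.float64)

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> Dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.params)}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            p.data = np.asarray(state[f"p{i}"], dtype=np.float32).reshape(p.data.shape)

    def save(self, path) -> None:
        meta = dict(
            depth=self.depth,
            base_channels=self.base,
            seed=self.config.seed,
            learning_rate=self.config.learning_rate,
            lr_decay_per_epoch=self.config.lr_decay_per_epoch,
            epochs=self.config.epochs,
            batch_size=self.config.batch_size,
        )
        np.savez(path, __meta__=np.array([repr(meta)]), **self.state_dict())

    @classmethod
    def load(cls, path) -> "UNetPP":
        with np.load(path, allow_pickle=False) as data:
            meta = eval(str(data["__meta__"][0]), {"__builtins__": {}})  # config echo
            config = SegTrainConfig(
                learning_rate=float(meta["learning_rate"]),
                lr_decay_per_epoch=float(meta["lr_decay_per_epoch"]),
                epochs=int(meta["epochs"]),
                batch_size=int(meta["batch_size"]),
                base_channels=int(meta["base_channels"]),
                depth=int(meta["depth"]),
                seed=int(meta["seed"]),
            )
            model = cls(config)
            model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model


def build_unetpp(config: SegTrainConfig) -> UNetPP:
    """Construct a freshly initialized network from a config."""
    return UNetPP(config)


class OracleSegmenter:
    """Returns a fixed ground-truth mask; used to isolate geometry from learning."""

    def __init__(self, mask: np.ndarray):
        self.mask = np.asarray(mask).astype(bool)

    def predict(self, image: np.ndarray) -> np.ndarray:
        if image.shape != self.mask.shape:
            raise ValueError("oracle mask does not match image shape")
        return self.mask.astype(np.float64)

    @property
    def source(self) -> str:
        return "oracle"


def _as_image_array(item) -> np.ndarray:
    if isinstance(item, CTSlice):
        return np.asarray(item.pixels, dtype=np.float32)
    return np.asarray(item, dtype=np.float32)


def train_segmenter(
    train: Sequence[Tuple[Union[CTSlice, np.ndarray], np.ndarray]],
    val: Sequence[Tuple[Union[CTSlice, np.ndarray], np.ndarray]],
    config: SegTrainConfig,
) -> Tuple[UNetPP, Dict[str, List[float]]]:
    """Adam minimization of the Dice loss with per-epoch learning-rate decay.

    Returns the model holding the weights that achieved the best validation
    loss (best training loss if the validation set is empty, with a logged
    warning) and the per-epoch loss history ``{"train": [...], "val": [...]}``.
    """
    if not train:
        raise ValueError("training set is empty")
    model = build_unetpp(config)
    images = np.stack([_as_image_array(im) / 255.0 for im, _ in train])[:, None]
    masks = np.stack([np.asarray(m, dtype=np.float32) for _, m in train])[:, None]
    if images.shape[2:] != masks.shape[2:]:
        raise ValueError("training masks are not aligned with their slices")
    has_val = len(val) > 0
    if has_val:
        vimages = np.stack([_as_image_array(im) / 255.0 for im, _ in val])[:, None]
        vmasks = np.stack([np.asarray(m, dtype=np.float32) for _, m in val])[:, None]
    else:
        warnings.warn("validation set empty: checkpointing on training loss")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.params, lr=config.learning_rate)
    history: Dict[str, List[float]] = {"train": [], "val": []}
    best = (np.inf, model.state_dict())
    n = len(train)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x = nn.Tensor(images[idx])
            out = model.forward(x)
            grads = np.empty_like(out.data)
            batch_loss = 0.0
            for b in range(len(idx)):
                loss_b, g = _dice_loss_grad(out.data[b, 0], masks[idx][b, 0])
                batch_loss += loss_b
                grads[b, 0] = g / len(idx)
            epoch_losses.append(batch_loss / len(idx))
            nn.zero_grads(model.params)
            nn.backward(out, grads)
            opt.step()
        history["train"].append(float(np.mean(epoch_losses)))
        if has_val:
            vloss = float(
                np.mean(
                    [
                        dice_loss(model.forward(nn.Tensor(vimages[i : i + 1])).data[0, 0],
                                  vmasks[i, 0])
                        for i in range(len(val))
                    ]
                )
            )
            history["val"].append(vloss)
            monitor = vloss
        else:
            monitor = history["train"][-1]
        if monitor < best[0]:
            best = (monitor, model.state_dict())
        opt.lr *= config.lr_decay_per_epoch
    model.load_state_dict(best[1])
    return model, history


def segment_eyes(ct: CTSlice, segmenter) -> SegResult:
    """Apply a segmenter (trained net or oracle) to one slice."""
    prob = segmenter.predict(np.asarray(ct.pixels))
    if prob.shape != ct.shape:
        raise ValueError("segmenter output shape does not match slice")
    source = getattr(segmenter, "source", "unetpp")
    return SegResult(probability_map=prob, mask=prob >= 0.5, source=source)
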