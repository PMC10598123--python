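"""Liver segmentation: a small encoder-decoder network (U-Net style, one
skip connection) trained on the hepatobiliary-phase T1 image, a
threshold-based analytic fallback, and Dice/recall/precision scoring.

The network is deliberately desk-scale (two resolution levels, a handful
of channels) — the liver in the synthetic studies is a bright convex-ish
blob on a dark background, which a tiny network learns quickly and
deterministically on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

from . import _nn
from .cohort import MRStudy


@dataclass(frozen=True)
class SegmentationMetrics:
    dice: float
    recall: float
    precision: float
    empty_prediction: bool = False


@dataclass
class SegmenterSpec:
    depth: int = 2
    channels: tuple = (6, 12)
    epochs: int = 40
    lr: float = 2e-3
    rng_seed: int = 0

    def validate(self):
        if self.depth < 1 or self.epochs < 1:
            raise ValueError("depth and epochs must be >= 1")
        return self


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegmentationMetrics:
    """Dice = 2|P&T|/(|P|+|T|), recall = |P&T|/|T|, precision = |P&T|/|P|
    (precision defined as 1 and flagged when the prediction is empty)."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    nt = int(truth.sum())
    if nt == 0:
        raise ValueError("truth mask is empty")
    np_ = int(pred.sum())
    inter = int((pred & truth).sum())
    dice = 2.0 * inter / (np_ + nt)
    recall = inter / nt
    if np_ == 0:
        return SegmentationMetrics(dice=0.0, recall=0.0, precision=1.0, empty_prediction=True)
    return SegmentationMetrics(dice=dice, recall=recall, precision=inter / np_)


def otsu_segment(image: np.ndarray) -> np.ndarray:
    """Analytic fallback: Otsu threshold, largest connected component,
    hole filling. Default segmentation for the bright-liver HBP image."""
    mask = image > threshold_otsu(image)
    if not mask.any():
        return mask
    labels = label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(labels == largest)


class UNetSegmenter:
    """Two-level encoder-decoder with one skip concatenation; pixelwise
    sigmoid output trained with binary cross-entropy."""

    def __init__(self, spec: SegmenterSpec):
        spec.validate()
        self.spec = spec
        c1, c2 = spec.channels
        rng = np.random.default_rng(spec.rng_seed)
        self.conv_a1 = _nn.Conv2d(1, c1, rng=rng)
        self.relu_a1 = _nn.ReLU()
        self.conv_a2 = _nn.Conv2d(c1, c1, rng=rng)
        self.relu_a2 = _nn.ReLU()
        self.down = _nn.Conv2d(c1, c2, stride=2, rng=rng)
        self.relu_d = _nn.ReLU()
        self.conv_b = _nn.Conv2d(c2, c2, rng=rng)
        self.relu_b = _nn.ReLU()
        self.up = _nn.Upsample2x()
        self.conv_u = _nn.Conv2d(c2, c1, rng=rng)
        self.relu_u = _nn.ReLU()
        self.conv_c = _nn.Conv2d(2 * c1, c1, rng=rng)
        self.relu_c = _nn.ReLU()
        self.head = _nn.Conv2d(c1, 1, k=1, pad=0, rng=rng)
        self.losses: list[float] = []

    def _layers(self):
        return [
            self.conv_a1, self.conv_a2, self.down, self.conv_b,
            self.conv_u, self.conv_c, self.head,
        ]

    def _forward(self, x):
        a = self.relu_a2.forward(self.conv_a2.forward(self.relu_a1.forward(self.conv_a1.forward(x))))
        self._skip = a
        b = self.relu_b.forward(self.conv_b.forward(self.relu_d.forward(self.down.forward(a))))
        u = self.relu_u.forward(self.conv_u.forward(self.up.forward(b)))
        cat = np.concatenate([a, u], axis=1)
        c = self.relu_c.forward(self.conv_c.forward(cat))
        return self.head.forward(c)[:, 0, :, :]

    def _backward(self, dlogits):
        d = self.head.backward(dlogits[:, None, :, :])
        d = self.conv_c.backward(self.relu_c.backward(d))
        c1 = self._skip.shape[1]
        d_a_skip, d_u = d[:, :c1], d[:, c1:]
        d = self.up.backward(self.conv_u.backward(self.relu_u.backward(d_u)))
        d = self.down.backward(self.relu_d.backward(self.conv_b.backward(self.relu_b.backward(d))))
        d = d + d_a_skip
        d = self.conv_a2.backward(self.relu_a2.backward(d))
        self.conv_a1.backward(self.relu_a1.backward(d))

    @staticmethod
    def _prep(image: np.ndarray) -> np.ndarray:
        sd = image.std()
        return (image - image.mean()) / (sd if sd > 0 else 1.0)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        x = self._prep(np.asarray(image, dtype=float))[None, None, :, :]
        return _nn.sigmoid(self._forward(x))[0]

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return segment(self, image)


def train_segmenter(
    studies: list[MRStudy], spec: SegmenterSpec | None = None, sequence: str = "t1_hbp"
) -> UNetSegmenter:
    """Train the network on the given studies using their masks as truth.
    The HBP sequence is the default input (segmentation is most reliable
    on hepatobiliary-phase images)."""
    spec = (spec or SegmenterSpec()).validate()
    if len(studies) < 2:
        raise ValueError("need at least 2 training studies")
    shapes = {s.liver_mask.shape for s in studies}
    if len(shapes) != 1:
        raise ValueError("training studies must share one image shape")
    x = np.stack([UNetSegmenter._prep(getattr(s, sequence).astype(float)) for s in studies])
    y = np.stack([s.liver_mask.astype(float) for s in studies])
    model = UNetSegmenter(spec)
    opt = _nn.Adam(model._layers(), lr=spec.lr)
    for _ in range(spec.epochs):
        logits = model._forward(x[:, None, :, :])
        loss, dlogits = _nn.bce_with_logits(logits, y)
        model._backward(dlogits)
        opt.step()
        model.losses.append(float(loss))
    return model


def segment(model, image: np.ndarray) -> np.ndarray:
    """Binary mask from a trained model (probability >= 0.5)."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    return model.predict_proba(image) >= 0.5
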