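"""Depth- and recurrence-parametric family of small image classifiers.

The family scales a fixed component set, mirroring how residual networks are
deepened without otherwise changing the architecture: a convolutional stem,
``n_blocks`` same-resolution 3x3 conv blocks (optionally with an identity
residual connection, optionally unrolled ``recurrent_steps`` extra times with
tied weights, the weight-clamped-recurrence view of deep ResNets), average
pooling, and a global-average-pool linear readout.  The shallowest member has
no residual connection, matching the convention that the residual shortcut is
removed when the network is too shallow to need one.

Training is plain seeded SGD with momentum on softmax cross-entropy; every
stochastic choice (initialization, shuffling, crop jitter) derives from the
given seed, so runs are bit-reproducible on one machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .scenegen import CONDITIONS, ImageDataset, StimulusSet

__all__ = ["ModelSpec", "Classifier", "TrainingCurve", "build_model", "train",
           "evaluate", "EvalResult", "default_family"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture parameters of one family member.

    n_blocks is the depth proxy; recurrent_steps > 0 unrolls each block that
    many extra times with tied weights (0 = pure feedforward).
    """

    n_blocks: int = 1
    residual: bool = False
    recurrent_steps: int = 0
    base_channels: int = 24
    n_classes: int = 6
    input_size: int = 32

    def validate(self) -> None:
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.recurrent_steps < 0:
            raise ValueError(f"recurrent_steps must be >= 0, got {self.recurrent_steps}")
        if self.base_channels < 1 or self.n_classes < 2:
            raise ValueError("base_channels >= 1 and n_classes >= 2 required")
        if self.input_size < 8 or self.input_size % 4:
            raise ValueError("input_size must be a multiple of 4 and >= 8")

    @property
    def name(self) -> str:
        tag = f"net{self.n_blocks}b"
        if self.residual:
            tag += "r"
        if self.recurrent_steps:
            tag += f"t{self.recurrent_steps}"
        return tag


def default_family(n_classes: int, input_size: int = 32,
                   base_channels: int = 24) -> list[ModelSpec]:
    """Shallow-to-deep default family: 1, 2, and 4 blocks; the shallowest
    member is non-residual."""
    return [
        ModelSpec(1, False, 0, base_channels, n_classes, input_size),
        ModelSpec(2, True, 0, base_channels, n_classes, input_size),
        ModelSpec(4, True, 0, base_channels, n_classes, input_size),
    ]


@dataclass
class TrainingCurve:
    diet: str
    spec: ModelSpec
    seed: int
    val_accuracy: list[float]

    @property
    def epochs(self) -> int:
        return len(self.val_accuracy)


class Classifier:
    """A trained (or freshly initialized) family member.

    Exposes pre-softmax class scores and per-layer post-ReLU activation
    stacks; both are deterministic functions of the stored parameters.
    """

    def __init__(self, spec: ModelSpec, seed: int):
        spec.validate()
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 97, spec.n_blocks,
                                    spec.base_channels))))
        c = spec.base_channels
        p: dict[str, np.ndarray] = {}
        p["stem_w"], p["stem_b"] = nn.he_conv(rng, 3, c)
        # damp residual branches at init (fixup-style) so deep normalization-
        # free stacks keep unit-scale activations and train stably
        steps = 1 + spec.recurrent_steps
        damp = np.float32((spec.n_blocks * steps) ** -0.5) if spec.residual else np.float32(1.0)
        for i in range(spec.n_blocks):
            w, b = nn.he_conv(rng, c, c)
            p[f"block{i + 1}_w"], p[f"block{i + 1}_b"] = w * damp, b
        p["fc_w"], p["fc_b"] = nn.he_linear(rng, c, spec.n_classes)
        self.params = p

    # ---- bookkeeping -----------------------------------------------------
    @property
    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    @property
    def layer_names(self) -> list[str]:
        return ["stem"] + [f"block{i + 1}" for i in range(self.spec.n_blocks)]

    # ---- forward / backward ----------------------------------------------
    @staticmethod
    def _prep(images: np.ndarray) -> np.ndarray:
        """(N,H,W,3) in [0,1] -> centered float32 NCHW."""
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2)) * 2.0 - 1.0

    def _forward(self, x: np.ndarray, want_cache: bool = False,
                 collect: bool = False, training: bool = False):
        p, spec = self.params, self.spec
        cache: list = []
        acts: dict[str, np.ndarray] = {}
        h, cv = nn.conv3x3_forward(x, p["stem_w"], p["stem_b"])
        h, rm = nn.relu_forward(h)
        cache.append(("stem", cv, rm))
        if collect:
            acts["stem"] = h
        h, ps = nn.avgpool2_forward(h)
        cache.append(("pool", ps))
        steps = 1 + spec.recurrent_steps
        # second downsampling sits mid-stack, so deeper members integrate the
        # later blocks at a coarser scale (multi-scale processing, as in
        # downsampling residual families)
        pool_after = (spec.n_blocks + 1) // 2
        for i in range(spec.n_blocks):
            name = f"block{i + 1}"
            step_caches = []
            for _ in range(steps):
                z, cv = nn.conv3x3_forward(h, p[f"{name}_w"], p[f"{name}_b"])
                if spec.residual:
                    z = z + h
                hn, rm = nn.relu_forward(z)
                step_caches.append((cv, rm))
                h = hn
            cache.append((name, step_caches))
            if collect:
                acts[name] = h
            if i + 1 == pool_after:
                h, ps = nn.avgpool2_forward(h)
                cache.append(("pool", ps))
        g, gs = nn.gap_forward(h)
        cache.append(("gap", gs))
        logits, xin = nn.linear_forward(g, p["fc_w"], p["fc_b"])
        cache.append(("fc", xin))
        if want_cache:
            return logits, cache
        if collect:
            return logits, acts
        return logits

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p, spec = self.params, self.spec
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        d = dlogits
        for entry in reversed(cache):
            tag = entry[0]
            if tag == "fc":
                d, grads["fc_w"], grads["fc_b"] = nn.linear_backward(d, entry[1], p["fc_w"])
            elif tag == "gap":
                d = nn.gap_backward(d, entry[1])
            elif tag == "pool":
                d = nn.avgpool2_backward(d, entry[1])
            elif tag == "stem":
                dz = nn.relu_backward(d, entry[2])
                _, grads["stem_w"], grads["stem_b"] = nn.conv3x3_backward(dz, entry[1])
            else:  # blockN, possibly weight-tied over several unrolled steps
                for cv, rm in reversed(entry[1]):
                    dz = nn.relu_backward(d, rm)
                    dx, dw, db = nn.conv3x3_backward(dz, cv)
                    grads[f"{tag}_w"] += dw
                    grads[f"{tag}_b"] += db
                    d = dx + dz if spec.residual else dx
        return grads

    # ---- public API ------------------------------------------------------
    def class_scores_batch(self, images: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Pre-softmax scores, (N, n_classes)."""
        x = self._prep(images)
        outs = [self._forward(x[i:i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(outs, axis=0)

    def class_scores(self, image: np.ndarray) -> np.ndarray:
        """Pre-softmax scores of a single (H,W,3) image."""
        return self.class_scores_batch(image[None])[0]

    def layer_activations(self, image: np.ndarray, layer: str) -> np.ndarray:
        """Post-ReLU activation stack (filters, H', W') of a named layer."""
        if layer not in self.layer_names:
            raise ValueError(f"unknown layer {layer!r}; valid layers: {self.layer_names}")
        _, acts = self._forward(self._prep(image[None]), collect=True)
        return acts[layer][0]

    def save(self, path: str | Path) -> None:
        meta = dict(self.spec.__dict__, seed=self.seed)
        np.savez(path, __meta__=np.array([json.dumps(meta)]), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "Classifier":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["__meta__"][0]))
        seed = meta.pop("seed")
        model = cls(ModelSpec(**meta), seed)
        for k in model.params:
            model.params[k] = data[k]
        return model


def build_model(spec: ModelSpec, seed: int) -> Classifier:
    """Deterministically initialize one family member."""
    return Classifier(spec, seed)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _augment(x: np.ndarray, pad: int, rng: np.random.Generator) -> np.ndarray:
    """Random-crop translation jitter: reflect-pad by ``pad`` and crop back."""
    if pad <= 0:
        return x
    n, h, w, _ = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)), mode="reflect")
    offs = rng.integers(0, 2 * pad + 1, size=(n, 2))
    out = np.empty_like(x)
    for i in range(n):
        r, c = offs[i]
        out[i] = xp[i, r:r + h, c:c + w]
    return out


def _top1_accuracy(model: Classifier, images: np.ndarray, labels: np.ndarray) -> float:
    scores = model.class_scores_batch(images)
    return float((scores.argmax(axis=1) == labels).mean())


def train(model: Classifier, train_data, val_data, epochs: int, seed: int,
          augment: int = 2, batch_size: int = 8, lr: float = 0.05,
          momentum: float = 0.9, weight_decay: float = 0.0,
          diet: str = "unspecified") -> TrainingCurve:
    """SGD-train a classifier, recording validation accuracy after each epoch.

    ``train_data``/``val_data`` are (images NHWC in [0,1], labels) pairs or
    :class:`~depthseg.scenegen.ImageDataset` train/val views.  ``augment`` is
    the crop-jitter padding in pixels (0 disables it).  Deep normalization-
    free stacks are kept stable by the damped residual initialization and the
    optimizer's gradient-norm clipping, so one learning rate serves the whole
    family.
    """
    tx, ty = train_data if not isinstance(train_data, ImageDataset) else train_data.train
    vx, vy = val_data if not isinstance(val_data, ImageDataset) else val_data.val
    if len(tx) == 0 or len(vx) == 0:
        raise ValueError("empty training or validation data")
    if int(max(ty.max(), vy.max())) >= model.spec.n_classes:
        raise ValueError("labels exceed the model's class count")
    tx = np.asarray(tx, dtype=np.float32)
    ty = np.asarray(ty, dtype=np.int64)
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence((int(seed) & 0x7FFFFFFF, 131))))
    opt = nn.SGD(model.params, lr=lr, momentum=momentum,
                 weight_decay=weight_decay)
    curve: list[float] = []
    for _epoch in range(int(epochs)):
        order = rng.permutation(len(tx))
        xb_all = _augment(tx[order], augment, rng)
        yb_all = ty[order]
        for i in range(0, len(tx), batch_size):
            xb = model._prep(xb_all[i:i + batch_size])
            yb = yb_all[i:i + batch_size]
            logits, cache = model._forward(xb, want_cache=True, training=True)
            _, dlogits = nn.softmax_xent(logits, yb)
            grads = model._backward(dlogits, cache)
            opt.step(grads)
        curve.append(_top1_accuracy(model, vx, vy))
    return TrainingCurve(diet=diet, spec=model.spec, seed=int(seed), val_accuracy=curve)


def curve_frame(curves: list[TrainingCurve]) -> pd.DataFrame:
    rows = [{"diet": c.diet, "model": c.spec.name, "seed": c.seed,
             "epoch": e + 1, "val_accuracy": a}
            for c in curves for e, a in enumerate(c.val_accuracy)]
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

@dataclass
class EvalResult:
    per_condition: pd.DataFrame  # condition, n, accuracy
    records: pd.DataFrame        # one row per scene

    def accuracy(self, condition: str) -> float:
        row = self.per_condition[self.per_condition.condition == condition]
        return float(row.accuracy.iloc[0]) if len(row) else float("nan")


def default_top_k(n_classes: int) -> int:
    """Top-5 scoring for rich label spaces, top-1 for few-class runs."""
    return 5 if n_classes >= 10 else 1


def evaluate(model, sset: StimulusSet, top_k: int | None = None) -> EvalResult:
    """Per-condition top-k accuracy on a stimulus set.

    A scene counts as correct when its true category is among the ``top_k``
    highest pre-softmax scores.  Per-scene records are retained for the
    statistics layer.
    """
    n_classes = int(model.spec.n_classes) if hasattr(model, "spec") else int(model.n_classes)
    if top_k is None:
        top_k = default_top_k(n_classes)
    if top_k > n_classes:
        raise ValueError(f"top_k={top_k} exceeds n_classes={n_classes}")
    cats = np.array([sc.category for sc in sset.scenes])
    if cats.max() >= n_classes:
        raise ValueError("stimulus set contains categories outside the model's label space")
    images = np.asarray([sc.pixels for sc in sset.scenes], dtype=np.float32)
    scores = model.class_scores_batch(images)
    topk_idx = np.argsort(-scores, axis=1, kind="stable")[:, :top_k]
    correct = (topk_idx == cats[:, None]).any(axis=1)
    records = sset.manifest.copy()
    records["correct"] = correct
    records["true_score"] = scores[np.arange(len(cats)), cats]
    rows = []
    for cond in CONDITIONS:
        sel = records.condition == cond
        if sel.any():
            rows.append({"condition": cond, "n": int(sel.sum()),
                         "accuracy": float(records.correct[sel].mean())})
    return EvalResult(per_condition=pd.DataFrame(rows), records=records)
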