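"""Downstream two-class discriminator fine-tuned from the pretrained encoder.

The classification head follows the U-net-to-classifier recipe: global
average pooling of the deepest encoder stage, a fully-connected layer with
ReLU, and a final fully-connected layer producing two logits (class A =
PD-like is the positive class throughout the package).  The encoder can be
initialised from a pretraining checkpoint (``init="pretrained"``) or left at
its random initialisation (``init="scratch"``) for the from-scratch
comparison.

Fine-tuning uses cross-entropy with AdamW and a cosine learning-rate decay
from ``lr_init`` to ``lr_floor`` (1e-5 to 1e-9 at paper scale); validation
accuracy is monitored every epoch and the weights of the best epoch
(earliest on ties) are restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from ._seeds import rng_from
from .recon_model import (
    ConvAutoencoder,
    EncoderConfig,
    load_checkpoint,
    save_checkpoint,
    stage_channels,
)
from .volume_io import MultiContrastVolume

__all__ = [
    "FinetuneConfig", "PredictionRecord", "ConvClassifier",
    "build_classifier", "train_finetune", "predict", "FinetuneResult",
    "POSITIVE_CLASS", "CLASS_TO_INDEX",
]

#: Class A (PD-like) is the positive class: sensitivity counts its detection.
POSITIVE_CLASS = "A"
CLASS_TO_INDEX = {"A": 0, "B": 1}
INDEX_TO_CLASS = {v: k for k, v in CLASS_TO_INDEX.items()}


@dataclass
class FinetuneConfig:
    """Fine-tuning schedule: cross-entropy, AdamW, cosine lr decay."""

    lr_init: float = 1e-5
    lr_floor: float = 1e-9
    epochs: int = 200
    batch_size: int = 8
    weight_decay: float = 1e-2
    init: str = "pretrained"           # or "scratch"
    hidden_width: int = 128
    seed: int = 0


@dataclass
class PredictionRecord:
    subject_id: str
    true_label: str
    predicted_label: str
    score: float                       # P(positive class A)


class ConvClassifier:
    """Encoder feature pyramid + GAP + FC/ReLU/FC two-logit head."""

    def __init__(self, cfg: EncoderConfig, hidden_width: int = 128):
        self.cfg = cfg
        self.hidden_width = int(hidden_width)
        self.encoder = ConvAutoencoder(cfg)
        deep = stage_channels(cfg.feature_size, cfg.n_downsamples)
        rng = rng_from(cfg.seed, 77)
        self.params: dict[str, nn.Tensor] = {
            k: v for k, v in self.encoder.params.items() if k.startswith("enc")
        }
        self.params["head.fc1.w"] = nn.Tensor(
            rng.normal(0.0, np.sqrt(2.0 / deep), size=(deep, self.hidden_width)),
            requires_grad=True)
        self.params["head.fc1.b"] = nn.Tensor(np.zeros(self.hidden_width), requires_grad=True)
        self.params["head.fc2.w"] = nn.Tensor(
            rng.normal(0.0, np.sqrt(2.0 / self.hidden_width), size=(self.hidden_width, 2)),
            requires_grad=True)
        self.params["head.fc2.b"] = nn.Tensor(np.zeros(2), requires_grad=True)

    def parameters(self):
        return list(self.params.values())

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        missing = set(self.params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=v.data.dtype)

    def load_pretrained_encoder(self, checkpoint_path) -> None:
        """Load encoder weights from a pretraining checkpoint archive.

        The checkpoint's encoder configuration must match this classifier's;
        differing keys are listed in the error.
        """
        state, config, _ = load_checkpoint(checkpoint_path)
        mine = self.cfg.to_dict()
        diffs = [k for k in mine if config.get(k) != mine[k] and k != "seed"]
        if diffs:
            raise ValueError(
                "pretraining checkpoint configuration does not match the "
                f"classifier encoder; differing keys: {diffs}"
            )
        for k in self.encoder.encoder_param_names():
            self.params[k].data = np.asarray(state[k], dtype=self.params[k].data.dtype)

    # -- forward --------------------------------------------------------------

    def logits(self, x_np: np.ndarray) -> nn.Tensor:
        feats = self.encoder.encode(nn.Tensor(x_np))
        # scale-free pooled features: pretraining may change the encoder's
        # activation scale arbitrarily, the head must not care
        h = nn.layer_norm(nn.global_avg_pool(feats[-1]))
        h = nn.relu(nn.linear(h, self.params["head.fc1.w"], self.params["head.fc1.b"]))
        return nn.linear(h, self.params["head.fc2.w"], self.params["head.fc2.b"])

    def predict_proba(self, x_np: np.ndarray) -> np.ndarray:
        """(N, 2) class probabilities in CLASS_TO_INDEX order; no tape kept."""
        logits = self.logits(np.asarray(x_np))
        probs = nn.autograd.softmax(logits.data)
        nn.autograd.release_graph(logits)
        return probs


def build_classifier(encoder_cfg: EncoderConfig, hidden_width: int = 128,
                     pretrained_checkpoint=None) -> ConvClassifier:
    model = ConvClassifier(encoder_cfg, hidden_width=hidden_width)
    if pretrained_checkpoint is not None:
        model.load_pretrained_encoder(pretrained_checkpoint)
    return model


@dataclass
class FinetuneResult:
    model: ConvClassifier
    history: pd.DataFrame        # epoch, train_loss, val_loss, val_accuracy, lr
    best: dict                   # epoch, val_accuracy
    checkpoint_path: str | None


def _as_batch(subjects) -> tuple[np.ndarray, np.ndarray, list]:
    xs, ys, ids = [], [], []
    for s in subjects:
        vol = s.volume if hasattr(s, "volume") else s
        arr = vol.channels if isinstance(vol, MultiContrastVolume) else np.asarray(vol)
        xs.append(arr)
        ys.append(CLASS_TO_INDEX[s.class_label] if hasattr(s, "class_label") else -1)
        ids.append(getattr(s, "subject_id", f"sub-{len(ids):03d}"))
    return np.stack(xs), np.asarray(ys), ids


def train_finetune(model: ConvClassifier, splits: dict, cfg: FinetuneConfig,
                   out_dir=None) -> FinetuneResult:
    """Fine-tune on ``splits['train']``, monitor ``splits['val']``.

    ``splits`` maps split names to sequences of subjects (anything with
    ``.volume`` and ``.class_label``).  The test split, if present, is never
    touched.  Returns the best-validation-accuracy model (earliest epoch on
    ties) together with the per-epoch history including the learning-rate
    trace.
    """
    for name in ("train", "val"):
        subjects = splits.get(name, [])
        classes = {s.class_label for s in subjects}
        if classes != {"A", "B"}:
            raise ValueError(f"split {name!r} must contain both classes, has {sorted(classes)}")
    x_train, y_train, _ = _as_batch(splits["train"])
    x_val, y_val, _ = _as_batch(splits["val"])

    opt = nn.AdamW(model.parameters(), lr=cfg.lr_init, weight_decay=cfg.weight_decay)
    rng = rng_from(cfg.seed, 31)
    rows = []
    best = {"val_accuracy": -np.inf, "epoch": -1, "state": None}
    for epoch in range(cfg.epochs):
        lr = nn.cosine_decay(cfg.lr_init, cfg.lr_floor, epoch, cfg.epochs)
        opt.lr = lr
        perm = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(x_train), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            logits = model.logits(x_train[idx])
            loss = nn.cross_entropy(logits, y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        probs = model.predict_proba(x_val)
        val_loss = float(-np.log(np.clip(probs[np.arange(len(y_val)), y_val], 1e-12, None)).mean())
        val_acc = float((probs.argmax(axis=1) == y_val).mean())
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss, "val_accuracy": val_acc, "lr": lr})
        if val_acc > best["val_accuracy"]:
            best = {"val_accuracy": val_acc, "epoch": epoch, "state": model.state_dict()}
    history = pd.DataFrame(rows)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    ckpt_path = None
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt_path = str(out_dir / "finetune_best.npz")
        cfg_dict = model.cfg.to_dict()
        cfg_dict["hidden_width"] = model.hidden_width
        save_checkpoint(ckpt_path, model.state_dict(), cfg_dict, history)
        history.to_csv(out_dir / "finetune_history.csv", index=False)
    return FinetuneResult(model, history,
                          {"epoch": best["epoch"], "val_accuracy": best["val_accuracy"]},
                          ckpt_path)


def predict(model: ConvClassifier, subjects, batch_size: int = 8) -> pd.DataFrame:
    """Per-subject prediction records; score is the probability of class A."""
    x, y, ids = _as_batch(subjects)
    grid = tuple(x.shape[2:])
    f = 2 ** model.cfg.n_downsamples
    if any(d % f for d in grid):
        raise ValueError(f"volume grid {grid} does not match the model's stride {f}")
    rows = []
    for start in range(0, len(x), batch_size):
        probs = model.predict_proba(x[start:start + batch_size])
        for i, p in enumerate(probs):
            j = start + i
            pred = INDEX_TO_CLASS[int(p.argmax())]
            rows.append({
                "subject_id": ids[j],
                "true_label": INDEX_TO_CLASS[int(y[j])] if y[j] >= 0 else "",
                "predicted_label": pred,
                "score": float(p[CLASS_TO_INDEX[POSITIVE_CLASS]]),
            })
    return pd.DataFrame(rows)
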