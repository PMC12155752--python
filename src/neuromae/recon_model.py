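"""Masked-reconstruction autoencoder, hybrid loss and pretraining loop.

The pretext task: each 3-channel volume is corrupted with an independent
block mask per channel (two independent corruptions per sample), the
U-shaped autoencoder reconstructs the full volume from each corruption, and
the hybrid loss couples reconstruction fidelity with cross-corruption
consistency::

    L_total = L_recon * (1 + L_contrast)

where ``L_recon`` is the mean absolute error between original and
reconstruction (averaged over the two corruptions) and ``L_contrast`` is the
discrepancy between the pair of reconstructions of the same sample under the
two different masking draws (mean absolute difference by default).

The encoder produces a feature pyramid whose stage ``i`` representation has
shape ``(X/2^i, Y/2^i, Z/2^i)`` with ``2^(i-1) * C`` feature maps (``C``
maps at stages 0 and 1).  The decoder upsamples back through skip
connections, and a 1x1x1 convolution with a sigmoid produces reconstructions
in (0, 1).  The encoder is detachable for downstream fine-tuning.

The test profile uses a plain convolutional pyramid honouring the same
stage-shape contract; ``depths``/``num_heads`` are retained as configuration
metadata for attention-based variants of the backbone and do not change the
convolutional profile.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import nn
from ._seeds import derive_seed, rng_from
from .masking import ChannelMaskSet, MaskScheme, make_channel_masks
from .volume_io import MultiContrastVolume

__all__ = [
    "EncoderConfig", "LossTerms", "PretrainConfig", "ReconQuality",
    "ConvAutoencoder", "build_autoencoder", "stage_shapes",
    "recon_loss", "contrast_loss", "total_loss", "ssim3d", "psnr",
    "pretrain_step", "train_pretrain", "PretrainResult",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class EncoderConfig:
    """Backbone hyperparameters.

    ``feature_size`` is the stage-0 channel width C (24 at paper scale, 8 in
    the desk-scale test profile).  ``n_downsamples`` sets the pyramid depth:
    stages 0..n_downsamples, so the input grid must be divisible by
    ``2**n_downsamples``.
    """

    feature_size: int = 24
    depths: tuple = (2, 2, 2, 2)
    num_heads: tuple = (3, 6, 12, 24)
    input_grid: tuple = (128, 128, 64)
    window_size: int = 7
    n_downsamples: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("depths", "num_heads", "input_grid"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EncoderConfig":
        d = dict(d)
        for k in ("depths", "num_heads", "input_grid"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def stage_channels(feature_size: int, i: int) -> int:
    """Feature maps at stage i: C for i in {0, 1}, 2^(i-1) * C beyond."""
    return feature_size if i <= 1 else feature_size * 2 ** (i - 1)


def stage_shapes(cfg: EncoderConfig, input_grid=None) -> list:
    """Per-stage representation shapes (X/2^i, Y/2^i, Z/2^i, channels)."""
    grid = tuple(input_grid or cfg.input_grid)
    shapes = []
    for i in range(cfg.n_downsamples + 1):
        f = 2 ** i
        for ax, d in enumerate(grid):
            if d % f:
                raise ValueError(
                    f"input grid dimension {d} (axis {ax}) is not divisible by "
                    f"2^{cfg.n_downsamples} = {2 ** cfg.n_downsamples}"
                )
        shapes.append(tuple(d // f for d in grid) + (stage_channels(cfg.feature_size, i),))
    return shapes


@dataclass
class LossTerms:
    l_recon: float
    l_contrast: float
    l_total: float


@dataclass
class ReconQuality:
    ssim: float
    psnr: float


@dataclass
class PretrainConfig:
    """Self-supervised pretraining schedule (Adam, fixed learning rate)."""

    learning_rate: float = 1e-4
    epochs: int = 500
    eval_interval: int = 5
    batch_size: int = 4
    seed: int = 0
    held_out_test_size: int = 500
    mask_scheme: MaskScheme = field(default_factory=MaskScheme)


class ConvAutoencoder:
    """U-shaped convolutional masked autoencoder on the numpy autodiff core."""

    def __init__(self, cfg: EncoderConfig):
        self.cfg = cfg
        rng = rng_from(cfg.seed)
        self.params: dict[str, nn.Tensor] = {}
        C = cfg.feature_size
        n = cfg.n_downsamples
        self.ch = [stage_channels(C, i) for i in range(n + 1)]

        def conv_param(name, cout, cin, k):
            std = np.sqrt(2.0 / (cin * k ** 3))
            self.params[f"{name}.w"] = nn.Tensor(
                rng.normal(0.0, std, size=(cout, cin, k, k, k)), requires_grad=True,
                name=f"{name}.w")
            self.params[f"{name}.b"] = nn.Tensor(
                np.zeros(cout), requires_grad=True, name=f"{name}.b")

        conv_param("enc0", self.ch[0], 3, 3)
        for i in range(1, n + 1):
            conv_param(f"enc{i}", self.ch[i], self.ch[i - 1], 3)
        for i in range(n - 1, -1, -1):
            conv_param(f"dec{i}", self.ch[i], self.ch[i + 1] + self.ch[i], 3)
        conv_param("out", 3, self.ch[0], 1)

    # -- parameter bookkeeping ------------------------------------------------

    def parameters(self):
        return list(self.params.values())

    def encoder_param_names(self):
        return [k for k in self.params if k.startswith("enc")]

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        missing = set(self.params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, v in self.params.items():
            v.data = np.array(state[k], dtype=np.float64)

    # -- forward passes -------------------------------------------------------

    def _p(self, name):
        return self.params[f"{name}.w"], self.params[f"{name}.b"]

    def encode(self, x: nn.Tensor) -> list:
        """Feature pyramid; stage i obeys the stage-shape contract."""
        feats = []
        w, b = self._p("enc0")
        h = nn.relu(nn.conv3d(x, w, b, stride=1, padding=1))
        feats.append(h)
        for i in range(1, self.cfg.n_downsamples + 1):
            w, b = self._p(f"enc{i}")
            h = nn.relu(nn.conv3d(h, w, b, stride=2, padding=1))
            feats.append(h)
        return feats

    def forward(self, x_np: np.ndarray) -> tuple[nn.Tensor, list]:
        """Reconstruct a batch (N, 3, X, Y, Z); returns (recon, features)."""
        self._check_grid(x_np.shape[2:])
        x = nn.Tensor(x_np)
        feats = self.encode(x)
        h = feats[-1]
        for i in range(self.cfg.n_downsamples - 1, -1, -1):
            w, b = self._p(f"dec{i}")
            h = nn.relu(nn.conv3d(nn.concat_channels(nn.upsample2(h), feats[i]),
                                  w, b, stride=1, padding=1))
        w, b = self._p("out")
        recon = nn.sigmoid(nn.conv3d(h, w, b, stride=1, padding=0))
        return recon, feats

    def _check_grid(self, grid) -> None:
        f = 2 ** self.cfg.n_downsamples
        for ax, d in enumerate(grid):
            if d % f:
                raise ValueError(
                    f"input grid dimension {d} (axis {ax}) is not divisible by "
                    f"2^{self.cfg.n_downsamples} = {f}"
                )

    def stage_shapes(self, input_grid=None) -> list:
        return stage_shapes(self.cfg, input_grid)


def build_autoencoder(cfg: EncoderConfig) -> ConvAutoencoder:
    """Validate the grid/depth combination and construct the autoencoder."""
    stage_shapes(cfg)  # raises with the offending dimension named
    return ConvAutoencoder(cfg)


# ---------------------------------------------------------------------------
# losses and reconstruction-quality metrics
# ---------------------------------------------------------------------------

def _as_array(x) -> np.ndarray:
    if isinstance(x, MultiContrastVolume):
        return x.channels
    return np.asarray(x, dtype=np.float64)


def recon_loss(original, reconstruction) -> float:
    """Mean absolute error between corresponding voxels, all channels."""
    a, b = _as_array(original), _as_array(reconstruction)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def contrast_loss(recon_a, recon_b) -> float:
    """Discrepancy between two reconstructions of one sample (mean |diff|)."""
    return recon_loss(recon_a, recon_b)


def total_loss(l_recon: float, l_contrast: float) -> float:
    """Hybrid loss: L_recon * (1 + L_contrast)."""
    if l_recon < 0 or l_contrast < 0:
        raise ValueError("loss terms must be non-negative")
    return l_recon * (1.0 + l_contrast)


def ssim3d(x, y, sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03,
           data_range: float = 1.0, truncate: float = 3.5) -> float:
    """Structural similarity with Gaussian weighting in 3D.

    Computed per channel for (3, X, Y, Z) inputs and averaged; plain 3D
    arrays are handled as a single channel.  Population (Wang et al.)
    covariance normalisation; the border affected by filter padding is
    cropped before averaging.
    """
    a, b = _as_array(x), _as_array(y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if a.ndim == 4:
        return float(np.mean([
            ssim3d(a[c], b[c], sigma=sigma, k1=k1, k2=k2,
                   data_range=data_range, truncate=truncate)
            for c in range(a.shape[0])
        ]))
    r = int(truncate * sigma + 0.5)
    filt = lambda v: gaussian_filter(v, sigma=sigma, truncate=truncate, mode="reflect")  # noqa: E731
    ux, uy = filt(a), filt(b)
    vx = filt(a * a) - ux * ux
    vy = filt(b * b) - uy * uy
    vxy = filt(a * b) - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    core = s[tuple(slice(r, d - r) for d in s.shape)]
    return float(core.mean())


def psnr(x, y, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the volumes coincide."""
    a, b = _as_array(x), _as_array(y)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    mse = float(((a - b) ** 2).mean())
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(max_value ** 2 / mse))


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------

def _batch_channel_masks(shape, scheme: MaskScheme, n: int, seed: int) -> np.ndarray:
    """(n, 3, X, Y, Z) boolean masks, one independent ChannelMaskSet per sample."""
    return np.stack([
        make_channel_masks(
            shape,
            MaskScheme(scheme.n_blocks, scheme.block_edge, scheme.fill_value,
                       seed=derive_seed(seed, i)),
        ).masks
        for i in range(n)
    ])


def pretrain_step(model: ConvAutoencoder, batch: np.ndarray, scheme: MaskScheme,
                  seed: int, mask_seed_pair=None):
    """One pretext step: two independent corruptions, paired reconstruction.

    Returns ``(LossTerms, total_tensor)``; call ``total_tensor.backward()``
    and an optimiser step to train.  Inputs must be normalised to [0, 1].
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 5 or batch.shape[1] != 3:
        raise ValueError(f"expected batch of shape (N, 3, X, Y, Z), got {batch.shape}")
    if batch.min() < 0.0 or batch.max() > 1.0:
        raise ValueError("pretraining inputs must be normalised to [0, 1]")
    n = batch.shape[0]
    grid = batch.shape[2:]
    if mask_seed_pair is None:
        mask_seed_pair = (derive_seed(seed, 0), derive_seed(seed, 1))
    masks1 = _batch_channel_masks(grid, scheme, n, mask_seed_pair[0])
    masks2 = _batch_channel_masks(grid, scheme, n, mask_seed_pair[1])
    x1, x2 = batch.copy(), batch.copy()
    x1[masks1] = scheme.fill_value
    x2[masks2] = scheme.fill_value

    target = nn.Tensor(batch)
    r1, _ = model.forward(x1)
    r2, _ = model.forward(x2)
    l_recon = 0.5 * (nn.l1_loss(r1, target) + nn.l1_loss(r2, target))
    l_contrast = nn.l1_loss(r1, r2)
    l_total = l_recon * (1.0 + l_contrast)
    terms = LossTerms(l_recon.item(), l_contrast.item(), l_total.item())
    return terms, l_total


@dataclass
class PretrainResult:
    model: ConvAutoencoder
    history: pd.DataFrame
    baseline: ReconQuality          # held-out quality of the untrained model
    baseline_l_recon: float         # held-out L1 of the untrained model
    best: dict
    checkpoint_path: str | None


def _eval_recon(model: ConvAutoencoder, vols: np.ndarray, scheme: MaskScheme,
                seed: int) -> tuple[ReconQuality, float]:
    ssims, psnrs, l1s = [], [], []
    for i, v in enumerate(vols):
        masks = _batch_channel_masks(v.shape[1:], scheme, 1, derive_seed(seed, i))[0]
        x = v.copy()
        x[masks] = scheme.fill_value
        r, _ = model.forward(x[None])
        rec = r.data[0].copy()
        nn.autograd.release_graph(r)
        ssims.append(ssim3d(v, rec))
        p = psnr(v, rec)
        psnrs.append(p if np.isfinite(p) else 100.0)
        l1s.append(recon_loss(v, rec))
    return ReconQuality(float(np.mean(ssims)), float(np.mean(psnrs))), float(np.mean(l1s))


def train_pretrain(model: ConvAutoencoder, volumes, cfg: PretrainConfig,
                   out_dir=None) -> PretrainResult:
    """Self-supervised pretraining with held-out reconstruction evaluation.

    ``volumes`` is a sequence of normalised volumes (arrays of shape
    (3, X, Y, Z) or :class:`MultiContrastVolume`).  ``held_out_test_size``
    volumes (seeded shuffle) are excluded from every update and used only
    for SSIM/PSNR evaluation at ``eval_interval`` epochs; the weights with
    the best held-out SSIM are restored at the end and, when ``out_dir`` is
    given, persisted as a checkpoint archive together with the history.
    """
    arrs = np.stack([_as_array(v) for v in volumes])
    n_total = len(arrs)
    n_test = int(cfg.held_out_test_size)
    if n_test <= 0 or n_test >= n_total:
        raise ValueError("held_out_test_size must leave both splits non-empty")
    order = rng_from(cfg.seed, 17).permutation(n_total)
    test, train = arrs[order[:n_test]], arrs[order[n_test:]]

    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    scheme = cfg.mask_scheme
    eval_seed = derive_seed(cfg.seed, 999)
    baseline, baseline_l1 = _eval_recon(model, test, scheme, eval_seed)

    eval_epochs = sorted(set(
        list(range(cfg.eval_interval, cfg.epochs + 1, cfg.eval_interval)) + [cfg.epochs]
    ))
    rows = []
    best = {"ssim": -np.inf, "epoch": -1, "state": None}
    rng = rng_from(cfg.seed, 23)
    step = 0
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(len(train))
        ep_terms = []
        for start in range(0, len(train), cfg.batch_size):
            batch = train[perm[start:start + cfg.batch_size]]
            terms, loss = pretrain_step(model, batch, scheme, derive_seed(cfg.seed, epoch, step))
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_terms.append(terms)
            step += 1
        if epoch in eval_epochs:
            quality, held_l1 = _eval_recon(model, test, scheme, eval_seed)
            rows.append({
                "epoch": epoch,
                "l_recon": float(np.mean([t.l_recon for t in ep_terms])),
                "l_contrast": float(np.mean([t.l_contrast for t in ep_terms])),
                "l_total": float(np.mean([t.l_total for t in ep_terms])),
                "ssim": quality.ssim,
                "psnr": quality.psnr,
                "held_out_l_recon": held_l1,
            })
            if quality.ssim > best["ssim"]:
                best = {"ssim": quality.ssim, "epoch": epoch, "state": model.state_dict()}
    history = pd.DataFrame(rows)
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    ckpt_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt_path = str(out_dir / "pretrain_best.npz")
        save_checkpoint(ckpt_path, model.state_dict(), model.cfg.to_dict(), history)
        history.to_csv(out_dir / "pretrain_history.csv", index=False)
    return PretrainResult(model, history, baseline, baseline_l1,
                          {"ssim": best["ssim"], "epoch": best["epoch"]}, ckpt_path)


# ---------------------------------------------------------------------------
# checkpoint archive: weights + config + history in one .npz
# ---------------------------------------------------------------------------

def save_checkpoint(path, state: dict, config: dict, history: pd.DataFrame | None = None) -> None:
    payload = {f"param/{k}": v for k, v in state.items()}
    payload["__config__"] = np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8
    )
    csv = history.to_csv(index=False) if history is not None else ""
    payload["__history__"] = np.frombuffer(csv.encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path):
    """Returns (state_dict, config_dict, history DataFrame or None)."""
    with np.load(path) as z:
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        config = json.loads(bytes(z["__config__"]).decode())
        csv = bytes(z["__history__"]).decode()
    history = pd.read_csv(io.StringIO(csv)) if csv.strip() else None
    return state, config, history
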