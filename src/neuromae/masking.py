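"""Per-channel random block masks for the cross-contrast pretext task.

The pretraining corruption hides axis-aligned cubic blocks — by default 84
blocks of 16 x 16 x 16 voxels on the 128 x 128 x 64 network grid — drawn
uniformly over all placements fully inside the grid, independently for each
of the three contrast channels.  Because each channel loses different
regions, recovering a masked region can draw on context both within the
channel and across the other contrasts at the same location.

Blocks may overlap, so the masked fraction is below ``n_blocks * edge^3 /
n_voxels``; :func:`masked_fractions` reports both the whole-grid and the
within-brain fraction (the paper-scale default covers at most 32.8 % of the
grid, i.e. roughly 40 % of brain content).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed, rng_from
from .volume_io import MultiContrastVolume

__all__ = [
    "MaskScheme",
    "ChannelMaskSet",
    "make_mask",
    "make_channel_masks",
    "apply_mask",
    "masked_fractions",
]


@dataclass
class MaskScheme:
    """Block-mask parameters: count, edge length, fill value and seed."""

    n_blocks: int = 84
    block_edge: int = 16
    fill_value: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        if self.block_edge < 1:
            raise ValueError("block_edge must be >= 1")


@dataclass
class ChannelMaskSet:
    """One boolean mask per contrast channel (independent draws)."""

    masks: np.ndarray = field(repr=False)  # (3, X, Y, Z) bool
    scheme: MaskScheme | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.masks.shape[1:])


def _check_fit(shape, edge: int) -> None:
    if any(edge > s for s in shape):
        raise ValueError(
            f"block edge {edge} exceeds grid dimension(s) in shape {tuple(shape)}"
        )


def make_mask(shape, scheme: MaskScheme, seed: int | None = None) -> np.ndarray:
    """Draw one boolean block mask; corner offsets uniform over full-inside placements."""
    shape = tuple(int(s) for s in shape)
    _check_fit(shape, scheme.block_edge)
    rng = rng_from(scheme.seed if seed is None else seed)
    mask = np.zeros(shape, dtype=bool)
    e = scheme.block_edge
    highs = [s - e + 1 for s in shape]
    for _ in range(scheme.n_blocks):
        x, y, z = (rng.integers(0, h) for h in highs)
        mask[x:x + e, y:y + e, z:z + e] = True
    return mask


def make_channel_masks(shape, scheme: MaskScheme) -> ChannelMaskSet:
    """Three independent block-mask draws, one per channel, sub-seeded per channel."""
    masks = np.stack(
        [make_mask(shape, scheme, seed=derive_seed(scheme.seed, ch)) for ch in range(3)]
    )
    return ChannelMaskSet(masks=masks, scheme=scheme)


def apply_mask(vol: MultiContrastVolume, cms: ChannelMaskSet,
               fill_value: float | None = None) -> MultiContrastVolume:
    """Fill masked voxels per channel; unmasked voxels are untouched (pure)."""
    if cms.shape != vol.grid_shape:
        raise ValueError(f"mask grid {cms.shape} != volume grid {vol.grid_shape}")
    if fill_value is None:
        fill_value = cms.scheme.fill_value if cms.scheme is not None else 0.0
    out = vol.copy()
    out.channels[cms.masks] = fill_value
    return out


def masked_fractions(cms: ChannelMaskSet, brain_mask: np.ndarray | None = None):
    """Per-channel masked fraction of the whole grid and, optionally, of the brain."""
    n = cms.masks[0].size
    whole = cms.masks.reshape(3, -1).sum(axis=1) / n
    if brain_mask is None:
        return whole, None
    brain_mask = np.asarray(brain_mask, dtype=bool)
    nb = brain_mask.sum()
    within = np.array([
        (cms.masks[c] & brain_mask).sum() / nb if nb else np.nan for c in range(3)
    ])
    return whole, within
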