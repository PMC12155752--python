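"""Multi-contrast volume container, NIFTI I/O and canonicalisation.

A subject is represented as three co-registered 3D intensity channels in the
fixed order T1-weighted, T2-weighted, FLAIR on a single voxel grid.  On disk
this is a 4D NIFTI file with the three contrasts stacked along the fourth
axis.  The preprocessing chain mirrors the standard clinical pipeline:
adaptive resampling to a common resolution, multiplication with a
(precomputed) brain mask, per-channel min–max intensity normalisation and a
trilinear resize to the network grid.  Skull stripping and cross-contrast
registration are accepted as precomputed inputs and are not performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

CHANNEL_NAMES = ("t1", "t2", "flair")

__all__ = [
    "CHANNEL_NAMES",
    "MultiContrastVolume",
    "read_volume",
    "write_volume",
    "concatenate_channels",
    "split_channels",
    "resample_adaptive",
    "apply_brain_mask",
    "normalize_intensity",
    "resize_to_grid",
]


@dataclass
class MultiContrastVolume:
    """Three co-registered intensity channels (T1, T2, FLAIR) on one grid.

    Parameters
    ----------
    channels : ndarray, shape (3, X, Y, Z)
        Intensity data, channel-first.
    spacing_mm : tuple of float
        Voxel size along each spatial axis in millimetres.
    provenance : str
        Free-text source tag (file path, generator spec, ...).
    """

    channels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: str = ""
    _skip_validation: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self._skip_validation:
            return
        if self.channels.ndim != 4 or self.channels.shape[0] != 3:
            raise ValueError(
                "expected channel-first array of shape (3, X, Y, Z), got "
                f"{self.channels.shape}"
            )
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("volume contains non-finite voxels")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.channels.shape[1:])

    def copy(self) -> "MultiContrastVolume":
        return MultiContrastVolume(
            self.channels.copy(), self.spacing_mm, self.provenance, _skip_validation=True
        )


def read_volume(path) -> MultiContrastVolume:
    """Read a 4D NIFTI file with three volumes (T1, T2, FLAIR) on axis 3."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4 or data.shape[3] != 3:
        raise ValueError(
            f"{path}: expected a 4D NIFTI with 3 volumes on the 4th axis, "
            f"got shape {data.shape}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MultiContrastVolume(
        np.moveaxis(data, 3, 0), spacing_mm=spacing, provenance=str(path)
    )


def write_volume(vol: MultiContrastVolume, path) -> None:
    """Write a :class:`MultiContrastVolume` as a 4D NIFTI file."""
    data = np.moveaxis(vol.channels, 0, 3).astype(np.float32)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(vol.spacing_mm) + (1.0,))
    nib.save(img, str(path))


def concatenate_channels(t1: np.ndarray, t2: np.ndarray, flair: np.ndarray,
                         spacing_mm=(1.0, 1.0, 1.0)) -> MultiContrastVolume:
    """Stack single-contrast grids into one volume in T1, T2, FLAIR order."""
    grids = {"t1": np.asarray(t1), "t2": np.asarray(t2), "flair": np.asarray(flair)}
    ref = grids["t1"].shape
    for name, g in grids.items():
        if g.ndim != 3:
            raise ValueError(f"{name}: expected a 3D grid, got ndim={g.ndim}")
        if g.shape != ref:
            raise ValueError(
                f"shape mismatch for contrast '{name}': {g.shape} vs t1 {ref}"
            )
    return MultiContrastVolume(
        np.stack([grids["t1"], grids["t2"], grids["flair"]]), spacing_mm=spacing_mm
    )


def split_channels(vol: MultiContrastVolume):
    """Inverse of :func:`concatenate_channels`; returns (t1, t2, flair)."""
    return tuple(vol.channels[i].copy() for i in range(3))


def _trilinear_resample(grid: np.ndarray, in_shape, out_shape, scale) -> np.ndarray:
    # Voxel-centre convention: output voxel i sits at physical (i + 0.5) * new
    # spacing; its input index is that position divided by old spacing, minus
    # the half-voxel offset.
    coords = []
    for ax in range(3):
        out_idx = np.arange(out_shape[ax], dtype=np.float64)
        coords.append((out_idx + 0.5) * scale[ax] - 0.5)
    mesh = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(
        np.asarray(grid, dtype=np.float64), np.stack(mesh), order=1, mode="nearest"
    )


def resample_adaptive(channel_grid: np.ndarray, spacing_mm, acquisition_kind: str):
    """Resample one contrast to the protocol resolution.

    Volumetric T1 acquisitions go to 1 mm isotropic; planar (2D-acquired)
    contrasts are resampled to 0.8 x 0.8 mm in plane with the slice spacing
    left untouched.  Interpolation is trilinear; the output grid covers the
    input's physical extent.

    Returns
    -------
    (resampled_grid, new_spacing_mm)
    """
    spacing = tuple(float(s) for s in spacing_mm)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    if acquisition_kind == "volumetric_t1":
        new_spacing = (1.0, 1.0, 1.0)
    elif acquisition_kind == "planar":
        new_spacing = (0.8, 0.8, spacing[2])
    else:
        raise ValueError(f"unknown acquisition kind {acquisition_kind!r}")
    grid = np.asarray(channel_grid, dtype=np.float64)
    in_shape = grid.shape
    out_shape = tuple(
        int(np.ceil(in_shape[ax] * spacing[ax] / new_spacing[ax] - 1e-9))
        for ax in range(3)
    )
    scale = tuple(new_spacing[ax] / spacing[ax] for ax in range(3))
    return _trilinear_resample(grid, in_shape, out_shape, scale), new_spacing


def apply_brain_mask(vol: MultiContrastVolume, mask: np.ndarray) -> MultiContrastVolume:
    """Zero every voxel outside the (precomputed) brain mask, all channels."""
    mask = np.asarray(mask)
    if mask.shape != vol.grid_shape:
        raise ValueError(f"mask shape {mask.shape} != volume grid {vol.grid_shape}")
    out = vol.copy()
    out.channels *= mask.astype(bool)[None]
    return out


def normalize_intensity(vol: MultiContrastVolume,
                        mask: np.ndarray | None = None) -> MultiContrastVolume:
    """Min–max normalise each channel onto [0, 1] over brain voxels.

    Skull-stripped backgrounds are exact zeros, so normalisation statistics
    are computed over brain voxels only; when no explicit mask is given, the
    brain is taken as the voxels that are non-zero in *any* channel (which
    makes repeated normalisation a no-op).  Background voxels stay exactly 0.
    A constant non-zero channel is mapped to 0 with a warning.
    """
    out = vol.copy()
    if mask is None:
        mask = np.any(vol.channels != 0, axis=0)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vol.grid_shape:
            raise ValueError(f"mask shape {mask.shape} != volume grid {vol.grid_shape}")
    for c in range(3):
        ch = out.channels[c]
        vals = ch[mask]
        if vals.size == 0:
            continue
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            if hi != 0.0:
                warnings.warn(
                    f"channel {CHANNEL_NAMES[c]} is constant ({hi}); mapped to 0",
                    RuntimeWarning,
                    stacklevel=2,
                )
            ch[mask] = 0.0
        else:
            ch[mask] = (vals - lo) / (hi - lo)
        ch[~mask] = 0.0
    return out


def resize_to_grid(vol: MultiContrastVolume, target_shape) -> MultiContrastVolume:
    """Trilinear resize of every channel to ``target_shape``.

    Values are clipped back to [0, 1] when the input already lay in that
    range, so a normalised volume stays normalised.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 4 for t in target_shape):
        raise ValueError(f"target dims must all be >= 4, got {target_shape}")
    in_shape = vol.grid_shape
    was_unit = vol.channels.min() >= 0.0 and vol.channels.max() <= 1.0
    scale = tuple(in_shape[ax] / target_shape[ax] for ax in range(3))
    chans = np.stack(
        [_trilinear_resample(vol.channels[c], in_shape, target_shape, scale)
         for c in range(3)]
    )
    if was_unit:
        np.clip(chans, 0.0, 1.0, out=chans)
    new_spacing = tuple(
        vol.spacing_mm[ax] * in_shape[ax] / target_shape[ax] for ax in range(3)
    )
    return MultiContrastVolume(chans, spacing_mm=new_spacing, provenance=vol.provenance)
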