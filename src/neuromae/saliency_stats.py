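"""Occlusion saliency and the group-statistics chain.

Per subject, an occlusion-sensitivity map measures how much the predicted
probability of the subject's true class drops when a cubic patch is hidden
(filled with the background value) at each position of a stride lattice;
overlapping contributions are averaged per voxel.  Group analysis then
follows the standard neuroimaging chain on the shared grid: Gaussian
smoothing of the per-subject maps, a voxelwise two-sample GLM contrast
(pooled-variance t, group A minus group B), threshold-free cluster
enhancement (TFCE) of the t map, and family-wise error control by the
max-statistic permutation test over group relabelings.

TFCE integrates cluster extent^E times height^H over all thresholds::

    TFCE(v) = sum_h e(v, h)^E * h^H * dh,   h in (0, max],

with E = 0.5, H = 2, 26-connectivity and dh = max / n_steps by default (the
field-standard choices).  Negative statistic values are enhanced by applying
TFCE to the negated map and recombining with sign, so both group directions
are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
import warnings

import numpy as np
from scipy import ndimage

from ._seeds import rng_from

__all__ = [
    "OcclusionParams", "SaliencyMap", "TfceParams", "GroupStatsResult",
    "occlusion_map", "smooth_map", "glm_group_contrast", "tfce",
    "permutation_fwer",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass
class OcclusionParams:
    """Occlusion patch geometry: cube edge, lattice stride, fill value."""

    patch_edge: int = 16
    stride: int = 8
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.patch_edge < 1 or self.stride < 1:
            raise ValueError("patch_edge and stride must be >= 1")


@dataclass
class SaliencyMap:
    values: np.ndarray
    subject_id: str = ""
    group: str = ""


@dataclass
class TfceParams:
    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 26

    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}.get(self.connectivity)
        if rank is None:
            raise ValueError(f"connectivity must be 6, 18 or 26, got {self.connectivity}")
        return ndimage.generate_binary_structure(3, rank)


@dataclass
class GroupStatsResult:
    t_map: np.ndarray
    tfce_map: np.ndarray
    p_map_fwer: np.ndarray
    sig_mask: np.ndarray
    null_max: np.ndarray = field(default=None, repr=False)


def _lattice(dim: int, edge: int, stride: int) -> list[int]:
    """Stride-lattice corner offsets, always including the flush-end position."""
    last = dim - edge
    offs = list(range(0, last + 1, stride))
    if offs[-1] != last:
        offs.append(last)
    return offs


def occlusion_map(model, volume, true_label, params: OcclusionParams | None = None,
                  batch_size: int = 16) -> SaliencyMap:
    """Occlusion-sensitivity map of one subject.

    ``model`` must expose ``predict_proba(batch) -> (N, 2)`` probabilities
    and the class order of :data:`neuromae.classifier.CLASS_TO_INDEX`;
    ``volume`` is (3, X, Y, Z) (or has ``.channels``).  For every patch
    position, the contribution is P(true) - P(true | patch hidden in all
    channels); per-voxel contributions are averaged over the patches
    covering the voxel.
    """
    from .classifier import CLASS_TO_INDEX

    params = params or OcclusionParams()
    arr = np.asarray(getattr(volume, "channels", volume), dtype=np.float64)
    grid = arr.shape[1:]
    e = params.patch_edge
    if any(e > d for d in grid):
        raise ValueError(f"patch edge {e} larger than grid {grid}")
    cls = CLASS_TO_INDEX[true_label] if isinstance(true_label, str) else int(true_label)

    corners = [(x, y, z)
               for x in _lattice(grid[0], e, params.stride)
               for y in _lattice(grid[1], e, params.stride)
               for z in _lattice(grid[2], e, params.stride)]
    base = float(model.predict_proba(arr[None])[0, cls])

    acc = np.zeros(grid)
    cover = np.zeros(grid)
    for start in range(0, len(corners), batch_size):
        chunk = corners[start:start + batch_size]
        batch = np.repeat(arr[None], len(chunk), axis=0)
        for i, (x, y, z) in enumerate(chunk):
            batch[i, :, x:x + e, y:y + e, z:z + e] = params.fill_value
        probs = model.predict_proba(batch)[:, cls]
        for i, (x, y, z) in enumerate(chunk):
            acc[x:x + e, y:y + e, z:z + e] += base - float(probs[i])
            cover[x:x + e, y:y + e, z:z + e] += 1.0
    with np.errstate(invalid="ignore"):
        values = np.where(cover > 0, acc / np.maximum(cover, 1), 0.0)
    return SaliencyMap(values=values)


def smooth_map(map_values: np.ndarray | SaliencyMap, fwhm_voxels: float) -> np.ndarray:
    """Gaussian smoothing with sigma = FWHM / 2.3548 (reflective padding)."""
    if fwhm_voxels < 0:
        raise ValueError("fwhm must be >= 0")
    vals = np.asarray(getattr(map_values, "values", map_values), dtype=np.float64)
    if fwhm_voxels == 0:
        return vals.copy()
    sigma = fwhm_voxels / FWHM_TO_SIGMA
    return ndimage.gaussian_filter(vals, sigma=sigma, mode="reflect")


def glm_group_contrast(maps_a, maps_b):
    """Voxelwise two-sample pooled-variance t statistic for group A - B.

    Returns ``(t_map, zero_variance_mask)``; voxels with zero pooled
    variance get t = 0 and are flagged in the mask.
    """
    a = np.stack([np.asarray(getattr(m, "values", m)) for m in maps_a])
    b = np.stack([np.asarray(getattr(m, "values", m)) for m in maps_b])
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError(f"need >= 2 maps per group, got {na} and {nb}")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se2 = pooled * (1.0 / na + 1.0 / nb)
    zero_var = se2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
    t[zero_var] = 0.0
    return t, zero_var


def _tfce_positive(stat: np.ndarray, params: TfceParams) -> np.ndarray:
    out = np.zeros_like(stat, dtype=np.float64)
    peak = float(stat.max(initial=0.0))
    if peak <= 0:
        return out
    struct = params.structure()
    dh = peak / params.n_steps
    flat = out.ravel()
    for step in range(1, params.n_steps + 1):
        h = step * dh
        sup = stat >= h
        if not sup.any():
            break
        lab, n = ndimage.label(sup, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        contrib = np.zeros(n + 1)
        contrib[1:] = sizes[1:] ** params.E * h ** params.H * dh
        flat += contrib[lab.ravel()]
    return out


def tfce(stat_map: np.ndarray, params: TfceParams | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement, signed for two-sided maps."""
    params = params or TfceParams()
    stat = np.asarray(stat_map, dtype=np.float64)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic map contains non-finite values")
    return _tfce_positive(stat, params) - _tfce_positive(-stat, params)


def permutation_fwer(maps_a, maps_b, n_perm: int, seed: int,
                     tfce_params: TfceParams | None = None,
                     alpha: float = 0.05) -> GroupStatsResult:
    """Max-statistic permutation FWER correction of the GLM + TFCE chain.

    The observed pipeline is ``glm_group_contrast`` followed by :func:`tfce`;
    the null distribution records the image-wide maximum |TFCE| under
    ``n_perm`` random relabelings of group membership.  Corrected
    ``p(v) = (1 + #{perm max >= |TFCE_obs(v)|}) / (n_perm + 1)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    tfce_params = tfce_params or TfceParams()
    a = np.stack([np.asarray(getattr(m, "values", m)) for m in maps_a])
    b = np.stack([np.asarray(getattr(m, "values", m)) for m in maps_b])
    na, nb = len(a), len(b)
    n_distinct = comb(na + nb, na)
    if n_distinct < 20:
        warnings.warn(
            f"only {n_distinct} distinct relabelings; the attainable minimum "
            f"corrected p is {1.0 / min(n_perm + 1, n_distinct):.4f}",
            RuntimeWarning, stacklevel=2,
        )

    t_obs, _ = glm_group_contrast(a, b)
    tfce_obs = tfce(t_obs, tfce_params)

    stacked = np.concatenate([a, b])
    rng = rng_from(seed, 404)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(na + nb)
        t_p, _ = glm_group_contrast(stacked[perm[:na]], stacked[perm[na:]])
        null_max[i] = np.abs(tfce(t_p, tfce_params)).max()

    obs_abs = np.abs(tfce_obs)
    # p(v) via sorted null: count of null maxima >= observed value
    order = np.sort(null_max)
    ge = len(order) - np.searchsorted(order, obs_abs.ravel(), side="left")
    p = ((1.0 + ge) / (n_perm + 1.0)).reshape(obs_abs.shape)
    return GroupStatsResult(
        t_map=t_obs, tfce_map=tfce_obs, p_map_fwer=p,
        sig_mask=p < alpha, null_max=null_max,
    )
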