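"""Synthetic multi-contrast phantom cohorts with a two-class structural effect.

Clinical multi-contrast MRI of parkinsonian syndromes is not publicly
distributable, so the package ships a procedural stand-in: each subject is a
tissue label map built from ellipsoidal shells (CSF ventricle, grey-matter
shell, white-matter core, a brainstem-like midline core and a
cerebellum-like posterior mass), rendered into three contrast channels with
channel-specific tissue intensity tables, Gaussian noise and a smooth
multiplicative bias field.  The two classes differ by a localised
morphological effect: class B (PPS-like) dilates the ventricle and erodes
the midline core, class A (PD-like) thins the posterior mass.  The voxels
altered by the effect are recorded per subject as a ground-truth lesion mask
against which the saliency statistics can be validated.

The rendering deliberately gives the three channels *different* tissue rank
orders, so that recovering a masked region of one channel from the other
channels is informative — the property the cross-contrast pretext task needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._seeds import derive_seed, rng_from
from .volume_io import MultiContrastVolume, normalize_intensity

__all__ = [
    "LABELS",
    "CONTRAST_LUT",
    "TissueLabelMap",
    "PhantomSubject",
    "CohortSpec",
    "PhantomCohort",
    "generate_tissue_map",
    "apply_class_effect",
    "render_contrasts",
    "generate_cohort",
    "split_sizes",
]

#: Tissue labels used throughout the package.
LABELS = {
    "background": 0,
    "ventricle": 1,   # CSF
    "grey_matter": 2,
    "white_matter": 3,
    "midline_core": 4,   # brainstem-like
    "posterior_mass": 5,  # cerebellum-like
}

#: Mean intensity per (channel, tissue label).  Rows are T1, T2, FLAIR;
#: columns are labels 0..5.  The tissue rank order differs between channels
#: (e.g. CSF is darkest on T1/FLAIR but brightest on T2), so no channel is a
#: monotone function of another.
CONTRAST_LUT = np.array(
    [
        # bg   CSF   GM    WM    core  posterior
        [0.0, 0.15, 0.55, 0.85, 0.75, 0.60],   # T1
        [0.0, 0.95, 0.65, 0.35, 0.45, 0.60],   # T2
        [0.0, 0.10, 0.80, 0.50, 0.60, 0.70],   # FLAIR
    ]
)


@dataclass
class TissueLabelMap:
    """Integer tissue segmentation on a voxel grid."""

    labels: np.ndarray
    shape: tuple[int, int, int]
    seed: int

    def copy(self) -> "TissueLabelMap":
        return TissueLabelMap(self.labels.copy(), self.shape, self.seed)


@dataclass
class PhantomSubject:
    """One synthetic subject: rendered volume, class label, lesion ground truth."""

    subject_id: str
    volume: MultiContrastVolume
    class_label: str                 # "A" (PD-like) or "B" (PPS-like)
    lesion_mask: np.ndarray          # boolean, voxels altered by the class effect
    subject_seed: int
    split: str = ""                  # train / val / test


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    n_per_class: int = 40
    effect_size: float = 1.0
    noise_sd: float = 0.05
    bias_field_amplitude: float = 0.1
    shape: tuple[int, int, int] = (32, 32, 16)
    split_ratios: tuple[float, float, float] = (8.0, 1.0, 1.0)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.split_ratios):
            raise ValueError(f"split ratios must be non-negative, got {self.split_ratios}")
        if sum(self.split_ratios) <= 0:
            raise ValueError("split ratios must not all be zero")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0 or self.bias_field_amplitude < 0:
            raise ValueError("noise_sd and bias_field_amplitude must be >= 0")


@dataclass
class PhantomCohort:
    spec: CohortSpec
    subjects: list[PhantomSubject] = field(default_factory=list)

    def split(self, name: str) -> list[PhantomSubject]:
        return [s for s in self.subjects if s.split == name]


def _ellipsoid(coords, center, radii) -> np.ndarray:
    u, v, w = coords
    return (
        ((u - center[0]) / radii[0]) ** 2
        + ((v - center[1]) / radii[1]) ** 2
        + ((w - center[2]) / radii[2]) ** 2
    ) <= 1.0


def generate_tissue_map(shape, seed: int) -> TissueLabelMap:
    """Build a procedural six-tissue label map.

    Deterministic per (shape, seed): the RNG only jitters the structure
    radii and centres slightly so different subjects differ anatomically.
    The non-background voxels always form a single connected brain.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 16 for s in shape):
        raise ValueError(
            f"every grid dimension must be >= 16 to place all six tissue classes, got {shape}"
        )
    rng = rng_from(seed)
    jit = lambda s: rng.uniform(-s, s)  # noqa: E731

    # Normalised voxel-centre coordinates in [-1, 1] per axis.
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    coords = np.meshgrid(*axes, indexing="ij")

    labels = np.zeros(shape, dtype=np.int8)
    brain_c = (jit(0.03), jit(0.03), jit(0.03))
    brain_r = (0.92 + jit(0.03), 0.92 + jit(0.03), 0.90 + jit(0.03))
    brain = _ellipsoid(coords, brain_c, brain_r)
    labels[brain] = LABELS["grey_matter"]

    wm = _ellipsoid(coords, brain_c, tuple(0.72 * r for r in brain_r))
    labels[wm] = LABELS["white_matter"]

    # Cerebellum-like posterior-inferior mass (+v is posterior, -w inferior).
    post = _ellipsoid(
        coords,
        (brain_c[0] + jit(0.02), 0.52 + jit(0.03), -0.42 + jit(0.03)),
        (0.42, 0.34, 0.30),
    )
    labels[post & brain] = LABELS["posterior_mass"]

    # Brainstem-like midline core: a central column extending inferiorly.
    u, v, w = coords
    core = (
        (np.abs(u - brain_c[0]) <= 0.14 + jit(0.01))
        & (np.abs(v - (0.10 + jit(0.02))) <= 0.22)
        & (w <= 0.05)
        & (w >= -0.75)
    )
    labels[core & brain] = LABELS["midline_core"]

    vent = _ellipsoid(
        coords,
        (brain_c[0] + jit(0.01), -0.10 + jit(0.02), 0.18 + jit(0.02)),
        (0.22, 0.26, 0.22),
    )
    labels[vent & brain] = LABELS["ventricle"]

    tmap = TissueLabelMap(labels, shape, int(seed))
    frac = np.count_nonzero(labels) / labels.size
    if not (0.2 <= frac <= 0.9):
        raise RuntimeError(f"brain fraction {frac:.3f} outside [0.2, 0.9]")
    missing = set(LABELS.values()) - set(np.unique(labels).tolist())
    if missing:
        raise RuntimeError(f"labels missing from generated map: {sorted(missing)}")
    return tmap


def _graded_morph(target: np.ndarray, allowed: np.ndarray, steps: float,
                  rng: np.random.Generator, grow: bool) -> np.ndarray:
    """Grow or shrink a region by a possibly fractional number of dilation steps.

    The integer part applies full morphological steps; the fractional
    remainder flips a random subset of the next boundary layer, drawn with a
    per-voxel uniform threshold so the flipped set grows monotonically with
    the remainder at a fixed RNG state.
    """
    region = target.copy()
    n_full = int(np.floor(steps))
    frac = steps - n_full
    struct = ndimage.generate_binary_structure(3, 1)
    for _ in range(n_full):
        if grow:
            region = ndimage.binary_dilation(region, struct) & allowed
        else:
            region = ndimage.binary_erosion(region, struct)
    if frac > 0:
        if grow:
            layer = (ndimage.binary_dilation(region, struct) & allowed) & ~region
        else:
            layer = region & ~ndimage.binary_erosion(region, struct)
        u = rng.random(region.shape)
        flip = layer & (u < frac)
        region = (region | flip) if grow else (region & ~flip)
    return region


def apply_class_effect(tmap: TissueLabelMap, class_label: str, effect_size: float,
                       seed: int):
    """Apply the class-specific morphological effect to a tissue map.

    Class B (PPS-like) dilates the ventricle into surrounding brain tissue
    and erodes the midline core; class A (PD-like) thins the posterior mass.
    The number of morphological steps is ``2 * effect_size`` (fractional
    steps flip a seeded random boundary subset).  Returns the modified map
    and a boolean lesion mask of exactly the changed voxels.
    """
    if class_label not in ("A", "B"):
        raise ValueError(f"unknown class label {class_label!r}; expected 'A' or 'B'")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    out = tmap.copy()
    if effect_size == 0:
        return out, np.zeros(tmap.labels.shape, dtype=bool)
    rng = rng_from(seed)
    labels = out.labels
    brain = labels > 0
    steps = 2.0 * float(effect_size)
    if class_label == "B":
        vent = labels == LABELS["ventricle"]
        grown = _graded_morph(vent, brain, steps, rng, grow=True)
        labels[grown & ~vent] = LABELS["ventricle"]
        core = labels == LABELS["midline_core"]
        shrunk = _graded_morph(core, brain, steps, rng, grow=False)
        labels[core & ~shrunk] = LABELS["white_matter"]
    else:
        post = labels == LABELS["posterior_mass"]
        shrunk = _graded_morph(post, brain, steps, rng, grow=False)
        labels[post & ~shrunk] = LABELS["grey_matter"]
    lesion = labels != tmap.labels
    return out, lesion


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias: 1 + amplitude * low-frequency field in [-1, 1]."""
    if amplitude == 0:
        return np.ones(shape)
    noise = rng.standard_normal(shape)
    sigma = [max(2.0, s / 4.0) for s in shape]
    field = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    peak = np.abs(field).max()
    if peak > 0:
        field /= peak
    return 1.0 + amplitude * field


def render_contrasts(tmap: TissueLabelMap, noise_sd: float,
                     bias_field_amplitude: float, seed: int) -> MultiContrastVolume:
    """Render a tissue map into a T1/T2/FLAIR volume.

    Each channel assigns its tissue mean from :data:`CONTRAST_LUT`, adds
    Gaussian noise inside the brain, multiplies by a smooth bias field and
    is then min–max normalised over brain voxels to [0, 1].  Background
    stays exactly 0.
    """
    if noise_sd < 0 or bias_field_amplitude < 0:
        raise ValueError("noise_sd and bias_field_amplitude must be >= 0")
    rng = rng_from(seed)
    labels = tmap.labels
    brain = labels > 0
    chans = np.empty((3,) + labels.shape)
    for c in range(3):
        ch = CONTRAST_LUT[c][labels].astype(np.float64)
        if noise_sd > 0:
            ch[brain] += rng.normal(0.0, noise_sd, size=int(brain.sum()))
        ch *= _bias_field(labels.shape, bias_field_amplitude, rng)
        ch[~brain] = 0.0
        chans[c] = ch
    vol = MultiContrastVolume(
        chans, provenance=f"phantom(seed={tmap.seed}, render_seed={seed})"
    )
    return normalize_intensity(vol, mask=brain)


def split_sizes(n: int, ratios) -> tuple[int, int, int]:
    """Per-class split sizes by largest-remainder apportionment (train/val/test)."""
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios < 0):
        raise ValueError(f"split ratios must be non-negative, got {tuple(ratios)}")
    probs = ratios / ratios.sum()
    raw = probs * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return tuple(int(b) for b in base)


def generate_cohort(spec: CohortSpec) -> PhantomCohort:
    """Generate a two-class cohort with a stratified, seeded 8:1:1-style split.

    Per-subject seeds are derived from ``master_seed`` and the subject index,
    so cohorts of any size are reproducible and extendable.
    """
    if spec.n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    cohort = PhantomCohort(spec)
    split_names = ("train", "val", "test")
    sizes = split_sizes(spec.n_per_class, spec.split_ratios)
    for class_idx, class_label in enumerate(("A", "B")):
        split_assign = np.concatenate(
            [np.full(sz, i) for i, sz in enumerate(sizes)]
        )
        rng_from(spec.master_seed, 1000 + class_idx).shuffle(split_assign)
        for j in range(spec.n_per_class):
            idx = class_idx * spec.n_per_class + j
            sseed = derive_seed(spec.master_seed, idx)
            tmap = generate_tissue_map(spec.shape, sseed)
            tmap, lesion = apply_class_effect(
                tmap, class_label, spec.effect_size, derive_seed(sseed, 1)
            )
            vol = render_contrasts(
                tmap, spec.noise_sd, spec.bias_field_amplitude, derive_seed(sseed, 2)
            )
            cohort.subjects.append(
                PhantomSubject(
                    subject_id=f"sub-{class_label}{j:03d}",
                    volume=vol,
                    class_label=class_label,
                    lesion_mask=lesion,
                    subject_seed=sseed,
                    split=split_names[int(split_assign[j])],
                )
            )
    return cohort
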