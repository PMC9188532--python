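"""Synthetic bilateral limb cross-section phantoms.

Generates 2D grayscale slices that mimic axial gradient-echo MRI of the thighs
or lower legs, together with per-muscle integer label maps.  Each slice shows
two limbs (left/right of the vertical midline); a limb is an elliptical body
with a bright subcutaneous fat ring, one (thigh) or two (leg) bone discs with
a dark cortical rim and bright marrow, and K angular-sector muscle
compartments arranged around the main bone.  A tunable *severity* parameter
mixes muscle intensity toward fat through a smooth, patchy random field,
emulating fatty replacement of dystrophic muscle; mild and severe disease
states map to low and high severity.

Labels: 0 = background (including fat and bone), 1..K = the K muscles, with
the same label assigned to the homologous compartment on both sides.  A thigh
slice therefore carries 13 classes (background + 12 muscles), a leg slice 7.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomConfig", "AnnotatedSlice", "generate_slice", "generate_dataset"]

#: number of muscle compartments per side, fixed by the anatomical district
MUSCLES_PER_SIDE = {"thigh": 12, "leg": 6}
#: number of bone cross-sections per side (femur vs tibia+fibula)
BONES_PER_SIDE = {"thigh": 1, "leg": 2}

# intensity conventions (arbitrary units on [0, 1] before noise/bias)
_FAT_INTENSITY = 0.92
_MUSCLE_INTENSITY = 0.30
_MARROW_INTENSITY = 0.85
_CORTICAL_INTENSITY = 0.05
_BACKGROUND_INTENSITY = 0.02


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of one synthetic limb slice.

    ``muscles_per_side`` and ``bones_per_side`` are forced by ``district``
    (thigh: 12 muscles around one femur; leg: 6 muscles around tibia+fibula)
    and cannot be overridden.  ``severity`` in [0, 1] is the mean fraction of
    muscle signal replaced by fat-like signal: 0 emulates a healthy subject,
    values >= 0.6 the severely fat-replaced disease subgroup.
    """

    district: str = "thigh"
    image_size: int = 432
    severity: float = 0.0
    noise_sd: float = 0.01
    bias_field_amplitude: float = 0.1
    seed: int = 0
    muscles_per_side: int = field(init=False)
    bones_per_side: int = field(init=False)

    def __post_init__(self) -> None:
        if self.district not in MUSCLES_PER_SIDE:
            raise ValueError(f"unknown district {self.district!r}; expected 'thigh' or 'leg'")
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must lie in [0, 1], got {self.severity}")
        if self.image_size < 64:
            raise ValueError(
                f"image_size {self.image_size} too small to place two limbs (minimum 64)"
            )
        object.__setattr__(self, "muscles_per_side", MUSCLES_PER_SIDE[self.district])
        object.__setattr__(self, "bones_per_side", BONES_PER_SIDE[self.district])

    @property
    def n_classes(self) -> int:
        """Total label classes including background (13 thigh, 7 leg)."""
        return self.muscles_per_side + 1

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class AnnotatedSlice:
    """An intensity image with its muscle label map and provenance."""

    image: np.ndarray
    labels: np.ndarray
    district: str
    severity: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape != self.labels.shape:
            raise ValueError(
                f"image shape {self.image.shape} != labels shape {self.labels.shape}"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be an integer array")

    @property
    def n_classes(self) -> int:
        return MUSCLES_PER_SIDE[self.district] + 1


def _ellipse_mask(shape, center, semi_axes, angle=0.0):
    """Boolean mask of a (possibly rotated) filled ellipse."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def _severity_field(shape, mean, rng, corr_px):
    """Smooth random field on [0, 1] with the requested spatial mean.

    Patchy fatty infiltration: correlated Gaussian noise is squashed through a
    logistic, then shifted multiplicatively to the target mean.
    """
    if mean <= 0:
        return np.zeros(shape)
    if mean >= 1:
        return np.ones(shape)
    raw = gaussian_filter(rng.standard_normal(shape), sigma=corr_px)
    raw /= max(raw.std(), 1e-9)
    f = 1.0 / (1.0 + np.exp(-2.0 * raw))
    # bisection on a global shift to hit the requested mean exactly
    lo, hi = -8.0, 8.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        m = np.mean(1.0 / (1.0 + np.exp(-(2.0 * raw + mid))))
        if m < mean:
            lo = mid
        else:
            hi = mid
    return 1.0 / (1.0 + np.exp(-(2.0 * raw + 0.5 * (lo + hi))))


def _draw_limb(image, labels, fat_mix, config, center, semi_axes, rng, sector_phase):
    """Paint one limb (outer contour, fat ring, bones, muscle sectors) in place."""
    s = config.image_size
    shape = (s, s)
    outer = _ellipse_mask(shape, center, semi_axes)
    ring = 0.13 + 0.05 * rng.random()  # subcutaneous fat ring thickness (fraction)
    inner = _ellipse_mask(shape, center, (semi_axes[0] * (1 - ring), semi_axes[1] * (1 - ring)))

    image[outer] = _FAT_INTENSITY
    image[inner] = _MUSCLE_INTENSITY

    # bones: thigh = single femur near the centre; leg = tibia (large,
    # anterior-medial) and fibula (small, lateral)
    if config.district == "thigh":
        bone_centers = [
            (
                center[0] - 0.12 * semi_axes[0] + rng.uniform(-1, 1) * 0.02 * s,
                center[1] + rng.uniform(-1, 1) * 0.02 * s,
            )
        ]
        bone_radii = [0.16 * min(semi_axes)]
    else:
        lateral = 1.0 if center[1] > s / 2 else -1.0
        bone_centers = [
            (center[0] - 0.25 * semi_axes[0], center[1] - lateral * 0.15 * semi_axes[1]),
            (center[0] - 0.05 * semi_axes[0], center[1] + lateral * 0.55 * semi_axes[1]),
        ]
        bone_radii = [0.22 * min(semi_axes), 0.09 * min(semi_axes)]

    bone_mask = np.zeros(shape, dtype=bool)
    for (bc, br) in zip(bone_centers, bone_radii):
        cortical = _ellipse_mask(shape, bc, (br, br))
        marrow = _ellipse_mask(shape, bc, (br * 0.62, br * 0.62))
        image[cortical & inner] = _CORTICAL_INTENSITY
        image[marrow & inner] = _MARROW_INTENSITY
        bone_mask |= cortical

    # muscles: K angular sectors around the main bone, separated by thin
    # background (fascia) gaps, restricted to an annulus inside the fat ring
    K = config.muscles_per_side
    rr, cc = np.mgrid[0:s, 0:s]
    theta = np.arctan2(rr - bone_centers[0][0], cc - bone_centers[0][1])
    muscle_zone = (
        _ellipse_mask(shape, center, (semi_axes[0] * (1 - ring - 0.04), semi_axes[1] * (1 - ring - 0.04)))
        & ~_dilate_bool(bone_mask, 2)
    )
    edges = np.linspace(-np.pi, np.pi, K + 1) + sector_phase
    gap = 0.035  # fascia gap half-width in radians
    for k in range(K):
        a0, a1 = edges[k], edges[k + 1]
        ang = np.mod(theta - a0, 2 * np.pi)
        width = np.mod(a1 - a0, 2 * np.pi)
        sector = (ang > gap) & (ang < width - gap)
        labels[sector & muscle_zone] = k + 1

    # fatty replacement: mix muscle pixels toward fat intensity
    limb_muscle = labels > 0
    region = limb_muscle & inner
    image[region] = (
        image[region] * (1 - fat_mix[region]) + _FAT_INTENSITY * fat_mix[region]
    )
    return outer, bone_mask


def _dilate_bool(mask, n):
    from scipy.ndimage import binary_dilation

    return binary_dilation(mask, iterations=n)


def generate_slice(config: PhantomConfig, *, _jitter=None) -> AnnotatedSlice:
    """Generate one annotated bilateral limb slice.

    Deterministic given ``config`` (including its seed).  ``_jitter`` is used
    internally by :func:`generate_dataset` to vary limb pose across slices.
    """
    s = config.image_size
    rng = np.random.default_rng(config.seed)
    jit = _jitter or {}

    image = np.full((s, s), _BACKGROUND_INTENSITY)
    labels = np.zeros((s, s), dtype=np.int16)

    # limb geometry: two ellipses left/right of the vertical midline
    base_r = s * (0.30 if config.district == "thigh" else 0.26)
    elong = 1.0 if config.district == "thigh" else 1.25  # legs are taller than wide
    scale = jit.get("scale", 1.0)
    severity = jit.get("severity", config.severity)
    fat_mix = _severity_field((s, s), severity, rng, corr_px=max(2.0, s / 30))

    for side, col_frac in (("left", 0.25), ("right", 0.75)):
        center = (
            s * 0.5 + jit.get(f"{side}_dr", 0.0) * s,
            s * col_frac + jit.get(f"{side}_dc", 0.0) * s,
        )
        semi = (base_r * elong * scale, base_r * 0.70 * scale)
        phase = jit.get(f"{side}_phase", 0.0) + rng.uniform(-0.05, 0.05)
        _draw_limb(image, labels, fat_mix, config, center, semi, rng, phase)

    # image-only corruptions: smooth multiplicative bias field + Gaussian noise
    if config.bias_field_amplitude > 0:
        bias = gaussian_filter(rng.standard_normal((s, s)), sigma=s / 4)
        bias /= max(np.abs(bias).max(), 1e-9)
        image = image * (1.0 + config.bias_field_amplitude * bias)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, (s, s))
    image = np.clip(image, 0.0, 1.0)

    missing = set(range(config.n_classes)) - set(np.unique(labels).tolist())
    if missing:
        raise RuntimeError(
            f"phantom geometry degenerate: classes {sorted(missing)} absent "
            f"(image_size={s}, jitter={jit})"
        )
    return AnnotatedSlice(
        image=image,
        labels=labels,
        district=config.district,
        severity=float(severity),
        provenance={"seed": config.seed, "config_hash": config.config_hash(), "jitter": jit},
    )


def generate_dataset(
    config: PhantomConfig,
    n: int,
    seed: int | None = None,
    severity_range: tuple[float, float] | None = None,
) -> list[AnnotatedSlice]:
    """Generate ``n`` slices with reproducible per-slice pose/severity jitter.

    Limb position, size, sector orientation and (optionally) severity are
    jittered per slice; per-slice seeds derive from the master ``seed`` so the
    whole dataset is bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for i in range(n):
        slice_seed = int(master.integers(0, 2**31 - 1))
        jrng = np.random.default_rng(slice_seed)
        jit = {
            "scale": float(jrng.uniform(0.90, 1.02)),
            "left_dr": float(jrng.uniform(-0.02, 0.02)),
            "left_dc": float(jrng.uniform(-0.015, 0.015)),
            "right_dr": float(jrng.uniform(-0.02, 0.02)),
            "right_dc": float(jrng.uniform(-0.015, 0.015)),
            "left_phase": float(jrng.uniform(-0.25, 0.25)),
            "right_phase": float(jrng.uniform(-0.25, 0.25)),
        }
        if severity_range is not None:
            jit["severity"] = float(jrng.uniform(*severity_range))
        cfg_i = dataclasses.replace(config, seed=slice_seed)
        out.append(generate_slice(cfg_i, _jitter=jit))
    return out
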