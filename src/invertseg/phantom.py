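"""Seeded synthetic abdominal phantom: CT-like, T1w-like, T2wfs-like + truth.

Each phantom case is one synthetic subject: three co-registered volumes
(CT-like, T1-weighted-like, T2-weighted-fat-saturated-like) over a
shared ground-truth label map containing paired kidneys, a renal lesion
of controllable volume, water-rich organs, fat, muscle, bone, lungs and
background air.

The phantom emulates the *intensity structure* that makes CT-to-MRI
model transfer work, not anatomy:

* CT-like means are ordered air << lung < fat < soft organs <
  contrast-aorta < bone (HU-like units).
* T1w-like means follow a monotone *decreasing* map of tissue density
  for non-air tissue (fat brightest, bone dark), so the soft-tissue
  ordering is reversed relative to CT; intensity inversion within the
  volume range therefore restores a CT-like ordering.
* T2wfs-like means put water-rich organs (kidneys, spleen, gallbladder,
  lesion) highest while fat and bone stay low (fat saturation).

Geometry is procedural (ellipsoids/cylinders at plausible relative
positions, jittered per seed); organs are positioned in fractional
coordinates of the physical extent so any grid shape/spacing works.
A Gaussian point-spread smoothing produces partial-volume voxels at
structure borders, a smooth multiplicative bias field and additive
Gaussian noise perturb the body; background air is noise-free (exactly
0 in the MR-like volumes, -1000 in the CT-like volume), emulating the
tight background plateau of magnitude MR images.  The lesion is placed
inside the requested kidney with CT/T2wfs-distinct but T1w-subtle
contrast; lung intensities straddle the background-zeroing threshold so
inversion with background zeroing partially blanks the lungs.

Everything is driven by ``PhantomSpec`` and fully deterministic per
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import LabelMap, Volume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "tissue_mean_intensities",
    "PHANTOM_CLASSES",
    "NON_AIR_CLASSES",
]


def _load_tissue_table() -> dict:
    text = resources.files("invertseg").joinpath("data/phantom_tissues.json").read_text()
    return json.loads(text)


_TISSUES = _load_tissue_table()
PHANTOM_CLASSES: dict[int, str] = {int(row["id"]): row["name"] for row in _TISSUES["classes"]}
_BY_NAME = {row["name"]: row for row in _TISSUES["classes"]}
_BACKGROUND = _TISSUES["background"]

# Tissues used for the cross-modality rank-correlation mechanism check:
# everything except background air and the air-filled lungs.
NON_AIR_CLASSES: tuple[str, ...] = tuple(
    row["name"] for row in _TISSUES["classes"] if not row["name"].startswith("lung")
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``tumor_volume_cm3`` is the target physical lesion volume; the
    realized voxel volume is matched to within 10% (or generation
    fails).  ``noise_sd`` is in intensity units (HU-like), applied
    inside the body only; ``bias_amplitude`` scales a smooth
    multiplicative field; ``psf_sigma_mm`` is the Gaussian
    point-spread blur producing partial-volume border voxels.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumor_volume_cm3: float = 29.0
    tumor_side: str = "left"
    noise_sd: float = 8.0
    bias_amplitude: float = 0.015
    psf_sigma_mm: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 ints >= 8, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive values, got {self.spacing_mm}")
        if self.tumor_volume_cm3 <= 0:
            raise ValueError("tumor_volume_cm3 must be positive")
        if self.tumor_side not in ("left", "right"):
            raise ValueError(f"tumor_side must be 'left' or 'right', got {self.tumor_side!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.bias_amplitude < 1:
            raise ValueError("bias_amplitude must lie in [0, 1)")


@dataclass
class PhantomCase:
    """One synthetic subject: three modalities plus ground truth."""

    case_id: str
    ct: Volume
    t1: Volume
    t2fs: Volume
    truth: LabelMap
    spec: PhantomSpec

    @property
    def realized_tumor_volume_cm3(self) -> float:
        return self.truth.class_volume_cm3(self.truth.id_of("tumor"))

    def volume(self, sequence: str) -> Volume:
        return {"CT": self.ct, "T1w": self.t1, "T2wfs": self.t2fs}[sequence]


# Organ geometry in fractional coordinates of the physical extent.
# Under the canonical affine the first axis increases toward patient
# right, so patient-left structures sit at fractions < 0.5.
_ELLIPSOIDS = {
    # name: (center_frac, semi_axes_frac)
    "lung_left": ((0.35, 0.45, 0.86), (0.11, 0.13, 0.10)),
    "lung_right": ((0.65, 0.45, 0.86), (0.11, 0.13, 0.10)),
    "liver": ((0.68, 0.42, 0.62), (0.16, 0.15, 0.14)),
    "spleen": ((0.27, 0.40, 0.64), (0.09, 0.09, 0.10)),
    "gallbladder": ((0.60, 0.30, 0.50), (0.05, 0.04, 0.06)),
    "kidney_left": ((0.30, 0.62, 0.40), (0.085, 0.065, 0.15)),
    "kidney_right": ((0.70, 0.62, 0.40), (0.085, 0.065, 0.15)),
}
_CYLINDERS = {
    # name: (center_xy_frac, radius_frac_of_x_extent, z_lo_frac, z_hi_frac)
    "aorta": ((0.50, 0.52), 0.050, 0.08, 0.92),
    "bone": ((0.50, 0.78), 0.070, 0.05, 0.95),
    "muscle_left": ((0.36, 0.74), 0.055, 0.05, 0.95),
    "muscle_right": ((0.64, 0.74), 0.055, 0.05, 0.95),
}
_BODY_SEMI_FRAC = (0.46, 0.38)  # elliptical cylinder, full z extent
_PAINT_ORDER = [
    "muscle_left", "muscle_right", "bone", "aorta",
    "lung_left", "lung_right", "liver", "spleen", "gallbladder",
    "kidney_left", "kidney_right",
]
_CLASS_OF_SHAPE = {name: name for name in _ELLIPSOIDS}
_CLASS_OF_SHAPE.update({"muscle_left": "muscle", "muscle_right": "muscle",
                        "aorta": "aorta", "bone": "bone"})


def _physical_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _jitter(rng: np.random.Generator, amount: float = 0.10) -> float:
    return 1.0 + amount * rng.uniform(-1.0, 1.0)


def _build_truth(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    extent = np.asarray(shape) * spacing
    X, Y, Z = _physical_grids(shape, spacing)
    cx, cy, cz = extent / 2.0

    body_ax = _BODY_SEMI_FRAC[0] * extent[0] * _jitter(rng, 0.05)
    body_ay = _BODY_SEMI_FRAC[1] * extent[1] * _jitter(rng, 0.05)
    body = np.broadcast_to(
        ((X - cx) / body_ax) ** 2 + ((Y - cy) / body_ay) ** 2 <= 1.0, shape)

    labels = np.zeros(shape, dtype=np.int16)
    fat_id = next(i for i, n in PHANTOM_CLASSES.items() if n == "fat")
    labels[body] = fat_id

    centers: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for name in _PAINT_ORDER:
        if name in _ELLIPSOIDS:
            (fx, fy, fz), (sx, sy, sz) = _ELLIPSOIDS[name]
            center = np.array([
                cx + (fx - 0.5) * extent[0] * _jitter(rng),
                cy + (fy - 0.5) * extent[1] * _jitter(rng),
                cz + (fz - 0.5) * extent[2] * _jitter(rng),
            ])
            semi = np.array([sx * extent[0] * _jitter(rng),
                             sy * extent[1] * _jitter(rng),
                             sz * extent[2] * _jitter(rng)])
            mask = (((X - center[0]) / semi[0]) ** 2
                    + ((Y - center[1]) / semi[1]) ** 2
                    + ((Z - center[2]) / semi[2]) ** 2) <= 1.0
            centers[name] = center
        else:
            (fx, fy), rfrac, zlo, zhi = _CYLINDERS[name]
            center = np.array([cx + (fx - 0.5) * extent[0] * _jitter(rng),
                               cy + (fy - 0.5) * extent[1] * _jitter(rng)])
            radius = rfrac * extent[0] * _jitter(rng)
            mask = ((((X - center[0]) / radius) ** 2 + ((Y - center[1]) / radius) ** 2 <= 1.0)
                    & (Z >= zlo * extent[2]) & (Z <= zhi * extent[2]))
            centers[name] = center
        mask &= body
        masks[name] = mask
        labels[mask] = next(i for i, n in PHANTOM_CLASSES.items()
                            if n == _CLASS_OF_SHAPE[name])

    # lesion: sphere centered in the chosen kidney, clipped to the body;
    # radius searched so the realized voxel volume matches the target.
    kidney_name = f"kidney_{spec.tumor_side}"
    tumor_center = centers[kidney_name] + np.array([
        0.03 * extent[0] * rng.uniform(-1, 1),
        0.03 * extent[1] * rng.uniform(-1, 1),
        0.05 * extent[2] * rng.uniform(-1, 1),
    ])
    voxel_mm3 = float(np.prod(spacing))
    target_vox = spec.tumor_volume_cm3 * 1000.0 / voxel_mm3
    dist2 = ((X - tumor_center[0]) ** 2 + (Y - tumor_center[1]) ** 2
             + (Z - tumor_center[2]) ** 2)

    def count(radius: float) -> int:
        return int(np.count_nonzero((dist2 <= radius * radius) & body))

    r0 = (3.0 * spec.tumor_volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    lo_r, hi_r = 0.3 * r0, 3.0 * r0
    if count(hi_r) < target_vox:
        raise ValueError(
            f"tumor of {spec.tumor_volume_cm3} cm3 is too large to fit in the "
            f"{spec.tumor_side} kidney region of this grid"
        )
    for _ in range(40):
        mid = 0.5 * (lo_r + hi_r)
        if count(mid) < target_vox:
            lo_r = mid
        else:
            hi_r = mid
    radius = hi_r
    tumor_mask = (dist2 <= radius * radius) & body
    realized = tumor_mask.sum() * voxel_mm3 / 1000.0
    if abs(realized - spec.tumor_volume_cm3) > 0.10 * spec.tumor_volume_cm3:
        raise ValueError(
            f"could not realize tumor volume {spec.tumor_volume_cm3} cm3 "
            f"within 10% (got {realized:.2f} cm3)"
        )
    tumor_id = next(i for i, n in PHANTOM_CLASSES.items() if n == "tumor")
    labels[tumor_mask] = tumor_id
    return labels, body


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    coarse = rng.standard_normal((4, 4, 4))
    zoom = [n / 4 for n in shape]
    smooth = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    peak = np.abs(smooth).max()
    if peak > 0:
        smooth = smooth / peak
    return (1.0 + amplitude * smooth).astype(np.float32)


def _render_modality(labels: np.ndarray, key: str, spec: PhantomSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Mean image -> bias -> PSF blur -> air reset -> in-body noise."""
    air_value = float(_BACKGROUND[key])
    img = np.full(labels.shape, air_value, dtype=np.float32)
    for cid, name in PHANTOM_CLASSES.items():
        img[labels == cid] = float(_BY_NAME[name][key])

    field = _bias_field(labels.shape, spec.bias_amplitude, rng)
    if key == "ct":
        img = (img - air_value) * field + air_value
    else:
        img = img * field

    sigma_vox = np.asarray(spec.psf_sigma_mm) / np.asarray(spec.spacing_mm, dtype=float)
    if np.any(sigma_vox > 0):
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="nearest")
    img[labels == 0] = air_value

    if spec.noise_sd > 0:
        body = labels != 0
        noise = rng.standard_normal(labels.shape).astype(np.float32) * spec.noise_sd
        for cid, name in PHANTOM_CLASSES.items():
            scale = float(_BY_NAME[name].get("noise_scale", 1.0))
            if scale != 1.0:
                noise[labels == cid] *= scale
        img[body] += noise[body]
    if key != "ct":
        np.clip(img, 0.0, None, out=img)  # magnitude images are non-negative
    return img


def generate_phantom(spec: PhantomSpec, case_id: str = "case_000") -> PhantomCase:
    """Generate one synthetic subject; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    labels, _body = _build_truth(spec, rng)
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])

    volumes = {}
    for key, tag in (("ct", "CT"), ("t1", "T1w"), ("t2", "T2wfs")):
        data = _render_modality(labels, key, spec, rng)
        volumes[key] = Volume(data=data, spacing=spacing.copy(), affine=affine.copy(),
                              modality_tag=tag)
    truth = LabelMap(data=labels, spacing=spacing.copy(), affine=affine.copy(),
                     vocabulary=dict(PHANTOM_CLASSES))
    return PhantomCase(case_id=case_id, ct=volumes["ct"], t1=volumes["t1"],
                       t2fs=volumes["t2"], truth=truth, spec=spec)


def generate_cohort(
    n: int,
    master_seed: int,
    tumor_volume_range_cm3: tuple[float, float] = (1.0, 200.0),
    side_fractions: tuple[float, float] = (0.45, 0.55),
    base_spec: PhantomSpec | None = None,
) -> list[PhantomCase]:
    """Generate a deterministic cohort of phantom cases.

    Tumor volumes are drawn log-uniformly from
    ``tumor_volume_range_cm3``; sides left/right with probabilities
    ``side_fractions``; per-case seeds derive from ``master_seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    lo, hi = tumor_volume_range_cm3
    if not 0 < lo < hi:
        raise ValueError(f"tumor volume range must satisfy 0 < lo < hi, got ({lo}, {hi})")
    if abs(sum(side_fractions) - 1.0) > 1e-9 or min(side_fractions) < 0:
        raise ValueError("side_fractions must be non-negative and sum to 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(master_seed)
    volumes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    sides = np.where(rng.random(n) < side_fractions[0], "left", "right")
    seeds = rng.integers(0, 2**31 - 1, size=n)
    cases = []
    for i in range(n):
        spec = replace(base, tumor_volume_cm3=float(volumes[i]),
                       tumor_side=str(sides[i]), seed=int(seeds[i]))
        cases.append(generate_phantom(spec, case_id=f"case_{i:03d}"))
    return cases


def tissue_mean_intensities(
    volume: Volume | np.ndarray,
    truth: LabelMap,
    class_names: Sequence[str] = NON_AIR_CLASSES,
) -> dict[str, float]:
    """Mean intensity per truth class; classes with no voxels are skipped."""
    data = volume.data if isinstance(volume, Volume) else np.asarray(volume)
    means = {}
    for name in class_names:
        mask = truth.data == truth.id_of(name)
        if mask.any():
            means[name] = float(data[mask].mean())
    return means
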