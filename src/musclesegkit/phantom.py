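"""Synthetic lower-limb phantoms: seeded (MR volume, label map) pairs.

The phantom emulates the geometry and intensity structure of a knee-to-hip
T1-weighted lower-limb acquisition at isotropic 1 mm spacing: a central
dark bone cylinder, ``n_muscles`` elongated quasi-cylindrical muscle
compartments arranged as angular sectors around it, a bright subcutaneous
fat rind, smooth multiplicative intensity inhomogeneity (bias field) and
additive noise.  Compartment geometry is controlled by a small number of
smooth coefficients so that a generated cohort has a genuinely
low-dimensional shape distribution — the property the downstream shape
model is designed to recover.

Nothing here attempts anatomical fidelity or MR physics; the phantoms
exist so that the whole pipeline (shape modelling, registration,
augmentation, training, evaluation) is exercisable end-to-end at small
grid sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import LabelMap, Subject, Volume

__all__ = ["PhantomSpec", "generate_subject", "generate_cohort"]

# tissue intensity means, relative units (muscle mean defines noise scale)
_I_BACKGROUND = 0.03
_I_BONE = 0.15
_I_FAT = 1.00
_I_MUSCLE = 0.55
_I_MUSCLE_SPREAD = 0.10  # deterministic per-muscle contrast offsets


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic subject family.

    Identical specs (including ``seed``) generate bit-identical output.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 96)
    spacing_mm: float | tuple[float, float, float] = 1.0
    n_muscles: int = 16
    fat_thickness_vox: float = 3.0
    noise_sigma: float = 0.05  # relative to mean muscle intensity
    bias_field_amplitude: float = 0.2
    rician_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(g) < 16 for g in self.grid_shape):
            raise ValueError(f"grid_shape axes must all be >= 16, got {self.grid_shape}")
        if self.n_muscles < 1:
            raise ValueError("n_muscles must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _geometry(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    half = min(nx, ny) / 2.0
    limb_r = 0.88 * half
    fat_inner = limb_r - spec.fat_thickness_vox
    outer_r = fat_inner - 0.5
    inner_r = 0.30 * half
    bone_r = 0.18 * half
    return half, limb_r, fat_inner, outer_r, inner_r, bone_r


def _check_sizing(spec: PhantomSpec) -> None:
    _, _, _, outer_r, inner_r, _ = _geometry(spec)
    gap_frac = 0.12
    min_arc = 2.0 * np.pi * inner_r / spec.n_muscles * (1.0 - gap_frac)
    if outer_r - inner_r < 3.0 or min_arc < 2.0:
        raise ValueError(
            f"grid {spec.grid_shape} too small to fit {spec.n_muscles} muscle "
            f"compartments (inner arc {min_arc:.2f} vox, radial depth "
            f"{outer_r - inner_r:.2f} vox); enlarge the grid or reduce n_muscles"
        )


def generate_subject(
    spec: PhantomSpec,
    morph_jitter: float = 0.05,
    subject_id: str = "phantom",
    shape_coeff: float | None = None,
) -> Subject:
    """Generate one synthetic subject.

    Parameters
    ----------
    spec:
        Phantom parameters; the RNG is seeded from ``spec.seed`` only.
    morph_jitter:
        Scale of the per-subject low-order random modulation of compartment
        radii (angular harmonics times smooth axial profiles).  0 disables
        random shape variation entirely.
    shape_coeff:
        Optional explicit value for the single dominant shape coefficient
        (a global radial scaling of the muscle compartments).  When None it
        is drawn from N(0, morph_jitter).  Cohort generation sets this to
        realise a one-dominant-mode shape family.
    """
    _check_sizing(spec)
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    _, limb_r, fat_inner, outer_r, inner_r, bone_r = _geometry(spec)
    n = spec.n_muscles

    # dominant mode: global radial scale of the muscle annulus
    c = float(rng.normal(0.0, morph_jitter)) if shape_coeff is None else float(shape_coeff)
    # low-order residual jitter: two angular harmonics x two axial profiles
    amps = rng.normal(0.0, 0.4 * morph_jitter, size=(2, 2))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=2)

    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    x = np.arange(nx)[:, None, None] - cx
    y = np.arange(ny)[None, :, None] - cy
    z01 = np.linspace(-1.0, 1.0, nz)[None, None, :]  # limb axis coordinate
    r = np.sqrt(x * x + y * y) + 0.0 * z01  # broadcast to 3D
    theta = np.arctan2(y, x) + 0.0 * z01

    # axial taper: full radius mid-limb, rounded-off ends
    taper = np.clip(1.0 - 0.45 * np.abs(z01) ** 4, 0.55, 1.0) + 0.0 * r
    # fusiform belly profile, staggered per muscle so compartment radii vary
    # along the limb axis (muscle bellies peak at different heights)
    belly_offsets = 0.35 * np.cos(2.0 * np.pi * np.arange(n) / max(n, 1) * 3.0)
    axial = [np.ones_like(z01) + 0.0 * r, z01 + 0.0 * r]

    sector = (theta + np.pi) / (2.0 * np.pi) * n  # in [0, n]
    sector_idx = np.minimum(np.floor(sector).astype(np.int32), n - 1)
    frac = sector - sector_idx
    gap_frac = 0.12
    in_gap = (frac < gap_frac / 2.0) | (frac > 1.0 - gap_frac / 2.0)

    # radial modulation field: dominant scale + low-order harmonics
    mod = 1.0 + c
    for h in range(2):
        ang = np.cos((h + 1) * theta + phases[h])
        for a in range(2):
            mod = mod + amps[h, a] * ang * axial[a]

    belly = 0.80 + 0.20 * np.cos(np.pi * (z01 - belly_offsets[sector_idx]))
    r_out = outer_r * taper * belly * mod
    r_in = np.full_like(r_out, inner_r)

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    # terminate compartments where the annulus thins below 30% of its own
    # mid-belly thickness (and at least 1 voxel): clean fusiform ends
    # instead of sub-voxel wisps, robust to the global radial scale
    thickness = r_out - r_in
    t_max = thickness.max(axis=2, keepdims=True)
    muscle = (
        (~in_gap)
        & (r > r_in)
        & (r < r_out)
        & (thickness > np.maximum(1.0, 0.3 * t_max))
        & (np.abs(z01 + 0.0 * r) < 0.98)
    )
    labels[muscle] = sector_idx[muscle] + 1

    bone = r < bone_r
    inside_limb = r < limb_r
    labels[bone] = 0  # bone stays unlabeled (dark tissue, no muscle label)

    # intensities
    img = np.full(spec.grid_shape, _I_BACKGROUND, dtype=np.float64)
    img[inside_limb] = _I_FAT
    img[bone] = _I_BONE
    for lab in range(1, n + 1):
        # deterministic per-muscle contrast offset, fixed across subjects
        offs = _I_MUSCLE_SPREAD * (((lab * 7) % n) / max(n - 1, 1) - 0.5)
        img[labels == lab] = _I_MUSCLE + offs

    if spec.bias_field_amplitude > 0:
        img = img * _bias_field(spec, rng)

    if spec.noise_sigma > 0:
        sigma = spec.noise_sigma * _I_MUSCLE
        if spec.rician_noise:
            n1 = rng.normal(0.0, sigma, spec.grid_shape)
            n2 = rng.normal(0.0, sigma, spec.grid_shape)
            img = np.sqrt((img + n1) ** 2 + n2**2)
        else:
            img = img + rng.normal(0.0, sigma, spec.grid_shape)

    vol = Volume(img, spacing=spec.spacing_mm)
    lab_map = LabelMap(labels, spacing=spec.spacing_mm)
    return Subject(
        id=subject_id,
        volume=vol,
        labels=lab_map,
        provenance="original",
        provenance_info={"shape_coeff": c, "morph_jitter": morph_jitter},
    )


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative inhomogeneity 1 + A*b with b in [-1, 1]."""
    nx, ny, nz = spec.grid_shape
    ph = rng.uniform(0.0, 2.0 * np.pi, size=3)
    gx = np.cos(np.pi * np.arange(nx) / nx + ph[0])[:, None, None]
    gy = np.cos(np.pi * np.arange(ny) / ny + ph[1])[None, :, None]
    gz = np.cos(np.pi * np.arange(nz) / nz + ph[2])[None, None, :]
    b = (gx + gy + gz) / 3.0
    return 1.0 + spec.bias_field_amplitude * b


def generate_cohort(
    spec: PhantomSpec,
    n_subjects: int,
    seed: int | None = None,
    shape_cv: float = 0.08,
    morph_jitter: float = 0.02,
    shape_coeffs: Sequence[float] | None = None,
    id_prefix: str = "subj",
) -> list[Subject]:
    """Generate a cohort sharing topology and varying smoothly in shape.

    The dominant across-subject variation is a single radial-scale
    coefficient drawn from N(0, ``shape_cv``); ``morph_jitter`` adds small
    higher-order per-subject variation.  Per-muscle volumes consequently
    span a coefficient of variation of roughly ``2 * shape_cv``.

    Pass ``shape_coeffs`` to plant explicit shape-family coordinates (e.g.
    an exactly one-parameter family with ``morph_jitter=0``).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    base_seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    if shape_coeffs is None:
        coeffs = rng.normal(0.0, shape_cv, size=n_subjects)
    else:
        coeffs = np.asarray(shape_coeffs, dtype=float)
        if coeffs.shape != (n_subjects,):
            raise ValueError("shape_coeffs must have length n_subjects")
    subjects = []
    for k in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_spec = replace(spec, seed=sub_seed)
        subjects.append(
            generate_subject(
                sub_spec,
                morph_jitter=morph_jitter,
                subject_id=f"{id_prefix}{k:02d}",
                shape_coeff=float(coeffs[k]),
            )
        )
    return subjects
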