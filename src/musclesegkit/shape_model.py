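"""Per-muscle statistical shape models via particle correspondence + PCA.

A cohort of segmentations of the same muscle is turned into a point-based
shape model in three steps:

1. surface extraction — each binary mask becomes a dense surface point
   cloud in physical (mm) coordinates;
2. particle correspondence — ``m`` particles are placed on every surface
   and optimised so that the *ensemble* of particle vectors is compact in
   shape space while the particles on each *individual* surface stay
   spread out.  The objective is the correspondence energy

       Q = H(Z) - sum_k H(x_k)

   with H(Z) a Gaussian-model entropy of the ensemble (0.5 * log det of
   the regularised shape-space covariance) and H(x_k) a Parzen estimate
   of the particle density on shape k.  Minimising Q trades off ensemble
   compactness against per-shape uniformity;
3. PCA — after generalized Procrustes alignment (rigid, no scaling, so
   volume differences survive), the mean shape and up to N-1 orthonormal
   modes are extracted; new shapes are synthesised as
   mean + s * sqrt(eigenvalue) * mode.

Synthesised point sets can be rasterised back to binary label maps via a
signed-distance reconstruction, which is what turns shape-space samples
into registration targets for the augmentation pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .core import LabelMap, Volume

__all__ = [
    "ParticleSystem",
    "ShapeSpaceModel",
    "CorrespondenceEnergy",
    "extract_surface",
    "optimize_correspondence",
    "correspondence_energy",
    "fit_pca",
    "synthesize_shape",
    "rasterize_shape",
]

DEFAULT_PARTICLES = 1024  # particles per shape when unspecified


# ---------------------------------------------------------------------------
# types


@dataclass
class ParticleSystem:
    """N corresponding particle sets of m points each, in mm coordinates.

    ``points`` has shape (N, m, 3); particle ``i`` is homologous across
    shapes.  ``alignment`` records the rigid transforms (R, t) applied to
    each shape to reach the common frame (identity when correspondence was
    run in the native scanner frame, as this implementation does).
    """

    points: np.ndarray
    alignment: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must have shape (N, m, 3)")
        if not self.alignment:
            self.alignment = [
                (np.eye(3), np.zeros(3)) for _ in range(self.points.shape[0])
            ]

    @property
    def n_shapes(self) -> int:
        return self.points.shape[0]

    @property
    def n_particles(self) -> int:
        return self.points.shape[1]

    def as_vectors(self) -> np.ndarray:
        """(N, 3m) flattened shape vectors x_k."""
        return self.points.reshape(self.n_shapes, -1)

    def save(self, out_dir: str | Path, prefix: str = "shape") -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for k in range(self.n_shapes):
            p = out / f"{prefix}{k:03d}.particles"
            np.savetxt(p, self.points[k], fmt="%.6f")
            paths.append(p)
        return paths

    @classmethod
    def load(cls, paths: Sequence[str | Path]) -> "ParticleSystem":
        pts = np.stack([np.loadtxt(p, ndmin=2) for p in paths])
        return cls(pts)


@dataclass
class ShapeSpaceModel:
    """Mean shape + PCA modes of a corresponded cohort.

    ``mean`` and ``modes`` live in the Procrustes-aligned model frame;
    ``world_rotation``/``world_translation`` map model-frame points back to
    scanner mm coordinates (the average of the per-shape inverse alignment
    transforms).
    """

    mean: np.ndarray  # (3m,)
    modes: np.ndarray  # (K, 3m), orthonormal rows
    eigenvalues: np.ndarray  # (K,), descending, >= 0
    n_input_shapes: int
    world_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    world_translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        if tot <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / tot

    def save(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "modes": self.modes.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_input_shapes": self.n_input_shapes,
            "world_rotation": self.world_rotation.tolist(),
            "world_translation": self.world_translation.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ShapeSpaceModel":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.asarray(d["mean"]),
            modes=np.asarray(d["modes"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            n_input_shapes=int(d["n_input_shapes"]),
            world_rotation=np.asarray(d["world_rotation"]),
            world_translation=np.asarray(d["world_translation"]),
        )


@dataclass
class CorrespondenceEnergy:
    """Bookkeeping of Q = ensemble_term - sum(sample_terms)."""

    ensemble_term: float
    sample_terms: np.ndarray

    @property
    def Q(self) -> float:
        return float(self.ensemble_term - np.sum(self.sample_terms))


# ---------------------------------------------------------------------------
# surface extraction


def extract_surface(labels: LabelMap, label_id: int) -> np.ndarray:
    """Dense surface point cloud (mm) of one label, via marching cubes."""
    mask = labels.mask(label_id)
    if not mask.any():
        raise ValueError(f"label {label_id} not present in label map")
    padded = np.pad(mask.astype(np.float64), 1)
    verts, *_ = measure.marching_cubes(padded, level=0.5, spacing=labels.spacing)
    verts = verts - np.asarray(labels.spacing)  # undo pad offset
    return verts + np.asarray(labels.origin)


# ---------------------------------------------------------------------------
# correspondence energy


def _ensemble_entropy(X: np.ndarray, alpha: float) -> float:
    """0.5 * log det(Cov + alpha I) with Cov the shape-space covariance.

    Computed through the N x N Gram matrix; the (3m - N) zero eigenvalues
    contribute log(alpha) each.
    """
    n, d = X.shape
    Y = X - X.mean(axis=0)
    G = (Y @ Y.T) / max(n - 1, 1)
    mu = np.clip(np.linalg.eigvalsh(G), 0.0, None)
    return 0.5 * (np.sum(np.log(mu + alpha)) + (d - n) * np.log(alpha))


def _sample_entropy(pts: np.ndarray, sigma: float) -> float:
    """Parzen (Gaussian kernel) entropy estimate of one shape's particles."""
    m = pts.shape[0]
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
    K = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(K, 0.0)
    dens = K.sum(axis=1) / ((m - 1) * (2.0 * np.pi * sigma**2) ** 1.5)
    return float(-np.mean(np.log(dens + 1e-300)))


def correspondence_energy(
    points: np.ndarray, alpha: float, sigmas: Sequence[float]
) -> CorrespondenceEnergy:
    """Evaluate Q for an (N, m, 3) particle configuration."""
    pts = np.asarray(points, dtype=np.float64)
    X = pts.reshape(pts.shape[0], -1)
    ens = _ensemble_entropy(X, alpha)
    samp = np.array(
        [_sample_entropy(pts[k], sigmas[k]) for k in range(pts.shape[0])]
    )
    return CorrespondenceEnergy(ensemble_term=ens, sample_terms=samp)


def _ensemble_grad(X: np.ndarray, alpha: float) -> np.ndarray:
    """d H(Z) / d x_k for all shapes, via the Gram-matrix identity."""
    n = X.shape[0]
    Y = X - X.mean(axis=0)
    G = (Y.T @ Y.T.T) if False else Y @ Y.T  # (n, n)
    A = G / max(n - 1, 1) + alpha * np.eye(n)
    # (Cov + aI)^-1 Y^T = Y^T A^-1 ; gradient wrt x_k is column k / (n-1)
    W = np.linalg.solve(A, Y) / max(n - 1, 1)  # (n, 3m)
    return 0.5 * W  # 0.5 from the log-det


def _sample_grad(pts: np.ndarray, sigma: float) -> np.ndarray:
    """d H(x_k) / d particle positions for one shape (m, 3)."""
    m = pts.shape[0]
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.sum(diff**2, axis=2)
    K = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(K, 0.0)
    D = K.sum(axis=1) + 1e-300
    coef = K * (1.0 / D[:, None] + 1.0 / D[None, :])
    g = (coef[:, :, None] * diff).sum(axis=1)
    return g / (m * sigma**2)


def _mean_nn_spacing(pts: np.ndarray) -> float:
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return float(np.mean(d[:, 1]))


def _fps(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Farthest-point sampling indices."""
    n = pts.shape[0]
    idx = [int(rng.integers(n))]
    dist = np.linalg.norm(pts - pts[idx[0]], axis=1)
    for _ in range(k - 1):
        i = int(np.argmax(dist))
        idx.append(i)
        dist = np.minimum(dist, np.linalg.norm(pts - pts[i], axis=1))
    return np.asarray(idx)


def optimize_correspondence(
    surfaces: Sequence[np.ndarray],
    m: int = DEFAULT_PARTICLES,
    iters: int = 30,
    seed: int = 0,
    step0: float | None = None,
) -> tuple[ParticleSystem, list[float]]:
    """Place ``m`` corresponding particles on each of N surfaces.

    Particles start from a farthest-point sampling of the first surface
    projected onto every other surface, then are grown by splitting
    (16 -> 32 -> ... -> m) with ``iters`` projected-gradient iterations per
    level.  Steps that do not decrease Q are rejected (backtracking), so
    the returned trace of accepted Q values is non-increasing within each
    particle-count level.

    Returns the particle system and the accepted-Q trace of the final
    (full-``m``) level.
    """
    n = len(surfaces)
    if n < 2:
        raise ValueError("need at least 2 surfaces")
    if m < 4:
        raise ValueError("need at least 4 particles per shape")
    surfaces = [np.asarray(s, dtype=np.float64) for s in surfaces]
    for k, s in enumerate(surfaces):
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError(f"surface {k} must be (P, 3)")
        if s.shape[0] < m:
            raise ValueError(
                f"surface {k} has only {s.shape[0]} candidate points; "
                f"cannot place {m} particles"
            )
    rng = np.random.default_rng(seed)
    trees = [cKDTree(s) for s in surfaces]

    def project(pts_all: np.ndarray) -> np.ndarray:
        out = np.empty_like(pts_all)
        for k in range(n):
            _, idx = trees[k].query(pts_all[k])
            out[k] = surfaces[k][idx]
        return out

    m0 = min(16, m)
    seeds = surfaces[0][_fps(surfaces[0], m0, rng)]
    pts = np.stack([seeds] * n)
    pts = project(pts)

    trace: list[float] = []
    cur_m = m0
    while True:
        sigmas = [max(_mean_nn_spacing(pts[k]), 1e-6) for k in range(n)]
        # regularization fixed per level so descent is well-defined
        X = pts.reshape(n, -1)
        Y = X - X.mean(axis=0)
        alpha = max(1e-3 * np.sum(Y * Y) / max(n - 1, 1) / X.shape[1], 1e-8)
        step = step0 if step0 is not None else 0.5 * float(np.mean(sigmas))

        e = correspondence_energy(pts, alpha, sigmas)
        q = e.Q
        trace = [q] if cur_m == m else trace  # keep final-level trace only
        level_trace = [q]
        for _ in range(iters):
            gens = _ensemble_grad(X, alpha).reshape(n, cur_m, 3)
            gsamp = np.stack([_sample_grad(pts[k], sigmas[k]) for k in range(n)])
            grad = gens - gsamp  # dQ/d points
            gnorm = np.max(np.linalg.norm(grad, axis=2))
            if gnorm < 1e-12:
                break
            accepted = False
            trial_step = step
            for _ in range(8):
                cand = project(pts - trial_step * grad / gnorm * np.max(sigmas))
                ec = correspondence_energy(cand, alpha, sigmas)
                if ec.Q <= q:
                    pts = cand
                    X = pts.reshape(n, -1)
                    q = ec.Q
                    step = min(trial_step * 1.3, 2.0)
                    accepted = True
                    break
                trial_step *= 0.5
            level_trace.append(q)
            if not accepted:
                step = trial_step
        if cur_m == m:
            trace = level_trace
            break
        # split: duplicate every particle with a shared jitter, reproject
        jitter = rng.normal(0.0, 0.5, size=(cur_m, 3)) * np.mean(sigmas)
        pts = np.concatenate([pts, pts + jitter[None, :, :]], axis=1)
        pts = project(pts)
        cur_m = pts.shape[1]
        if cur_m > m:  # m not a power-of-two multiple of 16: trim
            pts = pts[:, :m]
            cur_m = m

    return ParticleSystem(points=pts), trace


# ---------------------------------------------------------------------------
# alignment + PCA


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation R minimizing ||P @ R - Q|| for centered point sets."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def _procrustes_align(points: np.ndarray, max_iter: int = 10):
    """Generalized Procrustes alignment, rigid only (no scaling)."""
    n = points.shape[0]
    centroids = points.mean(axis=1)
    centered = points - centroids[:, None, :]
    rotations = [np.eye(3) for _ in range(n)]
    aligned = centered.copy()
    for _ in range(max_iter):
        mean = aligned.mean(axis=0)
        new = np.empty_like(aligned)
        for k in range(n):
            R = _kabsch(centered[k], mean)
            rotations[k] = R
            new[k] = centered[k] @ R
        if np.max(np.abs(new - aligned)) < 1e-10:
            aligned = new
            break
        aligned = new
    return aligned, rotations, centroids


def _mean_rotation(rotations: Sequence[np.ndarray]) -> np.ndarray:
    M = np.mean([R for R in rotations], axis=0)
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def fit_pca(ps: ParticleSystem) -> ShapeSpaceModel:
    """PCA of the Procrustes-aligned particle ensemble."""
    n, m, _ = ps.points.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 shapes")
    aligned, rotations, centroids = _procrustes_align(ps.points)
    X = aligned.reshape(n, -1)
    mean = X.mean(axis=0)
    Y = X - mean
    k = min(n - 1, 3 * m)
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    eigenvalues = (S**2) / (n - 1)
    order = np.argsort(eigenvalues)[::-1][:k]
    # model frame -> world: average inverse alignment
    world_R = _mean_rotation([R.T for R in rotations])
    world_t = centroids.mean(axis=0)
    return ShapeSpaceModel(
        mean=mean,
        modes=Vt[order],
        eigenvalues=np.clip(eigenvalues[order], 0.0, None),
        n_input_shapes=n,
        world_rotation=world_R,
        world_translation=world_t,
    )


def synthesize_shape(
    model: ShapeSpaceModel,
    mode_index: int = 0,
    s: float = 0.0,
    frame: str = "world",
) -> np.ndarray:
    """New shape at mean + s * sqrt(eigenvalue[mode]) * mode, as (m, 3)."""
    if not (0 <= mode_index < model.n_modes):
        raise IndexError(
            f"mode_index {mode_index} out of range (model has {model.n_modes} modes)"
        )
    vec = model.mean + s * np.sqrt(model.eigenvalues[mode_index]) * model.modes[mode_index]
    pts = vec.reshape(-1, 3)
    if frame == "model":
        return pts
    if frame == "world":
        return pts @ model.world_rotation.T + model.world_translation
    raise ValueError(f"unknown frame {frame!r}")


# ---------------------------------------------------------------------------
# rasterization


def _signed_field(
    points: np.ndarray,
    reference_grid: Volume | LabelMap,
    k_neighbors: int = 8,
    normal_neighbors: int = 12,
) -> np.ndarray:
    """Signed point-to-surface offset on the full grid (+inf far outside).

    Per-particle outward normals come from local PCA of the neighborhood,
    oriented away from the cloud centroid; each voxel's value is the
    inverse-distance weighted point-to-tangent-plane offset of its nearest
    particles.  Negative inside.  Only voxels near the point cloud's
    bounding box are evaluated; the rest are +inf.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("points must be (m >= 4, 3)")
    # degenerate (near-coplanar) check
    c = pts - pts.mean(axis=0)
    ev = np.linalg.eigvalsh(c.T @ c / pts.shape[0])
    if ev[0] < 1e-6 * max(ev[-1], 1e-12):
        raise ValueError("degenerate (near-coplanar) point set cannot be rasterized")

    grid_shape = reference_grid.shape
    spacing = np.asarray(reference_grid.spacing)
    origin = np.asarray(reference_grid.origin)

    field = np.full(grid_shape, np.inf)
    lo = np.floor((pts.min(axis=0) - origin) / spacing).astype(int) - 2
    hi = np.ceil((pts.max(axis=0) - origin) / spacing).astype(int) + 3
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, grid_shape)
    if np.any(lo_c >= hi_c):
        warnings.warn("point set lies entirely outside the reference grid")
        return field

    kn = min(normal_neighbors, pts.shape[0] - 1)
    tree = cKDTree(pts)
    _, nbr = tree.query(pts, k=kn + 1)
    normals = np.empty_like(pts)
    centroid = pts.mean(axis=0)
    for i in range(pts.shape[0]):
        local = pts[nbr[i]] - pts[nbr[i]].mean(axis=0)
        w, v = np.linalg.eigh(local.T @ local)
        nrm = v[:, 0]
        if np.dot(nrm, pts[i] - centroid) < 0:
            nrm = -nrm
        normals[i] = nrm

    axes = [
        origin[a] + spacing[a] * np.arange(lo_c[a], hi_c[a]) for a in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    vox = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    kq = min(k_neighbors, pts.shape[0])
    dist, idx = tree.query(vox, k=kq)
    dist = np.atleast_2d(dist.reshape(len(vox), kq))
    idx = idx.reshape(len(vox), kq)
    w = 1.0 / (dist + 1e-6)
    offs = np.einsum("vkd,vkd->vk", vox[:, None, :] - pts[idx], normals[idx])
    signed = np.sum(w * offs, axis=1) / np.sum(w, axis=1)
    field[lo_c[0] : hi_c[0], lo_c[1] : hi_c[1], lo_c[2] : hi_c[2]] = signed.reshape(
        tuple(hi_c - lo_c)
    )
    return field


def rasterize_shape(
    points: np.ndarray,
    reference_grid: Volume | LabelMap,
    k_neighbors: int = 8,
    normal_neighbors: int = 12,
) -> LabelMap:
    """Binary mask of the region enclosed by a closed-surface point set.

    Thresholds the signed-distance reconstruction of :func:`_signed_field`
    at zero.  Robust for star-shaped and mildly concave compartments when
    the sampling is dense relative to the local feature size (thin slabs
    need points on both faces closer than the slab thickness).
    """
    field = _signed_field(points, reference_grid, k_neighbors, normal_neighbors)
    return LabelMap(
        (field < 0.0).astype(np.int32),
        tuple(reference_grid.spacing),
        tuple(reference_grid.origin),
    )


def thin_plate_spline(src: np.ndarray, dst: np.ndarray):
    """3D thin-plate (biharmonic, phi(r) = r) interpolant src -> dst.

    Returns a callable mapping (n, 3) points.  Used to carry a dense
    surface along when corresponding particles move in shape space.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    m = src.shape[0]
    K = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=2)
    P = np.hstack([np.ones((m, 1)), src])
    A = np.zeros((m + 4, m + 4))
    A[:m, :m] = K + 1e-8 * np.eye(m)
    A[:m, m:] = P
    A[m:, :m] = P.T
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = dst
    sol = np.linalg.solve(A, rhs)
    w, a = sol[:m], sol[m:]

    def apply(pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        D = np.linalg.norm(pts[:, None, :] - src[None, :, :], axis=2)
        return D @ w + np.hstack([np.ones((len(pts), 1)), pts]) @ a

    return apply
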