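"""Shape model: surface extraction, correspondence energy, PCA,
synthesis and rasterization, each against an independent oracle."""

import numpy as np
import pytest

from musclesegkit.core import LabelMap
from musclesegkit.shape_model import (
    DEFAULT_PARTICLES,
    CorrespondenceEnergy,
    ParticleSystem,
    correspondence_energy,
    extract_surface,
    fit_pca,
    optimize_correspondence,
    rasterize_shape,
    synthesize_shape,
)

from conftest import ellipsoid_cloud


def cube_labelmap(lo=5, hi=15, n=20):
    arr = np.zeros((n, n, n), dtype=np.int32)
    arr[lo:hi, lo:hi, lo:hi] = 1
    return LabelMap(arr)


# ---------------------------------------------------------------------------
# extract_surface


def test_cube_surface_lies_on_analytic_faces():
    lm = cube_labelmap()
    pts = extract_surface(lm, 1)
    # analytic cube surface: [4.5, 14.5]^3 box boundary (voxel centres at
    # integer coordinates, boundary half a voxel outside)
    lo, hi = 4.5, 14.5
    inside = np.clip(pts, lo, hi)
    face_dist = np.abs(pts - inside).max(axis=1)
    onface = np.minimum(np.abs(pts - lo), np.abs(pts - hi)).min(axis=1)
    # every point within 1 voxel of the analytic surface
    assert float(np.maximum(face_dist, onface).max()) < 1.0


def test_absent_label_raises_naming_it():
    with pytest.raises(ValueError, match="3"):
        extract_surface(cube_labelmap(), 3)


def test_single_voxel_label_yields_points_near_voxel_center():
    arr = np.zeros((9, 9, 9), dtype=np.int32)
    arr[4, 4, 4] = 1
    pts = extract_surface(LabelMap(arr), 1)
    assert len(pts) > 0
    assert np.abs(pts - 4.0).max() <= 1.0


# ---------------------------------------------------------------------------
# correspondence


def test_energy_bookkeeping_identity():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(5, 32, 3))
    e = correspondence_energy(pts, alpha=1e-3, sigmas=[0.5] * 5)
    assert isinstance(e, CorrespondenceEnergy)
    assert abs(e.Q - (e.ensemble_term - e.sample_terms.sum())) <= 1e-9 * max(
        abs(e.Q), 1.0
    )


def test_identical_shapes_reach_ensemble_floor():
    cloud = ellipsoid_cloud(10, 8, 12, seed=3)
    ps, trace = optimize_correspondence([cloud, cloud.copy(), cloud.copy()],
                                        m=32, iters=5, seed=0)
    # identical shapes: particles identical across shapes, so the ensemble
    # covariance is exactly zero and H(Z) sits at its regularization floor
    assert np.allclose(ps.points[0], ps.points[1])
    X = ps.as_vectors()
    assert np.allclose(X - X.mean(axis=0), 0.0)


def test_energy_trace_non_increasing_on_ellipsoids(ellipsoid_cohort):
    ps, trace = optimize_correspondence(ellipsoid_cohort, m=64, iters=10, seed=1)
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
    assert ps.n_particles == 64


def test_default_particle_count_is_1024():
    import inspect

    assert DEFAULT_PARTICLES == 1024
    sig = inspect.signature(optimize_correspondence)
    assert sig.parameters["m"].default == 1024


def test_optimized_correspondence_beats_random_sampling(ellipsoid_cohort):
    """Across-shape particle variance should drop below what independent
    random surface sampling gives at the same m."""
    m = 64
    ps, _ = optimize_correspondence(ellipsoid_cohort, m=m, iters=10, seed=2)
    var_opt = ps.as_vectors().var(axis=0).sum()
    rng = np.random.default_rng(2)
    rand = np.stack(
        [s[rng.choice(len(s), m, replace=False)] for s in ellipsoid_cohort]
    )
    var_rand = rand.reshape(len(rand), -1).var(axis=0).sum()
    assert var_opt < var_rand


def test_too_few_candidate_points_raises():
    tiny = [np.random.default_rng(0).normal(size=(10, 3)) for _ in range(3)]
    with pytest.raises(ValueError, match="candidate"):
        optimize_correspondence(tiny, m=64, iters=2, seed=0)


def test_fewer_than_two_surfaces_raises():
    with pytest.raises(ValueError):
        optimize_correspondence([ellipsoid_cloud(5, 5, 5)], m=16)


# ---------------------------------------------------------------------------
# PCA


def planted_system(n=10, m=64, seed=4):
    """Shapes = base + c_k * v for a known unit direction v."""
    rng = np.random.default_rng(seed)
    base = ellipsoid_cloud(10, 9, 12, n=m, seed=seed)
    v = rng.normal(size=3 * m)
    v /= np.linalg.norm(v)
    coeffs = rng.normal(0, 2.0, size=n)
    pts = np.stack(
        [(base.ravel() + c * v).reshape(m, 3) for c in coeffs]
    )
    return ParticleSystem(points=pts), v, coeffs


def test_planted_single_mode_is_recovered():
    ps, v, coeffs = planted_system()
    model = fit_pca(ps)
    # note: rigid alignment may absorb a little of the planted direction,
    # but the dominant mode must remain collinear with v
    cos = abs(float(model.modes[0] @ v))
    assert cos > 0.99
    assert model.explained_variance_ratio()[0] > 0.99


def test_mode_count_at_most_n_minus_1():
    ps, _, _ = planted_system(n=10)
    model = fit_pca(ps)
    assert model.n_modes <= 9
    assert np.all(np.diff(model.eigenvalues) <= 1e-9)
    # orthonormality
    G = model.modes @ model.modes.T
    assert np.allclose(G, np.eye(model.n_modes), atol=1e-8)


def test_identical_shapes_give_zero_eigenvalues_and_mean():
    base = ellipsoid_cloud(8, 8, 8, n=32, seed=1)
    ps = ParticleSystem(points=np.stack([base] * 5))
    model = fit_pca(ps)
    assert np.all(model.eigenvalues < 1e-12)
    recon = synthesize_shape(model, 0, 0.0, frame="world")
    assert np.allclose(recon, base, atol=1e-6)


def test_pca_matches_bruteforce_eigendecomposition():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(6, 8, 3))
    # bypass alignment effects: center shapes identically
    pts -= pts.mean(axis=1, keepdims=True)
    ps = ParticleSystem(points=pts)
    model = fit_pca(ps)
    X = np.array([p @ R for p, (R, _) in zip(pts, ps.alignment)]).reshape(6, -1)
    # brute force: explicit 3m x 3m covariance of the aligned data
    from musclesegkit.shape_model import _procrustes_align

    aligned, _, _ = _procrustes_align(pts)
    Y = aligned.reshape(6, -1)
    C = np.cov(Y.T, bias=False)
    evals = np.sort(np.linalg.eigvalsh(C))[::-1]
    assert np.allclose(model.eigenvalues, evals[: model.n_modes], atol=1e-8)


def test_pca_needs_two_shapes():
    ps = ParticleSystem(points=np.zeros((1, 8, 3)))
    with pytest.raises(ValueError):
        fit_pca(ps)


# ---------------------------------------------------------------------------
# synthesis


def test_synthesize_zero_scale_is_mean_and_pm_average_to_mean():
    ps, _, _ = planted_system()
    model = fit_pca(ps)
    mean = synthesize_shape(model, 0, 0.0, frame="model")
    plus = synthesize_shape(model, 0, 1.0, frame="model")
    minus = synthesize_shape(model, 0, -1.0, frame="model")
    assert np.allclose(mean, model.mean.reshape(-1, 3))
    assert np.allclose((plus + minus) / 2.0, mean, atol=1e-8)


def test_synthesize_planted_closed_form():
    ps, v, _ = planted_system()
    model = fit_pca(ps)
    plus = synthesize_shape(model, 0, 1.0, frame="model").ravel()
    expect = model.mean + np.sqrt(model.eigenvalues[0]) * model.modes[0]
    assert np.allclose(plus, expect, atol=1e-9)


def test_synthesize_mode_out_of_range():
    ps, _, _ = planted_system(n=4)
    model = fit_pca(ps)
    with pytest.raises(IndexError):
        synthesize_shape(model, model.n_modes, 1.0)


# ---------------------------------------------------------------------------
# rasterization


def test_cube_roundtrip_dice():
    lm = cube_labelmap()
    ras = rasterize_shape(extract_surface(lm, 1), lm)
    inter = np.logical_and(ras.data > 0, lm.data > 0).sum()
    d = 2 * inter / (ras.data.sum() + lm.data.sum())
    assert d >= 0.95


def test_points_outside_grid_warn_and_give_empty_mask():
    lm = cube_labelmap()
    far = extract_surface(lm, 1) + 500.0
    with pytest.warns(UserWarning, match="outside"):
        out = rasterize_shape(far, lm)
    assert out.data.sum() == 0


def test_sphere_volume_within_10_percent():
    r = 9.0
    pts = ellipsoid_cloud(r, r, r, center=(16, 16, 16), n=3000, seed=0)
    grid = LabelMap(np.zeros((32, 32, 32), dtype=np.int32))
    vol = rasterize_shape(pts, grid).data.sum()
    analytic = 4.0 / 3.0 * np.pi * r**3
    assert abs(vol - analytic) / analytic < 0.10


def test_coplanar_points_raise():
    rng = np.random.default_rng(0)
    flat = np.column_stack([rng.uniform(2, 20, 50), rng.uniform(2, 20, 50),
                            np.full(50, 11.0)])
    grid = LabelMap(np.zeros((24, 24, 24), dtype=np.int32))
    with pytest.raises(ValueError, match="coplanar|degenerate"):
        rasterize_shape(flat, grid)


def test_particle_io_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    ps = ParticleSystem(points=rng.normal(size=(3, 16, 3)))
    paths = ps.save(tmp_path)
    back = ParticleSystem.load(paths)
    assert np.allclose(back.points, ps.points, atol=1e-5)
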