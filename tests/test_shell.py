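"""Alpha-concave hull, iterative densification, and voxelization."""

import numpy as np
import pytest
from scipy.spatial import Delaunay, cKDTree

from la_recon.shell import circumradii, concave_hull, densify, discretize

TETRA = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def unit_sphere_points(n, seed=0, jitter=0.0):
    """Near-uniform sphere samples; `jitter` is radial noise (relative).

    Points exactly on a sphere are degenerate for the alpha complex (every
    tetrahedron's circumsphere is the sphere itself), so surface-like tests
    use a small radial jitter, as voxel-snapped clinical samples have.
    """
    rng = np.random.default_rng(seed)
    p = rng.normal(size=(n, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    if jitter:
        p *= 1.0 + rng.normal(scale=jitter, size=(n, 1))
    return p


def brute_circumradius(tet):
    """Independent oracle: least-squares solve of |x - p_i|^2 = R^2."""
    # linearize pairwise differences against vertex 0
    a = 2 * (tet[1:] - tet[0])
    b = np.sum(tet[1:] ** 2, axis=1) - np.sum(tet[0] ** 2)
    center, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.linalg.norm(tet[0] - center)


def test_tetrahedron_convex_hull_faces():
    mesh = concave_hull(TETRA, alpha=np.inf)
    assert len(mesh.faces) == 4
    assert len(mesh.edges) == 6


def test_sphere_hull_area_matches_analytic():
    pts = unit_sphere_points(1500)
    mesh = concave_hull(pts, alpha=5.0)
    assert mesh.area == pytest.approx(4 * np.pi, rel=0.10)


def test_alpha_complex_nested_and_matches_brute_force():
    rng = np.random.default_rng(8)
    pts = rng.uniform(0, 4, size=(40, 3))
    tri = Delaunay(pts)
    radii = circumradii(pts, tri.simplices)
    brute = np.array([brute_circumradius(pts[s]) for s in tri.simplices])
    assert np.allclose(radii[np.isfinite(radii)], brute[np.isfinite(radii)], rtol=1e-6)
    small = {tuple(sorted(s)) for s in tri.simplices[radii <= 1.0]}
    large = {tuple(sorted(s)) for s in tri.simplices[radii <= 2.5]}
    assert small <= large  # alpha-complex nesting
    f_small = len(concave_hull(pts, 1.2).faces) if small else 0
    f_inf = len(concave_hull(pts, np.inf).faces)
    assert f_inf > 0 and f_small >= 0


def test_alpha_too_small_reports_admissible_value():
    with pytest.raises(ValueError, match="smallest circumradius"):
        concave_hull(TETRA * 10, alpha=0.01)


def test_densify_zero_iterations_is_identity():
    assert np.array_equal(densify(TETRA, alpha=np.inf, iterations=0), TETRA)


def test_densify_single_tetrahedron_adds_six_midpoints():
    out = densify(TETRA, alpha=np.inf, iterations=1)
    assert len(out) == 10  # 4 vertices + 6 unique edge midpoints
    out_b = densify(TETRA, alpha=np.inf, iterations=1, edge_source="boundary")
    assert len(out_b) == 10


def test_densification_growth_is_exponential():
    """Each iteration multiplies the point count several-fold (>= 3.5x) on
    well-sampled closed surfaces; three iterations exceed the ~60x total that
    turns thousands of samples into hundreds of thousands."""
    for seed, n in [(0, 400), (1, 500), (2, 600)]:
        pts = unit_sphere_points(n, seed=seed, jitter=0.02) * 20.0
        counts = [len(pts)]
        for _ in range(3):
            pts = densify(pts, alpha=5.0, iterations=1)
            counts.append(len(pts))
        ratios = [counts[i + 1] / counts[i] for i in range(3)]
        assert all(r >= 3.5 for r in ratios), ratios
        assert counts[3] / counts[0] >= 60


def test_discretize_single_point_and_duplicates():
    shell = discretize(np.array([[0.1, 0.2, 0.3]]), spacing_mm=1.0, crop_shape=(8, 8, 8))
    assert shell.volume.sum() == 1
    dup = discretize(np.array([[0.1, 0.2, 0.3]] * 5), spacing_mm=1.0, crop_shape=(8, 8, 8))
    assert np.array_equal(shell.volume, dup.volume)


def test_discretize_permutation_invariant():
    rng = np.random.default_rng(3)
    pts = rng.uniform(0, 10, size=(200, 3))
    a = discretize(pts, 1.0, crop_shape=(16, 16, 16))
    b = discretize(pts[rng.permutation(200)], 1.0, crop_shape=(16, 16, 16))
    assert np.array_equal(a.volume, b.volume)
    assert np.array_equal(a.crop_origin, b.crop_origin)


def test_discretize_rejects_oversized_cloud():
    pts = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    with pytest.raises(ValueError, match="bounding box"):
        discretize(pts, 1.0, crop_shape=(16, 16, 16))


def test_mesh_ply_and_shell_nifti_round_trip(tmp_path):
    mesh = concave_hull(unit_sphere_points(300, seed=2, jitter=0.02) * 10, alpha=5.0)
    mesh.save_ply(tmp_path / "mesh.ply")
    assert (tmp_path / "mesh.ply").stat().st_size > 0
    shell = discretize(mesh.vertices, spacing_mm=1.0, crop_shape=(32, 32, 32))
    shell.save(tmp_path / "shell.nii.gz")
    from la_recon.types import PartialShell

    back = PartialShell.load(tmp_path / "shell.nii.gz")
    assert np.array_equal(back.volume, shell.volume)
    assert np.array_equal(back.crop_origin, shell.crop_origin)


def test_densified_sphere_discretizes_to_thin_accurate_shell():
    r = 15.0
    pts = unit_sphere_points(500, seed=5, jitter=0.02) * r
    dense = densify(pts, alpha=5.0, iterations=2)
    shell = discretize(dense, spacing_mm=1.0, crop_shape=(48, 48, 48))
    shell.validate()  # thin: < 10% foreground
    # voxel centers of the shell sit within ~1 voxel of the analytic sphere
    idx = np.argwhere(shell.volume) + shell.crop_origin
    world = (idx + 0.5) * shell.spacing_mm
    dist = np.abs(np.linalg.norm(world, axis=1) - r)
    assert dist.mean() <= shell.spacing_mm
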