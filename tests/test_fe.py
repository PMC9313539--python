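"""Finite-element compression solver: assembly, mechanics identities,
post-yield behavior and failure-point extraction."""

import numpy as np
import pytest

from spinequant.core import CTVolume, SegmentationMask
from spinequant.fe import (CompressionConfig, DegenerateCurveError,
                           LoadDisplacementCurve, assemble, element_stiffness,
                           extract_failure, run_compression)
from spinequant.materials import MaterialCards
from spinequant.meshing import TetMesh, mask_to_mesh


def _single_cell_mesh():
    ct = CTVolume(np.full((2, 2, 2), 500.0), (1.0, 1.0, 1.0))
    mask = SegmentationMask(np.ones((2, 2, 2), np.int32), {1: "L1"})
    return mask_to_mesh(mask, ct, 2.0)


def test_free_mesh_has_six_rigid_body_modes():
    mesh = _single_cell_mesh()
    cards = MaterialCards.isotropic(mesh.n_elements, 1000.0, 0.3)
    K = assemble(mesh, cards).toarray()
    w = np.linalg.eigvalsh(K)
    assert np.all(np.abs(w[:6]) < 1e-6 * w[-1])
    assert w[6] > 1e-3 * w[-1]


def test_stiffness_linear_in_modulus():
    mesh = _single_cell_mesh()
    k1 = assemble(mesh, MaterialCards.isotropic(mesh.n_elements, 1000.0, 0.25))
    k2 = assemble(mesh, MaterialCards.isotropic(mesh.n_elements, 2000.0, 0.25))
    assert np.allclose(k2.toarray(), 2.0 * k1.toarray(), rtol=1e-12)


def test_element_stiffness_matches_energy_hessian_oracle():
    """One regular tet vs an independent route: the element stiffness must
    equal the Hessian of the strain energy of the linearly interpolated
    displacement field (finite differences, centroid quadrature)."""
    nodes = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 1.5, 0], [0, 0, 1.2]])
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]),
                   inferior_nodes=np.array([0]), superior_nodes=np.array([3]))
    E, nu = 1500.0, 0.28
    cards = MaterialCards.isotropic(1, E, nu)
    Ke, _, vol, _ = element_stiffness(mesh, cards)

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))

    def energy(u):
        # independent: fit affine displacement field, integrate W = 1/2 s:e
        A = np.column_stack([np.ones(4), nodes])
        coef = np.linalg.solve(A, u.reshape(4, 3))  # rows: const, x, y, z
        grad = coef[1:]  # du_j/dx_i
        eps = 0.5 * (grad + grad.T)
        W = 0.5 * lam * np.trace(eps) ** 2 + mu * np.sum(eps * eps)
        return W * float(vol[0])

    h = 1e-5
    H = np.zeros((12, 12))
    for i in range(12):
        for j in range(12):
            for si, sj, s in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)):
                u = np.zeros(12)
                u[i] += si * h
                u[j] += sj * h
                H[i, j] += s * energy(u)
            H[i, j] /= 4 * h * h
    assert np.allclose(Ke[0], H, rtol=1e-5, atol=1e-4 * np.abs(H).max())


@pytest.fixture(scope="module")
def cuboid():
    ct = CTVolume(np.full((10, 10, 10), 500.0), (1.0, 1.0, 1.0))
    mask = SegmentationMask(np.ones((10, 10, 10), np.int32), {1: "L1"})
    return mask_to_mesh(mask, ct, 2.0)


def test_elastic_slope_matches_EA_over_L(cuboid):
    """Uniaxial closed form dF/du = E*A/L; exact with nu=0 under any
    lateral boundary condition, within 2% with nu=0.3 and frictionless
    supports."""
    cfg = CompressionConfig(max_displacement_mm=0.01, n_increments=2)
    cards = MaterialCards.isotropic(cuboid.n_elements, 1000.0, 0.0)
    res = run_compression(cuboid, cards, cfg)
    slope = res.curve.force_N[-1] / res.curve.displacement_mm[-1]
    assert slope == pytest.approx(10_000.0, rel=1e-9)

    cfg_free = CompressionConfig(max_displacement_mm=0.01, n_increments=2,
                                 inferior_inplane_fixed=False)
    cards3 = MaterialCards.isotropic(cuboid.n_elements, 1000.0, 0.3)
    res3 = run_compression(cuboid, cards3, cfg_free)
    slope3 = res3.curve.force_N[-1] / res3.curve.displacement_mm[-1]
    assert slope3 == pytest.approx(10_000.0, rel=0.02)


def test_failure_load_matches_sigma_min_times_area(cuboid):
    cards = MaterialCards.isotropic(cuboid.n_elements, 1000.0, 0.0,
                                    sigma_min=10.0, eps_ab=0.05)
    res = run_compression(cuboid, cards,
                          CompressionConfig(max_displacement_mm=0.3,
                                            n_increments=30))
    assert res.failure_reached
    assert res.failure_load == pytest.approx(1000.0, rel=0.05)


def test_reaction_reciprocity(cuboid):
    """Total z-reaction on the fixed inferior face balances the superior
    face at every increment."""
    import scipy.sparse.linalg as spla

    cards = MaterialCards.isotropic(cuboid.n_elements, 1000.0, 0.3)
    K = assemble(cuboid, cards).tocsr()
    n_dof = K.shape[0]
    inf_d = (3 * cuboid.inferior_nodes[:, None] + np.arange(3)).ravel()
    sup_z = 3 * cuboid.superior_nodes + 2
    constrained = np.union1d(inf_d, sup_z)
    free = np.setdiff1d(np.arange(n_dof), constrained)
    u = np.zeros(n_dof)
    u[sup_z] = -0.01
    u[free] = spla.spsolve(K[free][:, free].tocsc(),
                           -(K[free][:, constrained] @ u[constrained]))
    r = K @ u
    f_inf = r[3 * cuboid.inferior_nodes + 2].sum()
    f_sup = r[sup_z].sum()
    assert abs(f_inf + f_sup) <= 1e-6 * abs(f_sup)


def test_elastic_path_independence(cuboid):
    """Halving the increment size leaves the elastic response unchanged."""
    cards = MaterialCards.isotropic(cuboid.n_elements, 1000.0, 0.3)
    forces = []
    for n in (4, 8):
        res = run_compression(cuboid, cards,
                              CompressionConfig(max_displacement_mm=0.02,
                                                n_increments=n))
        forces.append(res.curve.force_N[-1])
    assert forces[1] == pytest.approx(forces[0], rel=1e-3)


def test_failure_scaling_law(cuboid):
    """Scaling all moduli and strengths by c scales the failure load by c
    at unchanged failure displacement."""
    cfg = CompressionConfig(max_displacement_mm=0.3, n_increments=30)
    base = MaterialCards.isotropic(cuboid.n_elements, 1000.0, 0.1,
                                   sigma_min=10.0, sigma_max=15.0, eps_ab=0.03)
    c = 2.5
    scaled = MaterialCards.isotropic(cuboid.n_elements, c * 1000.0, 0.1,
                                     sigma_min=c * 10.0, sigma_max=c * 15.0,
                                     eps_ab=0.03)
    r1 = run_compression(cuboid, base, cfg)
    r2 = run_compression(cuboid, scaled, cfg)
    assert r2.failure_load == pytest.approx(c * r1.failure_load, rel=0.01)
    assert r2.failure_displacement == pytest.approx(r1.failure_displacement,
                                                    rel=1e-9)


def test_failure_point_on_curve(cuboid):
    cards = MaterialCards.isotropic(cuboid.n_elements, 1000.0, 0.0,
                                    sigma_min=10.0, eps_ab=0.02)
    res = run_compression(cuboid, cards,
                          CompressionConfig(max_displacement_mm=0.3,
                                            n_increments=30))
    i = np.flatnonzero(np.isclose(res.curve.displacement_mm,
                                  res.failure_displacement))
    assert len(i) == 1 and res.curve.force_N[i[0]] == res.failure_load
    assert res.failure_load <= res.curve.force_N.max() * (1 + 1e-9)


def test_zero_displacement_reports_not_reached(cuboid):
    cards = MaterialCards.isotropic(cuboid.n_elements, 1000.0, 0.0)
    res = run_compression(cuboid, cards,
                          CompressionConfig(max_displacement_mm=0.0))
    assert not res.failure_reached
    assert np.isnan(res.failure_load)
    assert res.curve.displacement_mm.tolist() == [0.0]


@pytest.mark.parametrize("force, expected", [
    ([0, 10, 20, 30], (30.0, 3.0)),               # strictly rising: last point
    ([0, 500, 1000, 900], (1000.0, 2.0)),         # peak then drop
    ([0, 800, 700, 1200, 1100], (800.0, 1.0)),    # first peak wins
])
def test_extract_failure_rules(force, expected):
    curve = LoadDisplacementCurve(np.arange(len(force), dtype=float),
                                  np.asarray(force, dtype=float))
    assert extract_failure(curve) == pytest.approx(expected)


def test_extract_failure_degenerate():
    with pytest.raises(DegenerateCurveError):
        extract_failure(LoadDisplacementCurve([0.0, 1.0], [0.0, 0.0]))
    with pytest.raises(DegenerateCurveError):
        extract_failure(LoadDisplacementCurve([0.0], [0.0]))
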