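"""Quasi-static displacement-controlled compression of a material-mapped
tetrahedral vertebra model.

Mechanics: small-strain linear tetrahedra (constant strain), transversely
isotropic elasticity about the superior-inferior z axis, and an
element-wise post-yield treatment: an element yields when its maximum
principal stress exceeds sigma_max or its minimum principal stress drops
below -sigma_min; yielded elements have their stiffness scaled down by a
secant factor so the violated principal stress is capped at the limit, and
are killed (stiffness scale 1e-3) once the accumulated post-yield axial
strain reaches eps_AB. The inferior surface is fixed; the superior surface
receives a prescribed axial displacement (in-plane translations free by
default). The recorded load-displacement curve yields failure load and
failure displacement at its first significant peak.

Units: mm, N, MPa (MPa * mm^2 = N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialCards
from .meshing import TetMesh

__all__ = [
    "CompressionConfig",
    "ElementStates",
    "LoadDisplacementCurve",
    "FEAResult",
    "assemble",
    "element_stiffness",
    "run_compression",
    "extract_failure",
]

ELASTIC, YIELDED, FAILED = 0, 1, 2


class MaterialError(RuntimeError):
    pass


class ConvergenceError(RuntimeError):
    pass


class DegenerateCurveError(RuntimeError):
    pass


@dataclass
class CompressionConfig:
    """Loading schedule and solver controls.

    max_displacement_mm overrides the fractional default of
    ``max_displacement_frac`` x specimen height (2% brackets the failure
    displacements of both patient groups on ~25-30 mm bodies).
    """

    max_displacement_mm: float | None = None
    max_displacement_frac: float = 0.02
    n_increments: int = 40
    max_state_iters: int = 50
    inferior_inplane_fixed: bool = True
    superior_inplane_fixed: bool = False
    kill_scale: float = 1e-3
    force_floor_frac: float = 0.5
    scale_tol: float = 0.01
    force_tol: float = 1e-3
    # stop as soon as the failure point is determined (first >1% drop from
    # the running peak, the extract_failure rule); the default keeps
    # loading until the 50%-of-peak floor so the full post-peak tail is on
    # the curve
    stop_on_failure: bool = False
    # crack-band regularization: post-yield strain localizes into a band
    # one element high, so the plastic-strain limit is scaled by
    # (reference length / element size) to keep the dissipated band
    # displacement mesh-independent; None disables
    crack_band_ref_mm: float | None = 2.0


@dataclass
class ElementStates:
    """Per-element damage bookkeeping (forward-only transitions)."""

    status: np.ndarray  # ELASTIC / YIELDED / FAILED
    scale: np.ndarray  # stiffness scale in (0, 1]
    yield_axial_strain: np.ndarray  # |eps_zz| at first yield
    post_yield_strain: np.ndarray  # accumulated |eps_zz| beyond yield

    @classmethod
    def fresh(cls, n: int) -> "ElementStates":
        return cls(np.full(n, ELASTIC, dtype=int), np.ones(n), np.zeros(n),
                   np.zeros(n))


@dataclass
class LoadDisplacementCurve:
    displacement_mm: np.ndarray
    force_N: np.ndarray

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)

    def to_csv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame({"displacement_mm": self.displacement_mm,
                      "force_N": self.force_N}).to_csv(path, index=False)


@dataclass
class FEAResult:
    failure_load: float  # N; nan when not reached
    failure_displacement: float  # mm; nan when not reached
    failure_reached: bool
    curve: LoadDisplacementCurve
    n_yielded: int = 0
    n_failed: int = 0
    states: ElementStates | None = field(default=None, repr=False)


def compliance_matrices(cards: MaterialCards) -> np.ndarray:
    """Per-element 6x6 compliance, Voigt order (xx, yy, zz, yz, xz, xy).

    Off-diagonal terms use the loading-in-first-axis Poisson convention
    (nu_xz couples stress along x to strain along z) and the matrix is
    built symmetric. Raises MaterialError naming the first element whose
    compliance is not positive definite.
    """
    m = len(cards)
    S = np.zeros((m, 6, 6))
    S[:, 0, 0] = 1.0 / cards.E_x
    S[:, 1, 1] = 1.0 / cards.E_y
    S[:, 2, 2] = 1.0 / cards.E_z
    S[:, 0, 1] = S[:, 1, 0] = -cards.nu_xy / cards.E_x
    S[:, 0, 2] = S[:, 2, 0] = -cards.nu_xz / cards.E_x
    S[:, 1, 2] = S[:, 2, 1] = -cards.nu_yz / cards.E_y
    S[:, 3, 3] = 1.0 / cards.G_yz
    S[:, 4, 4] = 1.0 / cards.G_xz
    S[:, 5, 5] = 1.0 / cards.G_xy
    eig = np.linalg.eigvalsh(S)
    bad = np.flatnonzero(eig[:, 0] <= 0)
    if len(bad):
        raise MaterialError(f"element {bad[0]}: compliance not positive definite")
    return S


def element_stiffness(mesh: TetMesh, cards: MaterialCards):
    """Unit-scale element stiffness matrices.

    Returns (Ke, B, volumes, D) with Ke of shape (m, 12, 12), the constant
    strain-displacement operators B (m, 6, 12), and stiffness tensors D.
    """
    D = np.linalg.inv(compliance_matrices(cards))
    coords = mesh.nodes[mesh.elements]  # (m, 4, 3)
    m = len(coords)
    ones = np.ones((m, 4, 1))
    M = np.concatenate([ones, coords], axis=2)  # (m, 4, 4)
    Cinv = np.linalg.inv(M)
    grads = Cinv[:, 1:4, :]  # (m, 3, 4): d/dx, d/dy, d/dz of each shape fn
    vol = np.abs(np.linalg.det(M)) / 6.0

    B = np.zeros((m, 6, 12))
    gx, gy, gz = grads[:, 0], grads[:, 1], grads[:, 2]
    for i in range(4):
        B[:, 0, 3 * i + 0] = gx[:, i]
        B[:, 1, 3 * i + 1] = gy[:, i]
        B[:, 2, 3 * i + 2] = gz[:, i]
        B[:, 3, 3 * i + 1] = gz[:, i]
        B[:, 3, 3 * i + 2] = gy[:, i]
        B[:, 4, 3 * i + 0] = gz[:, i]
        B[:, 4, 3 * i + 2] = gx[:, i]
        B[:, 5, 3 * i + 0] = gy[:, i]
        B[:, 5, 3 * i + 1] = gx[:, i]
    Ke = np.einsum("eji,ejk,ekl,e->eil", B, D, B, vol, optimize=True)
    return Ke, B, vol, D


def _dof_indices(mesh: TetMesh) -> np.ndarray:
    return (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(len(mesh.elements), 12)


def assemble(mesh: TetMesh, cards: MaterialCards, scale: np.ndarray | None = None,
             Ke: np.ndarray | None = None) -> sp.csr_array:
    """Global stiffness matrix (free mesh, no boundary conditions)."""
    if Ke is None:
        Ke, _, _, _ = element_stiffness(mesh, cards)
    if scale is None:
        scale = np.ones(len(mesh.elements))
    dofs = _dof_indices(mesh)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    data = (Ke * scale[:, None, None]).ravel()
    n = 3 * mesh.n_nodes
    return sp.coo_array((data, (rows, cols)), shape=(n, n)).tocsr()


def _principal_stresses(sigma_voigt: np.ndarray) -> np.ndarray:
    """Eigenvalues (ascending) of the per-element stress tensors."""
    m = len(sigma_voigt)
    T = np.empty((m, 3, 3))
    T[:, 0, 0] = sigma_voigt[:, 0]
    T[:, 1, 1] = sigma_voigt[:, 1]
    T[:, 2, 2] = sigma_voigt[:, 2]
    T[:, 1, 2] = T[:, 2, 1] = sigma_voigt[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = sigma_voigt[:, 4]
    T[:, 0, 1] = T[:, 1, 0] = sigma_voigt[:, 5]
    return np.linalg.eigvalsh(T)


def run_compression(mesh: TetMesh, cards: MaterialCards,
                    config: CompressionConfig | None = None) -> FEAResult:
    """Displacement-controlled axial compression to failure.

    At each displacement increment the element states are iterated to a
    fixed point: solve, evaluate principal stresses, yield-check, cap
    yielded-element stress by secant stiffness scaling, kill elements whose
    accumulated post-yield axial strain reaches eps_AB. Loading stops at
    the maximum displacement or once the reaction force falls below
    ``force_floor_frac`` of the running peak.
    """
    cfg = config or CompressionConfig()
    if len(mesh.inferior_nodes) == 0 or len(mesh.superior_nodes) == 0:
        raise ValueError("inferior/superior boundary node sets must be non-empty")
    if cfg.n_increments < 1:
        raise ValueError("n_increments must be >= 1")

    z = mesh.nodes[:, 2]
    height = z.max() - z.min()
    max_disp = (cfg.max_displacement_mm if cfg.max_displacement_mm is not None
                else cfg.max_displacement_frac * height)

    Ke, B, vol, D = element_stiffness(mesh, cards)
    dofs = _dof_indices(mesh)
    n_dof = 3 * mesh.n_nodes
    states = ElementStates.fresh(len(mesh.elements))
    eps_limit = np.asarray(cards.eps_AB, dtype=float)
    if cfg.crack_band_ref_mm is not None:
        char_len = np.cbrt(6.0 * np.abs(vol))  # cell side for Kuhn tets
        eps_limit = eps_limit * cfg.crack_band_ref_mm / char_len

    inf_dofs = (3 * mesh.inferior_nodes[:, None] + np.arange(3)).ravel() \
        if cfg.inferior_inplane_fixed else 3 * mesh.inferior_nodes + 2
    sup_z = 3 * mesh.superior_nodes + 2
    sup_xy = np.concatenate([3 * mesh.superior_nodes, 3 * mesh.superior_nodes + 1]) \
        if cfg.superior_inplane_fixed else np.array([], dtype=int)
    fixed = np.unique(np.concatenate([inf_dofs, sup_xy]))
    prescribed = np.setdiff1d(sup_z, fixed)
    constrained = np.union1d(fixed, prescribed)
    free = np.setdiff1d(np.arange(n_dof), constrained)

    disps = [0.0]
    forces = [0.0]
    if max_disp <= 0:
        return FEAResult(np.nan, np.nan, False,
                         LoadDisplacementCurve(disps, forces), states=states)

    u = np.zeros(n_dof)
    K = None
    Kff = None
    K_dirty = True
    lu = None
    lu_current = False
    lu_age = 0  # scale updates since the last factorization
    x_prev = None
    peak = 0.0
    collapsed = False
    for step in range(1, cfg.n_increments + 1):
        d = max_disp * step / cfg.n_increments
        converged = False
        F = 0.0
        F_prev = None
        for it in range(cfg.max_state_iters):
            if K_dirty:
                K = assemble(mesh, cards, states.scale, Ke=Ke)
                Kff = K[free][:, free].tocsc()
                K_dirty = False
                lu_current = False
            u[:] = 0.0
            u[sup_z] = -d
            rhs = -(K[free][:, constrained] @ u[constrained])
            if lu is not None and not lu_current:
                # the last factorization preconditions CG on the updated
                # system; stiffness changes between state passes are
                # localized, so CG converges in a few iterations and a
                # fresh factorization is needed only when it stalls
                M = spla.LinearOperator(Kff.shape, matvec=lu.solve)
                x, info = spla.cg(Kff, rhs, x0=x_prev, rtol=1e-10, atol=0.0,
                                  maxiter=80, M=M)
                if info == 0:
                    u[free] = x
                else:
                    lu = spla.splu(Kff)
                    lu_current = True
                    lu_age = 0
                    u[free] = lu.solve(rhs)
            else:
                if lu is None or not lu_current:
                    lu = spla.splu(Kff)
                    lu_current = True
                    lu_age = 0
                u[free] = lu.solve(rhs)
            x_prev = u[free].copy()
            F = -float((K @ u)[sup_z].sum())

            eps = np.einsum("eij,ej->ei", B, u[dofs])
            sigma = np.einsum("e,eij,ej->ei", states.scale, D, eps)
            princ = _principal_stresses(sigma)
            s3, s1 = princ[:, 0], princ[:, 2]

            active = states.status != FAILED
            over_t = active & (s1 > cards.sigma_max * (1 + 1e-9))
            over_c = active & (s3 < -cards.sigma_min * (1 + 1e-9))
            newly = (states.status == ELASTIC) & (over_t | over_c)
            states.status[newly] = YIELDED
            states.yield_axial_strain[newly] = np.abs(eps[newly, 2])

            ratio = np.ones(len(cards))
            with np.errstate(divide="ignore", invalid="ignore"):
                rt = np.where(over_t & (s1 > 0), cards.sigma_max / s1, np.inf)
                rc = np.where(over_c & (s3 < 0), cards.sigma_min / (-s3), np.inf)
            ratio = np.minimum(np.minimum(rt, rc), 1.0)
            new_scale = np.maximum(states.scale * ratio, cfg.kill_scale)

            # element kill: accumulated post-yield axial strain beyond eps_AB
            yielded = states.status == YIELDED
            acc = np.maximum(
                states.post_yield_strain,
                np.where(yielded,
                         np.abs(eps[:, 2]) - states.yield_axial_strain, 0.0))
            kill = yielded & (acc >= eps_limit)
            states.status[kill] = FAILED
            new_scale[kill] = cfg.kill_scale

            scale_change = np.max(np.abs(new_scale - states.scale)
                                  / np.maximum(states.scale, 1e-12))
            changed = newly.any() or kill.any() or scale_change > cfg.scale_tol
            if changed:
                states.scale = new_scale
                K_dirty = True
                lu_age += 1
            if not changed:
                converged = True
                break
            # the recorded observable is the reaction force: once it has
            # stabilized and no element was killed this pass, residual
            # micro-yielding cascades do not change the solution materially
            force_ref = max(abs(F), peak, 1e-12)
            if (F_prev is not None and not kill.any()
                    and abs(F - F_prev) <= cfg.force_tol * force_ref):
                converged = True
                break
            F_prev = F
        if not converged:
            # a fixed point can fail to exist during post-peak softening
            # (snap-through); end the loading there with the last state
            if peak > 0 and F < 0.995 * peak:
                collapsed = True
            else:
                raise ConvergenceError(
                    f"state iteration did not converge at increment {step}")

        states.post_yield_strain = np.maximum(
            states.post_yield_strain,
            np.where(states.status >= YIELDED,
                     np.abs(eps[:, 2]) - states.yield_axial_strain, 0.0))

        disps.append(d)
        forces.append(F)
        peak = max(peak, F)
        if collapsed or (peak > 0 and F < cfg.force_floor_frac * peak):
            break
        if cfg.stop_on_failure and peak > 0 and F < 0.99 * peak:
            break

    curve = LoadDisplacementCurve(np.array(disps), np.array(forces))
    try:
        fl, fd = extract_failure(curve)
        reached = True
    except DegenerateCurveError:
        fl, fd, reached = np.nan, np.nan, False
    return FEAResult(fl, fd, reached, curve,
                     n_yielded=int((states.status == YIELDED).sum()),
                     n_failed=int((states.status == FAILED).sum()),
                     states=states)


def extract_failure(curve: LoadDisplacementCurve,
                    drop_frac: float = 0.01) -> tuple[float, float]:
    """Failure point of a load-displacement curve.

    The failure point is the first local force maximum followed by a drop
    exceeding ``drop_frac`` of that maximum; with no such drop, the global
    maximum. A curve with no positive force is degenerate.
    """
    F = curve.force_N
    d = curve.displacement_mm
    if len(F) < 2:
        raise DegenerateCurveError("curve needs at least 2 points")
    if np.max(F) <= 0:
        raise DegenerateCurveError("no positive force on the curve")
    peak_idx = 0
    for i in range(1, len(F)):
        if F[i] > F[peak_idx]:
            peak_idx = i
        elif F[i] < F[peak_idx] * (1.0 - drop_frac):
            return float(F[peak_idx]), float(d[peak_idx])
    g = int(np.argmax(F))
    return float(F[g]), float(d[g])
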