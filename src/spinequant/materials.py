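"""HU -> density -> stiffness/strength constitutive relations for vertebral bone.

The chain is: a linear HU-to-apparent-density calibration (evaluated in
kg/m^3 as published, then converted to g/cm^3 so the power-law coefficients
are dimensionally meaningful), an ash-density fraction, a transversely
isotropic elastic card about the superior-inferior (z) axis, and
principal-stress strength limits with a density-dependent plastic strain
cap. All moduli are MPa, densities g/cm^3.

Relations::

    rho_app [kg/m^3] = 47 + 1.122 * HU          (floored at 0.001 g/cm^3)
    rho_ash          = 0.6 * rho_app
    E_z  = 4730 * rho_app^1.56                  E_x = E_y = 0.333 E_z
    G_xy = 0.121 E_z     G_xz = G_yz = 0.157 E_z
    nu_xy = 0.381        nu_xz = nu_yz = 0.104
    sigma_max = 137 * rho_ash^1.88   (rho_ash <= 0.317)
              = 114 * rho_ash^1.72   (rho_ash >  0.317)
    sigma_min = 65.1 * rho_ash^1.93
    eps_AB    = max(0, -0.00315 + 0.0728 * rho_ash)
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "MaterialCards",
    "hu_to_apparent_density",
    "apparent_to_ash",
    "elastic_card",
    "strength_card",
    "map_elements",
    "cards_to_csv",
    "cards_to_inp",
]

RHO_APP_FLOOR = 0.001  # g/cm^3; keeps power laws positive for marrow/air voxels
ASH_BRANCH = 0.317  # g/cm^3; strength power-law breakpoint
EX_OVER_EZ = 0.333
GXY_OVER_EZ = 0.121
GXZ_OVER_EZ = 0.157
NU_XY = 0.381
NU_XZ = 0.104


class MappingError(RuntimeError):
    """An element could not be assigned an HU value."""


def hu_to_apparent_density(hu):
    """Apparent density in g/cm^3 from Hounsfield units.

    The linear calibration is evaluated in kg/m^3, divided by 1000, and
    floored at 0.001 g/cm^3 (fatty-marrow and air voxels map to near-zero
    stiffness rather than negative density).
    """
    hu = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU values must be finite")
    rho = (47.0 + 1.122 * hu) / 1000.0
    return np.maximum(rho, RHO_APP_FLOOR)[()]


def apparent_to_ash(rho_app):
    """Ash density = 0.6 * apparent density (both g/cm^3)."""
    rho_app = np.asarray(rho_app, dtype=float)
    if np.any(rho_app < 0):
        raise ValueError("apparent density must be non-negative")
    return (0.6 * rho_app)[()]


def elastic_card(rho_app):
    """Transversely isotropic elastic constants from apparent density.

    Returns a dict with E_z, E_x, E_y, G_xy, G_xz, G_yz (MPa) and the three
    Poisson ratios. z is the superior-inferior axis.
    """
    rho_app = np.asarray(rho_app, dtype=float)
    if np.any(rho_app <= 0):
        raise ValueError("apparent density must be positive for the modulus law")
    E_z = 4730.0 * rho_app**1.56
    ones = np.ones_like(E_z)
    return {
        "E_z": E_z[()],
        "E_x": (EX_OVER_EZ * E_z)[()],
        "E_y": (EX_OVER_EZ * E_z)[()],
        "G_xy": (GXY_OVER_EZ * E_z)[()],
        "G_xz": (GXZ_OVER_EZ * E_z)[()],
        "G_yz": (GXZ_OVER_EZ * E_z)[()],
        "nu_xy": (NU_XY * ones)[()],
        "nu_xz": (NU_XZ * ones)[()],
        "nu_yz": (NU_XZ * ones)[()],
    }


def strength_card(rho_ash):
    """Principal-stress limits (MPa) and plastic strain cap from ash density.

    The maximum-principal-stress law switches branch at 0.317 g/cm^3 (lower
    branch used at the breakpoint itself); eps_AB is clamped at zero where
    the affine relation would go negative (rho_ash < 0.0433 g/cm^3).
    """
    rho_ash = np.asarray(rho_ash, dtype=float)
    if np.any(rho_ash < 0):
        raise ValueError("ash density must be non-negative")
    low = 137.0 * rho_ash**1.88
    high = 114.0 * rho_ash**1.72
    sigma_max = np.where(rho_ash <= ASH_BRANCH, low, high)
    sigma_min = 65.1 * rho_ash**1.93
    eps_ab = np.maximum(0.0, -0.00315 + 0.0728 * rho_ash)
    return sigma_max[()], sigma_min[()], eps_ab[()]


@dataclass
class MaterialCards:
    """Per-element material parameters, stored as parallel arrays.

    One entry per mesh element. Densities g/cm^3, moduli MPa, strengths MPa,
    plastic strain dimensionless.
    """

    rho_app: np.ndarray
    rho_ash: np.ndarray
    E_z: np.ndarray
    E_x: np.ndarray
    E_y: np.ndarray
    G_xy: np.ndarray
    G_xz: np.ndarray
    G_yz: np.ndarray
    nu_xy: np.ndarray
    nu_xz: np.ndarray
    nu_yz: np.ndarray
    sigma_max: np.ndarray
    sigma_min: np.ndarray
    eps_AB: np.ndarray

    def __post_init__(self) -> None:
        n = None
        for f in fields(self):
            arr = np.atleast_1d(np.asarray(getattr(self, f.name), dtype=float))
            setattr(self, f.name, arr)
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError("all MaterialCards fields must have equal length")

    def __len__(self) -> int:
        return len(self.E_z)

    @classmethod
    def from_hu(cls, hu) -> "MaterialCards":
        """Compose the full density -> elasticity -> strength chain."""
        hu = np.atleast_1d(np.asarray(hu, dtype=float))
        rho_app = hu_to_apparent_density(hu)
        rho_ash = apparent_to_ash(rho_app)
        el = elastic_card(rho_app)
        sigma_max, sigma_min, eps_ab = strength_card(rho_ash)
        return cls(rho_app=rho_app, rho_ash=rho_ash, sigma_max=sigma_max,
                   sigma_min=sigma_min, eps_AB=eps_ab, **el)

    @classmethod
    def isotropic(cls, n: int, E: float, nu: float, sigma_max: float = np.inf,
                  sigma_min: float = np.inf, eps_ab: float = np.inf) -> "MaterialCards":
        """Isotropic override card (verification against closed forms)."""
        o = np.ones(n)
        G = E / (2.0 * (1.0 + nu))
        return cls(rho_app=o, rho_ash=0.6 * o, E_z=E * o, E_x=E * o, E_y=E * o,
                   G_xy=G * o, G_xz=G * o, G_yz=G * o, nu_xy=nu * o, nu_xz=nu * o,
                   nu_yz=nu * o, sigma_max=sigma_max * o, sigma_min=sigma_min * o,
                   eps_AB=eps_ab * o)


MODULUS_EXPONENT = 1.56  # E_z power-law exponent, reused for E-integration


def _effective_hu(hu_vox: np.ndarray, integration: str) -> float:
    """Collapse the voxel HU sample of one element to one effective HU.

    'hu': plain arithmetic mean of HU. 'modulus': volume-average the
    elastic modulus instead — the per-voxel apparent densities are averaged
    under the modulus power law and converted back to an equivalent HU, so
    that the element's E_z equals the mean of the voxel-wise E_z. The
    modulus integration removes the systematic stiffening of coarse
    elements that HU averaging produces under the convex density-modulus
    law (Jensen bias), which is what makes failure loads mesh-converged.
    """
    if integration == "hu":
        return float(np.mean(hu_vox))
    rho = hu_to_apparent_density(hu_vox)
    rho_eff = float(np.mean(np.atleast_1d(rho) ** MODULUS_EXPONENT)
                    ** (1.0 / MODULUS_EXPONENT))
    return (1000.0 * rho_eff - 47.0) / 1.122


def _cell_hu(ct, mesh, mask, integration: str) -> np.ndarray:
    """Effective HU per element for cell-derived meshes.

    All six tetrahedra of a source cell share the effective HU pooled over
    the cell's (masked) voxels. Pooling at cell level partitions the masked
    voxel set identically at every cell size, so integrated stiffness and
    strength are independent of the mesh resolution.
    """
    data = ct.data
    n_cells = len(mesh.cell_ranges)
    sel = mesh.cell_assignment >= 0
    if mask is not None:
        sel &= mask.binary()
    ids = mesh.cell_assignment[sel]
    vals = data[sel]
    counts = np.bincount(ids, minlength=n_cells).astype(float)
    if integration == "modulus":
        w = np.bincount(ids, weights=np.atleast_1d(
            hu_to_apparent_density(vals)) ** MODULUS_EXPONENT,
            minlength=n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_eff = (w / counts) ** (1.0 / MODULUS_EXPONENT)
        hu_cell = (1000.0 * rho_eff - 47.0) / 1.122
    else:
        w = np.bincount(ids, weights=vals, minlength=n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            hu_cell = w / counts
    # cells with no contributing voxel: HU at the cell-box centre
    for c in np.flatnonzero(counts == 0):
        a, b = mesh.cell_ranges[c]
        mid = tuple(np.minimum((a + b) // 2, np.asarray(data.shape) - 1))
        hu_cell[c] = data[mid]
    return hu_cell[mesh.element_cell]


def element_hu(ct, mesh, mask=None, integration: str = "modulus") -> np.ndarray:
    """Effective HU per element from voxel centers inside it.

    Voxel centers are at (i + 0.5) * spacing in the mesh coordinate frame.
    With ``mask`` given, only voxels inside the segmentation contribute —
    boundary elements then carry bone HU rather than a bone/air mixture
    whose proportions depend on the element size. ``integration`` selects
    plain HU averaging ('hu') or modulus-consistent averaging ('modulus',
    default; see :func:`_effective_hu`). Elements with no interior voxel
    center fall back to the HU at the nearest voxel to their centroid;
    elements whose bounding box misses the volume entirely raise
    :class:`MappingError` naming the element.
    """
    if integration not in ("hu", "modulus"):
        raise ValueError("integration must be 'hu' or 'modulus'")
    if getattr(mesh, "cell_ranges", None) is not None:
        return _cell_hu(ct, mesh, mask, integration)
    sp = np.asarray(ct.spacing)
    shape = np.asarray(ct.shape)
    allowed = None if mask is None else mask.binary()
    nodes = mesh.nodes
    elems = mesh.elements
    hu_out = np.empty(len(elems))
    coords = nodes[elems]  # (m, 4, 3)
    los = np.floor(coords.min(axis=1) / sp - 0.5).astype(int)
    his = np.ceil(coords.max(axis=1) / sp - 0.5).astype(int) + 1
    for e in range(len(elems)):
        lo = np.maximum(los[e], 0)
        hi = np.minimum(his[e], shape)
        if np.any(lo >= hi):
            raise MappingError(f"element {e} lies outside the CT volume")
        ii, jj, kk = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)),
                                 indexing="ij")
        idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        centers = (idx + 0.5) * sp
        inside = _barycentric_inside(coords[e], centers)
        if allowed is not None and inside.any():
            masked = inside & allowed[idx[:, 0], idx[:, 1], idx[:, 2]]
            if masked.any():
                inside = masked
        if inside.any():
            sel = idx[inside]
            hu_out[e] = _effective_hu(
                ct.data[sel[:, 0], sel[:, 1], sel[:, 2]], integration)
        else:
            cen = coords[e].mean(axis=0)
            vox = np.clip(np.round(cen / sp - 0.5).astype(int), 0, shape - 1)
            hu_out[e] = ct.data[tuple(vox)]
    return hu_out


def _barycentric_inside(tet: np.ndarray, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    T = np.column_stack([tet[1] - tet[0], tet[2] - tet[0], tet[3] - tet[0]])
    lam = np.linalg.solve(T, (pts - tet[0]).T).T
    w = 1.0 - lam.sum(axis=1)
    return (lam >= -tol).all(axis=1) & (w >= -tol)


def map_elements(ct, mesh, mask=None, integration: str = "modulus",
                 partial_volume: bool = True) -> MaterialCards:
    """Assign a material card to every mesh element from the CT volume.

    Pass the segmentation ``mask`` to restrict the per-element HU sample to
    voxels inside the vertebra; ``integration`` as in :func:`element_hu`.
    With ``partial_volume`` (default), boundary elements are homogenized:
    moduli and strength limits are scaled by the element's masked-volume
    fraction, so the structure's integrated stiffness and load capacity
    converge to the true boundary integral independent of the cell size.
    Applied only together with a mask (otherwise the element is all tissue).
    """
    cards = MaterialCards.from_hu(element_hu(ct, mesh, mask, integration))
    occ = getattr(mesh, "element_occupancy", None)
    if partial_volume and mask is not None and occ is not None:
        for name in ("E_z", "E_x", "E_y", "G_xy", "G_xz", "G_yz",
                     "sigma_max", "sigma_min"):
            setattr(cards, name, getattr(cards, name) * occ)
    return cards


def cards_to_csv(cards: MaterialCards, path: str) -> None:
    """One row per element, all card fields."""
    import pandas as pd

    pd.DataFrame({f.name: getattr(cards, f.name) for f in fields(cards)}).to_csv(
        path, index_label="element"
    )


def cards_to_inp(cards: MaterialCards, path: str, n_bins: int = 100) -> np.ndarray:
    """Write an Abaqus-style material block with binned element sets.

    Elements are binned on E_z into ``n_bins`` equal-width bins; each bin
    becomes one *MATERIAL with the bin-mean constants. Returns the bin index
    per element (for pairing with a mesh INP export).
    """
    ez = cards.E_z
    edges = np.linspace(ez.min(), ez.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(ez, edges) - 1, 0, n_bins - 1)
    lines = ["** spinequant material cards"]
    for b in np.unique(which):
        sel = which == b
        lines.append(f"*ELSET, ELSET=MAT{b + 1}")
        ids = np.flatnonzero(sel) + 1
        for i in range(0, len(ids), 16):
            lines.append(", ".join(str(x) for x in ids[i:i + 16]))
        lines.append(f"*MATERIAL, NAME=MAT{b + 1}")
        lines.append("*ELASTIC, TYPE=ENGINEERING CONSTANTS")
        lines.append(
            f"{cards.E_x[sel].mean():.6g}, {cards.E_y[sel].mean():.6g}, "
            f"{cards.E_z[sel].mean():.6g}, {cards.nu_xy[sel].mean():.4g}, "
            f"{cards.nu_xz[sel].mean():.4g}, {cards.nu_yz[sel].mean():.4g}, "
            f"{cards.G_xy[sel].mean():.6g}, {cards.G_xz[sel].mean():.6g}"
        )
        lines.append(f"{cards.G_yz[sel].mean():.6g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return which
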