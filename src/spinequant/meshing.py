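"""Voxel mask -> conforming linear-tetrahedral (C3D4) mesh.

Voxels are aggregated into cubic cells of side close to the requested edge
length; every cell at least half occupied by the mask becomes six tetrahedra
via the Kuhn/Freudenthal subdivision. The subdivision uses the same main
diagonal in every cell, which makes shared cell faces carry matching
triangle diagonals, so the global mesh is conforming by construction.

Boundary node sets for compression loading are the nodes on the lowest and
highest occupied z-planes (phantoms are axis-aligned; the superior-inferior
axis is z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

__all__ = ["TetMesh", "mask_to_mesh", "convergence_study", "mesh_to_vtu", "mesh_to_inp"]


class MeshError(RuntimeError):
    pass


# Kuhn subdivision: for each axis permutation, walk from corner (0,0,0) to
# (1,1,1) adding one axis at a time; the four visited corners form one tet.
def _kuhn_tets() -> np.ndarray:
    tets = []
    for perm in sorted(permutations(range(3))):
        corner = np.zeros(3, dtype=int)
        verts = [corner.copy()]
        for ax in perm:
            corner = corner.copy()
            corner[ax] = 1
            verts.append(corner)
        tets.append(verts)
    return np.array(tets)  # (6, 4, 3) corner offsets


_KUHN = _kuhn_tets()


@dataclass
class TetMesh:
    """Linear tetrahedral mesh in mm coordinates.

    ``elements`` are 4-node index rows ordered for positive volume;
    ``inferior_nodes`` / ``superior_nodes`` are the loading surface node sets.
    """

    nodes: np.ndarray  # (n, 3) float, mm
    elements: np.ndarray  # (m, 4) int
    element_material: np.ndarray = None
    inferior_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    superior_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    # masked-volume fraction of the source cell; boundary elements < 1
    element_occupancy: np.ndarray = None
    # provenance of cell-derived meshes: voxel index ranges per source cell
    # (n_cells, 2, 3), the source cell of every element, and the voxel ->
    # cell assignment map (volume-shaped int array, -1 outside; masked
    # voxels of dropped boundary cells are adopted by the nearest kept
    # cell so the material integrals are conserved at any cell size);
    # None for meshes not built from a voxel grid
    cell_ranges: np.ndarray = None
    element_cell: np.ndarray = None
    cell_assignment: np.ndarray = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=int)
        if self.element_material is None:
            self.element_material = np.zeros(len(self.elements), dtype=int)
        if self.element_occupancy is None:
            self.element_occupancy = np.ones(len(self.elements))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def volumes(self) -> np.ndarray:
        c = self.nodes[self.elements]
        return np.linalg.det(c[:, 1:] - c[:, :1]) / 6.0

    def faces(self) -> np.ndarray:
        """All element faces as sorted node triples, one row per face use."""
        e = self.elements
        f = np.concatenate([e[:, [0, 1, 2]], e[:, [0, 1, 3]],
                            e[:, [0, 2, 3]], e[:, [1, 2, 3]]])
        return np.sort(f, axis=1)


def mask_to_mesh(mask, ct, edge_length_mm: float, occupancy: float = 0.5,
                 label: int | None = None) -> TetMesh:
    """Mesh a segmentation mask with six-tet cells of side ~= edge_length.

    The cell side is the nearest integer multiple of the voxel spacing per
    axis (at least one voxel). A cell is kept when the masked volume
    fraction over the full cell is >= ``occupancy``.
    """
    binary = mask.binary(label)
    if not binary.any():
        raise MeshError("mask is empty")
    sp = np.asarray(ct.spacing)
    if edge_length_mm < max(sp):
        raise ValueError(
            f"edge length {edge_length_mm} mm below voxel spacing {max(sp)} mm"
        )
    nvox = np.maximum(1, np.round(edge_length_mm / sp).astype(int))

    idx = np.argwhere(binary)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    ncell = -((lo - hi) // nvox)  # ceil division

    # cell occupancy by box-sum of the binary mask
    occ = np.zeros(tuple(ncell))
    full = float(np.prod(nvox))
    for ci in np.ndindex(*ncell):
        a = lo + np.array(ci) * nvox
        b = np.minimum(a + nvox, binary.shape)
        occ[ci] = binary[a[0]:b[0], a[1]:b[1], a[2]:b[2]].sum() / full
    keep = np.argwhere(occ >= occupancy)
    if len(keep) == 0:
        raise MeshError("no cell reaches the occupancy threshold")

    # voxel -> kept-cell assignment; masked voxels in dropped boundary
    # cells are adopted by the nearest kept cell (Chebyshev rings) so that
    # the material integrals over the segmentation do not depend on the
    # cell size
    kept_id = np.full(tuple(ncell), -1, dtype=int)
    for c, ci in enumerate(keep):
        kept_id[tuple(ci)] = c
    assignment = np.full(binary.shape, -1, dtype=np.int32)
    for c, ci in enumerate(keep):
        a = lo + ci * nvox
        b = np.minimum(a + nvox, binary.shape)
        assignment[a[0]:b[0], a[1]:b[1], a[2]:b[2]] = c
    for ci in np.argwhere((occ > 0) & (occ < occupancy)):
        target = -1
        for r in (1, 2, 3):
            ring = []
            for off in np.ndindex(*(2 * r + 1,) * 3):
                d = np.array(off) - r
                if np.abs(d).max() != r:
                    continue
                cj = ci + d
                if np.all(cj >= 0) and np.all(cj < ncell) and kept_id[tuple(cj)] >= 0:
                    ring.append((np.abs(d).sum(), kept_id[tuple(cj)]))
            if ring:
                target = min(ring)[1]
                break
        if target < 0:
            continue  # isolated blob: its voxels stay unrepresented
        a = lo + ci * nvox
        b = np.minimum(a + nvox, binary.shape)
        sub = np.s_[a[0]:b[0], a[1]:b[1], a[2]:b[2]]
        adopt = binary[sub]
        assignment[sub][adopt] = target

    masked_counts = np.bincount(
        assignment[binary & (assignment >= 0)], minlength=len(keep))
    cell_occ = masked_counts / full  # can exceed 1 after adoption

    # global corner-node grid
    corner_ids = {}
    nodes = []

    def node_id(gc):
        key = tuple(gc)
        if key not in corner_ids:
            corner_ids[key] = len(nodes)
            nodes.append((lo + np.asarray(gc) * nvox) * sp)
        return corner_ids[key]

    elements = []
    materials = []
    occupancies = []
    cell_ranges = []
    element_cell = []
    for c, ci in enumerate(keep):
        a = lo + ci * nvox
        b = np.minimum(a + nvox, binary.shape)
        cell_ranges.append([a, b])
        corner_nodes = np.empty((2, 2, 2), dtype=int)
        for off in np.ndindex(2, 2, 2):
            corner_nodes[off] = node_id(ci + np.array(off))
        for tet in _KUHN:
            elements.append([corner_nodes[tuple(v)] for v in tet])
            materials.append(0)
            occupancies.append(cell_occ[c])
            element_cell.append(c)
    nodes = np.asarray(nodes)
    elements = np.asarray(elements, dtype=int)

    # enforce positive orientation deterministically
    c = nodes[elements]
    neg = np.linalg.det(c[:, 1:] - c[:, :1]) < 0
    elements[neg] = elements[neg][:, [0, 1, 3, 2]]

    z = nodes[:, 2]
    inferior = np.flatnonzero(np.isclose(z, z.min()))
    superior = np.flatnonzero(np.isclose(z, z.max()))
    return TetMesh(nodes, elements, np.asarray(materials), inferior, superior,
                   np.asarray(occupancies), np.asarray(cell_ranges),
                   np.asarray(element_cell), assignment)


def convergence_study(ct, mask, edge_lengths_mm=(1.0, 1.5, 2.0, 2.5, 3.0),
                      solver_config=None, cards_fn=None):
    """Run the full compression solve at each edge length.

    Returns a DataFrame with failure load/displacement per edge length and
    the relative change between successive refinement levels (coarse vs the
    next finer mesh).
    """
    import pandas as pd

    from .fe import CompressionConfig, run_compression
    from .materials import map_elements

    cfg = solver_config or CompressionConfig()
    rows = []
    for h in edge_lengths_mm:
        try:
            mesh = mask_to_mesh(mask, ct, h)
            cards = (map_elements(ct, mesh, mask) if cards_fn is None
                     else cards_fn(mesh))
            res = run_compression(mesh, cards, config=cfg)
        except Exception as exc:  # tag solver failures with the edge length
            raise RuntimeError(f"solve failed at edge length {h} mm") from exc
        rows.append({"edge_length_mm": h, "n_elements": mesh.n_elements,
                     "failure_load_N": res.failure_load,
                     "failure_displacement_mm": res.failure_displacement})
    df = pd.DataFrame(rows).sort_values("edge_length_mm", ignore_index=True)
    rel = [np.nan]
    for i in range(1, len(df)):
        prev = df.failure_load_N[i - 1]
        rel.append(abs(df.failure_load_N[i] - prev) / abs(prev))
    df["rel_change_vs_finer"] = rel
    return df


def mesh_to_vtu(mesh: TetMesh, path: str) -> None:
    """Minimal ASCII VTK XML unstructured-grid export (tet cells only)."""
    n, m = mesh.n_nodes, mesh.n_elements
    pts = " ".join(f"{x:.9g}" for x in mesh.nodes.ravel())
    conn = " ".join(str(i) for i in mesh.elements.ravel())
    offs = " ".join(str(4 * (i + 1)) for i in range(m))
    types = " ".join("10" for _ in range(m))
    mat = " ".join(str(i) for i in mesh.element_material)
    with open(path, "w") as fh:
        fh.write(
            '<?xml version="1.0"?>\n'
            '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
            f'<UnstructuredGrid><Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n'
            '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n'
            f"{pts}\n</DataArray></Points>\n<Cells>\n"
            '<DataArray type="Int64" Name="connectivity" format="ascii">\n'
            f"{conn}\n</DataArray>\n"
            '<DataArray type="Int64" Name="offsets" format="ascii">\n'
            f"{offs}\n</DataArray>\n"
            '<DataArray type="UInt8" Name="types" format="ascii">\n'
            f"{types}\n</DataArray>\n</Cells>\n"
            '<CellData><DataArray type="Int32" Name="material" format="ascii">\n'
            f"{mat}\n</DataArray></CellData>\n"
            "</Piece></UnstructuredGrid></VTKFile>\n"
        )


def mesh_to_inp(mesh: TetMesh, path: str) -> None:
    """Abaqus INP export: nodes, C3D4 elements, loading-surface NSETs."""
    lines = ["*NODE"]
    for i, p in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}")
    lines.append("*ELEMENT, TYPE=C3D4")
    for i, e in enumerate(mesh.elements, start=1):
        lines.append(f"{i}, {e[0] + 1}, {e[1] + 1}, {e[2] + 1}, {e[3] + 1}")
    for name, ids in (("INFERIOR", mesh.inferior_nodes),
                      ("SUPERIOR", mesh.superior_nodes)):
        lines.append(f"*NSET, NSET={name}")
        ids1 = np.asarray(ids) + 1
        for i in range(0, len(ids1), 16):
            lines.append(", ".join(str(x) for x in ids1[i:i + 16]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
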