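"""Tetrahedral meshes: container, validation, boundary topology, point location, I/O.

All coordinates are in millimetres.  Node and element indices are 0-based
internally; the two-file node/ele ASCII format is 1-based on disk and is
converted at the I/O boundary.  Element node order is normalized on
construction so that every signed volume is positive, which keeps the FEM
assembly sign-safe.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Mesh",
    "MeshFormatError",
    "OutsideMeshError",
    "load_mesh",
    "save_mesh",
    "save_vtk",
    "boundary_nodes",
    "locate_element",
]


class MeshFormatError(ValueError):
    """Malformed mesh data: bad indices, degenerate elements, unreadable file."""


class OutsideMeshError(ValueError):
    """A query point does not lie inside any element of the mesh."""


# The four faces of a tetrahedron (local corner indices).
_TET_FACES = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])


@dataclasses.dataclass
class Mesh:
    """Linear tetrahedral mesh.

    Parameters
    ----------
    nodes : (n, 3) float array
        Node coordinates in mm.
    elements : (m, 4) int array
        Node indices of each tetrahedron (0-based).
    region : (m,) int array, optional
        Integer region label per element (defaults to zeros).
    boundary : (n,) bool array, optional
        Boundary flag per node.  Computed from face topology when omitted:
        a node is on the boundary iff it belongs to a face owned by exactly
        one element.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray | None = None
    boundary: np.ndarray | None = None

    def __post_init__(self) -> None:
        nodes = np.ascontiguousarray(np.asarray(self.nodes, dtype=float))
        elements = np.ascontiguousarray(np.asarray(self.elements, dtype=np.int64))
        if nodes.ndim != 2 or nodes.shape[1] != 3:
            raise MeshFormatError(f"nodes must be (n, 3), got {nodes.shape}")
        if elements.ndim != 2 or elements.shape[1] != 4:
            raise MeshFormatError(f"elements must be (m, 4), got {elements.shape}")
        if not np.all(np.isfinite(nodes)):
            bad = int(np.flatnonzero(~np.isfinite(nodes).all(axis=1))[0])
            raise MeshFormatError(f"non-finite coordinates at node {bad}")
        if elements.size and (elements.min() < 0 or elements.max() >= len(nodes)):
            bad = int(
                np.flatnonzero(
                    (elements < 0).any(axis=1) | (elements >= len(nodes)).any(axis=1)
                )[0]
            )
            raise MeshFormatError(f"element {bad} references a missing node")
        # Repeated corner => zero volume, caught below; check explicitly for a
        # clearer message.
        sorted_el = np.sort(elements, axis=1)
        dup = (np.diff(sorted_el, axis=1) == 0).any(axis=1)
        if dup.any():
            raise MeshFormatError(
                f"element {int(np.flatnonzero(dup)[0])} repeats a node index"
            )

        # Orientation fix: swap the last two corners where the signed volume
        # is negative, then reject any element that is still non-positive
        # (degenerate) relative to its own edge scale.
        vol = _signed_volumes(nodes, elements)
        flip = vol < 0
        if flip.any():
            elements = elements.copy()
            elements[flip, 2], elements[flip, 3] = (
                elements[flip, 3].copy(),
                elements[flip, 2].copy(),
            )
            vol = np.abs(vol)
        edge = _longest_edges(nodes, elements)
        degenerate = vol <= 1e-10 * edge**3
        if degenerate.any():
            raise MeshFormatError(
                f"degenerate element {int(np.flatnonzero(degenerate)[0])} "
                "(zero signed volume)"
            )

        region = self.region
        if region is None:
            region = np.zeros(len(elements), dtype=np.int64)
        else:
            region = np.asarray(region, dtype=np.int64)
            if region.shape != (len(elements),):
                raise MeshFormatError("region labels must be one per element")

        self.nodes = nodes
        self.elements = elements
        self.region = region
        if self.boundary is None:
            self.boundary = _boundary_flags(len(nodes), elements)
        else:
            self.boundary = np.asarray(self.boundary, dtype=bool)
            if self.boundary.shape != (len(nodes),):
                raise MeshFormatError("boundary flags must be one per node")
        self._centroid_tree: cKDTree | None = None

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        """Positive tetrahedron volumes in mm^3."""
        return _signed_volumes(self.nodes, self.elements)

    def boundary_faces(self) -> np.ndarray:
        """(f, 3) node indices of faces owned by exactly one element."""
        faces = self.elements[:, _TET_FACES].reshape(-1, 3)
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        return faces[idx[counts == 1]]

    def _tree(self) -> cKDTree:
        if self._centroid_tree is None:
            centroids = self.nodes[self.elements].mean(axis=1)
            self._centroid_tree = cKDTree(centroids)
        return self._centroid_tree


def _signed_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = nodes[elements]
    e = p[:, 1:, :] - p[:, :1, :]
    return np.linalg.det(e) / 6.0


def _longest_edges(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = nodes[elements]
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    d = np.stack(
        [np.linalg.norm(p[:, i] - p[:, j], axis=1) for i, j in pairs], axis=1
    )
    return d.max(axis=1)


def _boundary_flags(n_nodes: int, elements: np.ndarray) -> np.ndarray:
    faces = np.sort(elements[:, _TET_FACES].reshape(-1, 3), axis=1)
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    flags = np.zeros(n_nodes, dtype=bool)
    flags[uniq[counts == 1].ravel()] = True
    return flags


def boundary_nodes(mesh: Mesh) -> np.ndarray:
    """Sorted indices of nodes on single-owner (surface) faces."""
    return np.flatnonzero(mesh.boundary)


def locate_element(
    mesh: Mesh, point, tol: float = 1e-8
) -> tuple[int, np.ndarray]:
    """Find the element containing ``point`` and its barycentric weights.

    Returns ``(element_index, weights)`` with ``weights`` nonnegative and
    summing to one.  Raises :class:`OutsideMeshError` when the point is not
    inside any element (within ``tol`` of the barycentric boundary).
    """
    point = np.asarray(point, dtype=float).reshape(3)
    tree = mesh._tree()
    m = mesh.n_elements
    k = min(8, m)
    seen = 0
    while True:
        _, idx = tree.query(point, k=k)
        idx = np.atleast_1d(idx)[seen:]
        for ei in idx:
            w = _barycentric(mesh, int(ei), point)
            if w.min() >= -tol:
                w = np.clip(w, 0.0, None)
                return int(ei), w / w.sum()
        if k >= m:
            raise OutsideMeshError(f"point {point.tolist()} lies outside the mesh")
        seen = k
        k = min(k * 16, m)


def _barycentric(mesh: Mesh, element: int, point: np.ndarray) -> np.ndarray:
    p = mesh.nodes[mesh.elements[element]]
    # Columns of E are the edge vectors from corner 0.
    e = (p[1:] - p[0]).T
    b = np.linalg.solve(e, point - p[0])
    return np.concatenate(([1.0 - b.sum()], b))


# -- I/O -------------------------------------------------------------------


def load_mesh(path) -> Mesh:
    """Load a mesh from VTK legacy ASCII (.vtk) or the node/ele pair format.

    For the pair format pass either the ``.node`` file or the common stem;
    the matching ``.ele`` file must sit next to it.
    """
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        return _load_vtk(path)
    return _load_pair(path)


def save_mesh(path, mesh: Mesh) -> None:
    """Save to VTK legacy ASCII (.vtk) or the node/ele pair format."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        save_vtk(path, mesh)
    else:
        _save_pair(path, mesh)


def _load_vtk(path: Path) -> Mesh:
    try:
        tokens = path.read_text().split()
    except OSError as exc:
        raise MeshFormatError(f"cannot read {path}: {exc}") from exc
    upper = [t.upper() for t in tokens]

    def _find(word: str) -> int:
        try:
            return upper.index(word)
        except ValueError:
            raise MeshFormatError(f"{path}: missing VTK keyword {word}") from None

    i = _find("POINTS")
    n = int(tokens[i + 1])
    coords = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
    i = _find("CELLS")
    m = int(tokens[i + 1])
    total = int(tokens[i + 2])
    raw = np.array(tokens[i + 3 : i + 3 + total], dtype=np.int64)
    elements = np.empty((m, 4), dtype=np.int64)
    pos = 0
    for c in range(m):
        cnt = raw[pos]
        if cnt != 4:
            raise MeshFormatError(f"{path}: cell {c} has {cnt} nodes, expected 4")
        elements[c] = raw[pos + 1 : pos + 5]
        pos += 5
    i = _find("CELL_TYPES")
    types = np.array(tokens[i + 2 : i + 2 + m], dtype=int)
    if not np.all(types == 10):
        bad = int(np.flatnonzero(types != 10)[0])
        raise MeshFormatError(f"{path}: cell {bad} is not a linear tetrahedron")
    region = None
    if "CELL_DATA" in upper:
        j = upper.index("CELL_DATA")
        # look for a SCALARS region block
        for k in range(j, len(upper) - 2):
            if upper[k] == "SCALARS" and tokens[k + 1] == "region":
                start = k + 5  # SCALARS name type [ncomp] LOOKUP_TABLE default
                if upper[k + 3] != "LOOKUP_TABLE":
                    start = k + 6
                region = np.array(tokens[start : start + m], dtype=np.int64)
                break
    return Mesh(coords, elements, region=region)


def save_vtk(path, mesh: Mesh, point_data: dict | None = None) -> None:
    """Write VTK legacy ASCII unstructured grid, optionally with nodal fields."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "lumitomo mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in row) for row in mesh.nodes]
    m = mesh.n_elements
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(map(str, el)) for el in mesh.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += ["10"] * m
    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(r) for r in mesh.region]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (mesh.n_nodes,):
                raise ValueError(f"point data {name!r} must be one value per node")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.10g}" for v in values]
    path.write_text("\n".join(lines) + "\n")


def _pair_paths(path: Path) -> tuple[Path, Path]:
    if path.suffix == ".node":
        return path, path.with_suffix(".ele")
    if path.suffix == ".ele":
        return path.with_suffix(".node"), path
    return path.with_suffix(".node"), path.with_suffix(".ele")


def _load_pair(path: Path) -> Mesh:
    node_path, ele_path = _pair_paths(path)
    if not node_path.exists() or not ele_path.exists():
        raise MeshFormatError(f"mesh files {node_path} / {ele_path} not found")
    node_rows = _read_table(node_path)
    n = int(node_rows[0][0])
    coords = np.array([r[1:4] for r in node_rows[1 : n + 1]], dtype=float)
    ele_rows = _read_table(ele_path)
    m = int(ele_rows[0][0])
    body = np.array([r[1:] for r in ele_rows[1 : m + 1]], dtype=np.int64)
    elements = body[:, :4] - 1  # on-disk format is 1-based
    region = body[:, 4] if body.shape[1] > 4 else None
    return Mesh(coords, elements, region=region)


def _read_table(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.split("#")[0].strip()
        if line:
            rows.append(line.split())
    if not rows:
        raise MeshFormatError(f"{path}: empty file")
    return rows


def _save_pair(path: Path, mesh: Mesh) -> None:
    node_path, ele_path = _pair_paths(path)
    with node_path.open("w") as fh:
        fh.write(f"{mesh.n_nodes} 3\n")
        for i, row in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} " + " ".join(f"{v:.10g}" for v in row) + "\n")
    with ele_path.open("w") as fh:
        fh.write(f"{mesh.n_elements} 4\n")
        for i, (el, reg) in enumerate(zip(mesh.elements, mesh.region), start=1):
            fh.write(f"{i} " + " ".join(str(v + 1) for v in el) + f" {reg}\n")
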