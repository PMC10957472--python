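"""Mesh data model, graph Laplacians, Procrustes alignment and geometric indices.

All cohorts are *registered*: every subject's mesh has the same number of
vertices ``M`` and identical triangle connectivity, so a subject is fully
described by its vertex coordinate matrix ``S_i`` (M x 3, millimetres) and the
shared adjacency ``A``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh


class MeshStructureError(ValueError):
    """Raised when faces/vertices violate the triangle-mesh contract."""


# ---------------------------------------------------------------------------
# TriangleMesh
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """A triangle mesh with vertices in millimetres.

    Attributes
    ----------
    vertices : (M, 3) float array
    faces : (F, 3) int array of 0-based vertex indices
    adjacency : (M, M) sparse binary symmetric matrix, zero diagonal
    """

    vertices: np.ndarray
    faces: np.ndarray
    adjacency: sp.csr_matrix = field(repr=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[0] < e[1]."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])

    def is_closed(self) -> bool:
        """True iff every edge is shared by exactly two faces."""
        return _edge_face_counts(self.faces).size > 0 and bool(
            np.all(_edge_face_counts(self.faces) == 2)
        )

    def copy_with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(np.asarray(vertices, float), self.faces, self.adjacency)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def _edge_face_counts(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return counts


def adjacency_from_faces(n_vertices: int, faces: np.ndarray) -> sp.csr_matrix:
    """Symmetric 0/1 adjacency with zero diagonal derived from the face list."""
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    data = np.ones(i.size)
    a = sp.coo_matrix((data, (i, j)), shape=(n_vertices, n_vertices))
    a = a + a.T
    a.data[:] = 1.0
    a = a.tocsr()
    a.setdiag(0)
    a.eliminate_zeros()
    return a


def build_mesh(vertices: np.ndarray, faces: np.ndarray, repair_winding: bool = True) -> TriangleMesh:
    """Validate raw arrays and assemble a :class:`TriangleMesh`.

    Orientation is auto-repaired by majority winding when the faces of a
    closed mesh are inconsistently wound (a warning is emitted).
    """
    vertices = np.ascontiguousarray(vertices, dtype=float)
    faces = np.ascontiguousarray(faces, dtype=np.int64)
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise MeshStructureError("vertices must be an (M, 3) array")
    m = vertices.shape[0]
    if m < 3:
        raise MeshStructureError(f"need at least 3 vertices, got {m}")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshStructureError("faces must be an (F, 3) array")
    if faces.min(initial=0) < 0 or faces.max(initial=-1) >= m:
        raise MeshStructureError("face index out of range [0, M)")
    degenerate = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    if degenerate.any():
        raise MeshStructureError(
            f"degenerate faces with repeated vertices at rows {np.flatnonzero(degenerate)[:5]}"
        )
    if repair_winding and _edge_face_counts(faces).max(initial=0) == 2:
        # closed mesh: check winding consistency via directed edge duplicates
        directed = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        _, cnt = np.unique(directed, axis=0, return_counts=True)
        if cnt.max(initial=1) > 1:
            warnings.warn("inconsistent face winding; repairing by majority winding")
            tm = trimesh.Trimesh(vertices, faces, process=False)
            trimesh.repair.fix_normals(tm)
            faces = np.asarray(tm.faces, dtype=np.int64)
    return TriangleMesh(vertices, faces, adjacency_from_faces(m, faces))


# ---------------------------------------------------------------------------
# Graph Laplacian
# ---------------------------------------------------------------------------

@dataclass
class GraphLaplacian:
    """Combinatorial (``D - A``) or scaled symmetric-normalized Laplacian.

    The scaled mode returns ``2 L_sym / lambda_max - I`` with
    ``L_sym = I - D^{-1/2} A D^{-1/2}``, whose spectrum lies in [-1, 1] as
    required for stable Chebyshev polynomial filtering.
    """

    laplacian: sp.csr_matrix
    mode: str
    lambda_max: float | None = None

    @property
    def n(self) -> int:
        return self.laplacian.shape[0]


def _lambda_max_power_iteration(l_sym: sp.csr_matrix, tol: float = 1e-6, max_iter: int = 1000) -> float:
    rng = np.random.default_rng(0)
    x = rng.standard_normal(l_sym.shape[0])
    x /= np.linalg.norm(x)
    lam = 0.0
    for _ in range(max_iter):
        y = l_sym @ x
        lam_new = float(x @ y)
        ny = np.linalg.norm(y)
        if ny == 0:
            return 0.0
        x = y / ny
        if abs(lam_new - lam) < tol:
            return lam_new
        lam = lam_new
    return lam


def graph_laplacian(mesh: TriangleMesh, mode: str = "combinatorial") -> GraphLaplacian:
    """Build the graph Laplacian of the mesh in the requested ``mode``."""
    a = mesh.adjacency
    deg = mesh.degrees()
    if mode == "combinatorial":
        lap = sp.diags(deg) - a
        return GraphLaplacian(lap.tocsr(), mode)
    if mode in ("scaled", "sym-normalized-scaled"):
        if np.any(deg == 0):
            raise MeshStructureError("isolated vertex (degree 0) in scaled Laplacian mode")
        d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
        l_sym = (sp.eye(mesh.n_vertices) - d_inv_sqrt @ a @ d_inv_sqrt).tocsr()
        try:
            v0 = np.random.default_rng(0).standard_normal(l_sym.shape[0])
            lam_max = float(
                spla.eigsh(l_sym, k=1, which="LA", return_eigenvectors=False, tol=1e-9, v0=v0)[0]
            )
        except Exception:  # Lanczos can fail on tiny/degenerate graphs
            lam_max = _lambda_max_power_iteration(l_sym)
        lam_max = max(lam_max, 1e-12)
        lap = (2.0 / lam_max) * l_sym - sp.eye(mesh.n_vertices)
        return GraphLaplacian(lap.tocsr(), "sym-normalized-scaled", lam_max)
    raise ValueError(f"unknown Laplacian mode {mode!r}")


# ---------------------------------------------------------------------------
# ShapeCohort
# ---------------------------------------------------------------------------

@dataclass
class ShapeCohort:
    """A registered cohort: N subjects sharing one template connectivity."""

    subject_ids: list[str]
    shapes: np.ndarray  # (N, M, 3)
    template_faces: np.ndarray
    aligned: bool = False

    def __post_init__(self):
        self.shapes = np.asarray(self.shapes, float)
        if self.shapes.ndim != 3 or self.shapes.shape[2] != 3:
            raise ValueError("shapes must be (N, M, 3)")
        if len(self.subject_ids) != self.shapes.shape[0]:
            raise ValueError("subject_ids length != number of shapes")

    @property
    def n_subjects(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.shapes.shape[1]

    def vectorized(self) -> np.ndarray:
        """(N, 3M) row-per-subject flattening (x1 y1 z1 x2 y2 z2 ...)."""
        return self.shapes.reshape(self.n_subjects, -1)

    def template_mesh(self, vertices: np.ndarray | None = None) -> TriangleMesh:
        v = self.shapes.mean(axis=0) if vertices is None else vertices
        return build_mesh(v, self.template_faces)

    def subject_mesh(self, i: int) -> TriangleMesh:
        return build_mesh(self.shapes[i], self.template_faces)


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _orthogonal_procrustes_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||x R - target||_F (no scaling/reflection)."""
    u, _, vt = np.linalg.svd(x.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def generalized_procrustes(
    cohort: ShapeCohort, tol: float = 1e-9, max_iter: int = 100
) -> tuple[ShapeCohort, np.ndarray]:
    """Remove translation and rotation (not scale) by iterative alignment.

    Each shape is centred at the origin and rotated (proper rotations only)
    to the running mean shape; the mean is recomputed until its Frobenius
    change falls below ``tol``. Returns the aligned cohort and the mean shape.
    """
    if cohort.n_subjects < 2:
        raise ValueError("generalized Procrustes needs at least 2 subjects")
    shapes = cohort.shapes - cohort.shapes.mean(axis=1, keepdims=True)
    mean = shapes[0].copy()
    converged = False
    for _ in range(max_iter):
        for i in range(shapes.shape[0]):
            r = _orthogonal_procrustes_rotation(shapes[i], mean)
            shapes[i] = shapes[i] @ r
        new_mean = shapes.mean(axis=0)
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            converged = True
            break
        mean = new_mean
    if not converged:
        warnings.warn(f"generalized Procrustes did not converge in {max_iter} iterations")
    aligned = ShapeCohort(list(cohort.subject_ids), shapes, cohort.template_faces, aligned=True)
    return aligned, mean


# ---------------------------------------------------------------------------
# Geometric phenotypes
# ---------------------------------------------------------------------------

def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) by the signed-tetrahedron sum.

    Positive for outward-oriented closed meshes; raises on open meshes.
    """
    if not mesh.is_closed():
        raise MeshStructureError("mesh_volume requires a closed mesh")
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def surface_area(mesh: TriangleMesh) -> float:
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())


def sphericity(mesh: TriangleMesh) -> float:
    """Isoperimetric sphericity Psi = pi^(1/3) (6V)^(2/3) / A, in (0, 1].

    Equals 1 for a sphere; decreases for elongated or irregular shapes.
    """
    vol = mesh_volume(mesh)
    if vol <= 0:
        raise MeshStructureError("sphericity requires positive enclosed volume")
    area = surface_area(mesh)
    return float(np.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / area)


def handcrafted_phenotypes(cohort: ShapeCohort) -> "np.ndarray":
    """Per-subject (volume mm^3, sphericity) for a registered cohort.

    These mirror classical end-diastolic volume and sphericity indices
    computed directly from the surface mesh. Returns an (N, 2) array.
    """
    out = np.empty((cohort.n_subjects, 2))
    for i in range(cohort.n_subjects):
        m = cohort.subject_mesh(i)
        out[i, 0] = mesh_volume(m)
        out[i, 1] = sphericity(m)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

ARCHIVE_VERSION = 1


def read_mesh(path) -> TriangleMesh:
    """Read a PLY/OBJ mesh file (format inferred from the extension)."""
    tm = trimesh.load_mesh(str(path), process=False)
    return build_mesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write PLY (ascii or binary chosen by trimesh) or OBJ by extension."""
    mesh.as_trimesh().export(str(path))


def save_cohort(cohort: ShapeCohort, path) -> None:
    """Write the cohort archive: a versioned .npz with ids, coords, faces."""
    np.savez_compressed(
        str(path),
        version=np.int64(ARCHIVE_VERSION),
        subject_ids=np.asarray(cohort.subject_ids, dtype="U"),
        shapes=cohort.shapes.astype(np.float64),
        faces=cohort.template_faces.astype(np.int64),
        aligned=np.bool_(cohort.aligned),
    )


def load_cohort(path) -> ShapeCohort:
    with np.load(str(path), allow_pickle=False) as z:
        if int(z["version"]) != ARCHIVE_VERSION:
            raise ValueError(f"unsupported cohort archive version {int(z['version'])}")
        return ShapeCohort(
            [str(s) for s in z["subject_ids"]],
            z["shapes"],
            z["faces"],
            aligned=bool(z["aligned"]),
        )
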