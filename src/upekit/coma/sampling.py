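"""Mesh down/upsampling operators via quadric-error-metric decimation.

Pooling in the mesh autoencoder removes vertices by iteratively collapsing
the edge with the smallest quadric error (Garland-Heckbert quadrics), in the
*half-edge* variant: a collapse moves one endpoint onto the other, so every
surviving vertex keeps its original template coordinates. The down-map is
then a binary selection matrix; the up-map stores, for each removed vertex,
the barycentric coordinates of its projection onto the nearest triangle of
the decimated mesh. Operators are built once from a single template shape
(the cohort mean) and shared by all subjects.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ..mesh_core import TriangleMesh, build_mesh


# ---------------------------------------------------------------------------
# Quadric-error half-edge collapse
# ---------------------------------------------------------------------------

def _vertex_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Sum of fundamental error quadrics of incident face planes, per vertex."""
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    n = np.cross(b - a, c - a)
    norm = np.linalg.norm(n, axis=1)
    norm[norm == 0] = 1.0
    n = n / norm[:, None]
    d = -np.einsum("ij,ij->i", n, a)
    p = np.column_stack([n, d])                       # (F, 4) plane coefficients
    kp = np.einsum("fi,fj->fij", p, p)                # (F, 4, 4)
    q = np.zeros((vertices.shape[0], 4, 4))
    for col in range(3):
        np.add.at(q, faces[:, col], kp)
    return q


def _collapse_cost(q_sum: np.ndarray, target: np.ndarray) -> float:
    h = np.append(target, 1.0)
    return float(h @ q_sum @ h)


def qem_decimate(mesh: TriangleMesh, target_vertices: int) -> tuple[np.ndarray, TriangleMesh]:
    """Decimate to ``target_vertices`` by half-edge collapses.

    Returns ``(kept_indices, coarse_mesh)`` where ``kept_indices`` are indices
    into the input mesh (sorted ascending) and the coarse mesh reuses their
    exact coordinates.
    """
    m = mesh.n_vertices
    if target_vertices < 4:
        raise ValueError("cannot decimate below 4 vertices")
    if target_vertices >= m:
        keep = np.arange(m)
        return keep, mesh

    verts = mesh.vertices
    quadrics = _vertex_quadrics(verts, mesh.faces)
    neighbors: list[set[int]] = [set() for _ in range(m)]
    coo = sp.triu(mesh.adjacency, k=1).tocoo()
    for u, v in zip(coo.row, coo.col):
        neighbors[u].add(int(v))
        neighbors[v].add(int(u))
    alive = np.ones(m, dtype=bool)
    parent = np.arange(m)                 # collapse target of each removed vertex
    stamp = np.zeros(m, dtype=np.int64)   # invalidates stale heap entries

    heap: list[tuple[float, int, int, int, int]] = []

    def push_pair(u: int, v: int) -> None:
        qs = quadrics[u] + quadrics[v]
        heapq.heappush(heap, (_collapse_cost(qs, verts[v]), u, v, int(stamp[u]), int(stamp[v])))
        heapq.heappush(heap, (_collapse_cost(qs, verts[u]), v, u, int(stamp[v]), int(stamp[u])))

    for u in range(m):
        for v in neighbors[u]:
            if u < v:
                push_pair(u, v)

    n_alive = m
    while n_alive > target_vertices and heap:
        cost, u, v, su, sv = heapq.heappop(heap)
        if not (alive[u] and alive[v]) or stamp[u] != su or stamp[v] != sv:
            continue
        if v not in neighbors[u]:
            continue
        # collapse u -> v: u disappears, its neighbors reconnect to v
        quadrics[v] = quadrics[v] + quadrics[u]
        alive[u] = False
        parent[u] = v
        n_alive -= 1
        for w in list(neighbors[u]):
            neighbors[w].discard(u)
            if w != v:
                neighbors[w].add(v)
                neighbors[v].add(w)
        neighbors[u].clear()
        stamp[v] += 1
        for w in neighbors[v]:
            stamp[w] += 1
        for w in neighbors[v]:
            push_pair(v, w)

    keep = np.flatnonzero(alive)
    return keep, _rebuild_coarse(mesh, keep, parent)


def _resolve_parents(parent: np.ndarray) -> np.ndarray:
    mapping = parent.copy()
    while True:
        nxt = mapping[mapping]
        if np.array_equal(nxt, mapping):
            return mapping
        mapping = nxt


def _rebuild_coarse(mesh: TriangleMesh, keep: np.ndarray, parent: np.ndarray) -> TriangleMesh:
    """Rebuild faces on survivors by routing each removed vertex to the
    survivor it was (transitively) collapsed into, then dropping degenerate
    and duplicated faces."""
    m = mesh.n_vertices
    mapping = _resolve_parents(parent)
    faces = mapping[mesh.faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[ok]
    # drop duplicate faces irrespective of winding
    key = np.sort(faces, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    faces = faces[np.sort(first)]
    reindex = -np.ones(m, dtype=np.int64)
    reindex[keep] = np.arange(keep.size)
    faces = reindex[faces]
    coarse_verts = mesh.vertices[keep]
    # guard: at very coarse levels a survivor can lose all incident faces;
    # reconnect it to its two nearest survivors so the graph stays connected
    used = np.zeros(keep.size, dtype=bool)
    if faces.size:
        used[np.unique(faces)] = True
    for u in np.flatnonzero(~used):
        d = np.linalg.norm(coarse_verts - coarse_verts[u], axis=1)
        d[u] = np.inf
        a, b = np.argsort(d)[:2]
        faces = np.vstack([faces, [u, int(a), int(b)]])
    return build_mesh(coarse_verts, faces, repair_winding=False)


# ---------------------------------------------------------------------------
# Barycentric up-map
# ---------------------------------------------------------------------------

def _point_triangle_barycentric(p: np.ndarray, tri: np.ndarray) -> tuple[float, np.ndarray]:
    """Closest point of triangle ``tri`` (3,3) to ``p``; returns (dist2, bary)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(ap @ ap), np.array([1.0, 0.0, 0.0])
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(bp @ bp), np.array([0.0, 1.0, 0.0])
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        t = d1 / (d1 - d3) if d1 != d3 else 0.0
        q = a + t * ab
        return float((p - q) @ (p - q)), np.array([1 - t, t, 0.0])
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(cp @ cp), np.array([0.0, 0.0, 1.0])
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        t = d2 / (d2 - d6) if d2 != d6 else 0.0
        q = a + t * ac
        return float((p - q) @ (p - q)), np.array([1 - t, 0.0, t])
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        q = b + t * (c - b)
        return float((p - q) @ (p - q)), np.array([0.0, 1 - t, t])
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    q = a + v * ab + w * ac
    return float((p - q) @ (p - q)), np.array([1 - v - w, v, w])


def barycentric_up_map(
    fine_vertices: np.ndarray, keep: np.ndarray, coarse: TriangleMesh
) -> sp.csr_matrix:
    """(M_fine, M_coarse) matrix: indicators for kept vertices, barycentric
    weights of the nearest coarse triangle for removed vertices."""
    m_fine = fine_vertices.shape[0]
    m_coarse = coarse.n_vertices
    reindex = -np.ones(m_fine, dtype=np.int64)
    reindex[keep] = np.arange(keep.size)
    rows, cols, data = [], [], []
    kept_mask = np.zeros(m_fine, dtype=bool)
    kept_mask[keep] = True
    tri_coords = coarse.vertices[coarse.faces]  # (F, 3, 3)
    # max triangle diameter bounds how much the point-triangle distance can
    # undercut the nearest-vertex distance, making the pruned scan exact
    edges = np.stack(
        [
            tri_coords[:, 0] - tri_coords[:, 1],
            tri_coords[:, 1] - tri_coords[:, 2],
            tri_coords[:, 2] - tri_coords[:, 0],
        ]
    )
    max_diam = float(np.linalg.norm(edges, axis=2).max())
    for j in range(m_fine):
        if kept_mask[j]:
            rows.append(j)
            cols.append(int(reindex[j]))
            data.append(1.0)
            continue
        p = fine_vertices[j]
        best = (np.inf, None, None)
        d2v = np.min(np.sum((tri_coords - p) ** 2, axis=2), axis=1)
        order = np.argsort(d2v)
        for f in order:
            if best[0] < np.inf and np.sqrt(d2v[f]) - max_diam > np.sqrt(best[0]):
                break
            dist2, bary = _point_triangle_barycentric(p, tri_coords[f])
            if dist2 < best[0]:
                best = (dist2, f, bary)
        f, bary = best[1], best[2]
        for corner in range(3):
            if bary[corner] != 0.0:
                rows.append(j)
                cols.append(int(coarse.faces[f, corner]))
                data.append(float(bary[corner]))
    return sp.csr_matrix((data, (rows, cols)), shape=(m_fine, m_coarse))


# ---------------------------------------------------------------------------
# Operator stack
# ---------------------------------------------------------------------------

@dataclass
class SamplingOperators:
    level_meshes: list[TriangleMesh] = field(default_factory=list)  # finest first
    down_maps: list[sp.csr_matrix] = field(default_factory=list)    # (M_{l+1}, M_l)
    up_maps: list[sp.csr_matrix] = field(default_factory=list)      # (M_l, M_{l+1})

    @property
    def n_levels(self) -> int:
        return len(self.down_maps)

    def vertex_counts(self) -> list[int]:
        return [m.n_vertices for m in self.level_meshes]


def build_sampling_operators(template: TriangleMesh, factors: list[int]) -> SamplingOperators:
    """Decimation hierarchy with per-level vertex count ceil(M_prev/factor)."""
    ops = SamplingOperators(level_meshes=[template])
    current = template
    for f in factors:
        if f < 1:
            raise ValueError("downsampling factor must be >= 1")
        target = int(np.ceil(current.n_vertices / f))
        if target < 4:
            raise ValueError(
                f"decimation to {target} vertices below the 4-vertex minimum"
            )
        if f == 1:
            m = current.n_vertices
            eye = sp.identity(m, format="csr")
            ops.down_maps.append(eye)
            ops.up_maps.append(eye.copy())
            ops.level_meshes.append(current)
            continue
        keep, coarse = qem_decimate(current, target)
        m = current.n_vertices
        down = sp.csr_matrix(
            (np.ones(keep.size), (np.arange(keep.size), keep)), shape=(keep.size, m)
        )
        up = barycentric_up_map(current.vertices, keep, coarse)
        ops.down_maps.append(down)
        ops.up_maps.append(up)
        ops.level_meshes.append(coarse)
        current = coarse
    return ops
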