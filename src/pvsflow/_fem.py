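"""Internal P1 finite elements on polygonal cross sections.

Meshing: the polygon boundary is resampled to roughly the target edge
length, interior nodes are laid on a hexagonal lattice clipped a safe
distance away from the boundary, the combined point set is Delaunay
triangulated, and triangles whose centroid falls outside the polygon are
discarded (this also carves out concave regions of the bi-lobed shapes).
Linear (P1) elements then solve the Dirichlet Poisson problem.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve
from scipy.spatial import Delaunay
from shapely.geometry import Polygon as _ShapelyPolygon


class MeshingError(RuntimeError):
    """Raised when a usable triangulation could not be built."""


def resample_boundary(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon boundary at n equal arc-length points."""
    v = np.asarray(vertices, dtype=float)
    closed = np.vstack([v, v[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    return np.column_stack([x, y])


def triangulate_polygon(vertices: np.ndarray, target_h: float):
    """Mesh the interior of a simple polygon.

    Returns (points, triangles, n_boundary): the first ``n_boundary`` points
    lie on the boundary (Dirichlet nodes).
    """
    poly = _ShapelyPolygon(vertices)
    if not poly.is_valid or poly.area <= 0:
        raise MeshingError("invalid polygon")
    perim = poly.length
    n_b = max(int(np.ceil(perim / target_h)), 12)
    boundary = resample_boundary(vertices, n_b)

    minx, miny, maxx, maxy = poly.bounds
    dx = target_h
    dy = target_h * np.sqrt(3.0) / 2.0
    ys = np.arange(miny - dy, maxy + 2 * dy, dy)
    rows = []
    for k, yv in enumerate(ys):
        off = 0.5 * dx if k % 2 else 0.0
        xs = np.arange(minx - dx, maxx + 2 * dx, dx) + off
        rows.append(np.column_stack([xs, np.full_like(xs, yv)]))
    lattice = np.vstack(rows)

    # keep lattice nodes safely inside (>= 0.4 h from the wall)
    inner = poly.buffer(-0.4 * target_h)
    if inner.is_empty:
        interior = np.empty((0, 2))
    else:
        mask = shapely.contains_xy(inner, lattice[:, 0], lattice[:, 1])
        interior = lattice[mask]

    pts = np.vstack([boundary, interior])
    tri = Delaunay(pts)
    cent = pts[tri.simplices].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    simplices = tri.simplices[keep]
    if len(simplices) == 0:
        raise MeshingError("no interior triangles; target_h too coarse?")
    # drop slivers with vanishing area
    p0, p1, p2 = (pts[simplices[:, i]] for i in range(3))
    area2 = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - (
        p2[:, 0] - p0[:, 0]
    ) * (p1[:, 1] - p0[:, 1])
    simplices = simplices[np.abs(area2) > 1e-12 * target_h**2]
    return pts, simplices, n_b


def _p1_geometry(pts: np.ndarray, tris: np.ndarray):
    p0, p1, p2 = (pts[tris[:, i]] for i in range(3))
    b_ = np.stack(
        [p1[:, 1] - p2[:, 1], p2[:, 1] - p0[:, 1], p0[:, 1] - p1[:, 1]], axis=1
    )
    c_ = np.stack(
        [p2[:, 0] - p1[:, 0], p0[:, 0] - p2[:, 0], p1[:, 0] - p0[:, 0]], axis=1
    )
    area = 0.5 * (
        (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1])
        - (p2[:, 0] - p0[:, 0]) * (p1[:, 1] - p0[:, 1])
    )
    return b_, c_, np.abs(area)


def poisson_flow(pts: np.ndarray, tris: np.ndarray, n_boundary: int, mu: float):
    """Solve µ ∇²w = dp/dz (unit negative gradient) with w = 0 on boundary.

    Returns (w, Q) with w the nodal axial velocity for dp/dz = -1 and
    Q = ∫ w dA its flux, so the resistance per unit length is 1/Q.
    """
    n = len(pts)
    b_, c_, area = _p1_geometry(pts, tris)
    # element stiffness K_ij = (b_i b_j + c_i c_j) / (4 area)
    Ke = (
        b_[:, :, None] * b_[:, None, :] + c_[:, :, None] * c_[:, None, :]
    ) / (4.0 * area[:, None, None])
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    K = coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    # load vector for unit source: ∫ φ_i dA = area/3 per vertex
    f = np.zeros(n)
    np.add.at(f, tris.ravel(), np.repeat(area / 3.0, 3))

    free = np.arange(n_boundary, n)
    w = np.zeros(n)
    # µ ∇²w = -1  =>  K w = f / µ on free nodes
    w[free] = spsolve(K[free][:, free], f[free] / mu)
    Q = float(f @ w)
    return w, Q
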