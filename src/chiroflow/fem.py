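"""Minimal P2/P1 triangular finite-element kernel for axisymmetric problems.

Implements exactly what the meridional solvers need: quadratic (P2) scalar
fields with linear (P1) pressure on a conforming triangulation, rho-weighted
bilinear forms (the standard axisymmetric weighting that regularises the
1/rho and 1/rho**2 terms), boundary edge integrals for penalty conditions,
and point evaluation via a trapezoid-map triangle locator.

Local P2 numbering: nodes 0-2 are the triangle vertices, node 3+k is the
midpoint of local edge k with edges (0,1), (1,2), (2,0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["FeSpace", "build_space", "TRI_QUAD_D5", "TRI_QUAD_D9"]


def _tri_rule_d5():
    """Classic 7-point degree-5 symmetric rule (exact closed-form constants).

    Weights are normalised so that ``sum(w) = 1/2``: integrals over a
    physical triangle are ``sum_q w_q f_q * det`` with ``det`` twice the
    triangle area (the Jacobian of the affine reference map).
    """
    s15 = np.sqrt(15.0)
    a1, w1 = (9.0 - 2.0 * s15) / 21.0, (155.0 + s15) / 1200.0
    a2, w2 = (9.0 + 2.0 * s15) / 21.0, (155.0 - s15) / 1200.0
    pts = [(1 / 3, 1 / 3, 1 / 3)]
    wts = [9.0 / 40.0]
    for a, w in ((a1, w1), (a2, w2)):
        b = (1.0 - a) / 2.0
        pts += [(a, b, b), (b, a, b), (b, b, a)]
        wts += [w, w, w]
    return np.array(pts), 0.5 * np.array(wts)


def _tri_rule_collapsed(n: int = 5):
    """Collapsed Gauss-Jacobi product rule on the triangle, degree ``2n - 1``.

    Built from the Duffy map of the unit square: exact node/weight
    construction (no tabulated constants), n**2 points, all weights
    positive.  Same normalisation as :func:`_tri_rule_d5`.
    """
    from scipy.special import roots_jacobi

    xj, wj = roots_jacobi(n, 1.0, 0.0)        # weight (1-x) on [-1, 1]
    u = 0.5 * (xj + 1.0)
    wu = wj / 4.0                              # int_0^1 (1-u) f du
    xl, wl = np.polynomial.legendre.leggauss(n)
    v = 0.5 * (xl + 1.0)
    wv = wl / 2.0                              # int_0^1 f dv
    uu, vv = np.meshgrid(u, v, indexing="ij")
    l2 = uu.ravel()
    l3 = (vv * (1.0 - uu)).ravel()
    pts = np.column_stack([1.0 - l2 - l3, l2, l3])
    wts = np.outer(wu, wv).ravel()             # sums to 1/2 = reference area
    return pts, wts


TRI_QUAD_D5 = _tri_rule_d5()
TRI_QUAD_D9 = _tri_rule_collapsed(5)


def _p2_basis(bary: np.ndarray):
    """P2 basis values and barycentric gradients at barycentric points.

    Returns ``N`` with shape (nq, 6) and ``dNdL`` with shape (nq, 6, 3).
    """
    L = bary
    nq = L.shape[0]
    N = np.empty((nq, 6))
    dNdL = np.zeros((nq, 6, 3))
    for i in range(3):
        N[:, i] = L[:, i] * (2.0 * L[:, i] - 1.0)
        dNdL[:, i, i] = 4.0 * L[:, i] - 1.0
    edges = ((0, 1), (1, 2), (2, 0))
    for k, (i, j) in enumerate(edges):
        N[:, 3 + k] = 4.0 * L[:, i] * L[:, j]
        dNdL[:, 3 + k, i] = 4.0 * L[:, j]
        dNdL[:, 3 + k, j] = 4.0 * L[:, i]
    return N, dNdL


def _p1_basis(bary: np.ndarray):
    return bary.copy()  # (nq, 3)


@dataclass
class FeSpace:
    """P2 velocity / P1 pressure space on a fixed triangulation."""

    points: np.ndarray           # (nv, 2) vertex coordinates
    triangles: np.ndarray        # (nt, 3)
    p2_points: np.ndarray        # (n2, 2) vertex + edge-midpoint coordinates
    tri_dofs: np.ndarray         # (nt, 6) P2 dof indices per triangle
    edge_midpoint: dict          # frozenset vertex pair -> midpoint dof index
    boundary: dict               # tag -> (n_edges, 2) vertex pairs
    quad: tuple = field(default=None, repr=False)
    _finder: object = field(default=None, repr=False)

    @property
    def n_p1(self) -> int:
        return self.points.shape[0]

    @property
    def n_p2(self) -> int:
        return self.p2_points.shape[0]

    # -- geometric factors -------------------------------------------------
    def _geom(self):
        p, t = self.points, self.triangles
        v0, v1, v2 = p[t[:, 0]], p[t[:, 1]], p[t[:, 2]]
        d1, d2 = v1 - v0, v2 - v0
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]   # 2*area, >0 (CCW)
        # gradients of barycentric coordinates (nt, 3, 2)
        gradL = np.empty((t.shape[0], 3, 2))
        gradL[:, 1, 0] = d2[:, 1]
        gradL[:, 1, 1] = -d2[:, 0]
        gradL[:, 2, 0] = -d1[:, 1]
        gradL[:, 2, 1] = d1[:, 0]
        gradL[:, 1:] /= det[:, None, None]
        gradL[:, 0] = -gradL[:, 1] - gradL[:, 2]
        return det, gradL

    def quad_points(self):
        """Physical coordinates of quadrature points, shape (nt, nq, 2)."""
        bary, _ = self.quad
        p, t = self.points, self.triangles
        verts = p[t]                                      # (nt, 3, 2)
        return np.einsum("qi,tid->tqd", bary, verts)

    # -- assembly ----------------------------------------------------------
    def _p2_eval_data(self):
        bary, w = self.quad
        N, dNdL = _p2_basis(bary)
        det, gradL = self._geom()
        # physical gradients: (nt, nq, 6, 2)
        dN = np.einsum("qik,tkd->tqid", dNdL, gradL)
        return N, dN, det, w

    def assemble_p2_bilinear(self, c_grad=None, c_mass=None) -> sp.csr_matrix:
        """Assemble ``int c_grad grad(u).grad(v) + c_mass u v`` on P2.

        ``c_grad`` and ``c_mass`` are arrays of shape (nt, nq) evaluated at
        the quadrature points (use :meth:`quad_points`), or None to skip.
        """
        N, dN, det, w = self._p2_eval_data()
        nt = det.shape[0]
        ke = np.zeros((nt, 6, 6))
        if c_grad is not None:
            ke += np.einsum("q,tq,tqid,tqjd->tij", w, c_grad, dN, dN)
        if c_mass is not None:
            ke += np.einsum("q,tq,qi,qj->tij", w, c_mass, N, N)
        ke *= det[:, None, None]
        d = self.tri_dofs
        rows = np.repeat(d, 6, axis=1).ravel()
        cols = np.tile(d, (1, 6)).ravel()
        return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(self.n_p2, self.n_p2)).tocsr()

    def assemble_p2_load(self, values) -> np.ndarray:
        """Assemble ``int values * phi_i`` for P2 basis; values shape (nt, nq)."""
        N, dN, det, w = self._p2_eval_data()
        fe = np.einsum("q,tq,qi->ti", w, values, N) * det[:, None]
        out = np.zeros(self.n_p2)
        np.add.at(out, self.tri_dofs, fe)
        return out

    def assemble_divergence(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        """P1-tested cylindrical divergence operators.

        ``B_rho[q, i] = int psi_q (phi_i + rho d_rho phi_i)`` and
        ``B_z[q, i] = int psi_q rho d_z phi_i`` so that
        ``B_rho v_rho + B_z v_z`` is the rho-weighted weak divergence.
        """
        bary, w = self.quad
        N, dN, det, _ = self._p2_eval_data()
        P1 = _p1_basis(bary)
        xq = self.quad_points()
        rho = xq[:, :, 0]
        nt = det.shape[0]
        be_r = np.einsum("q,qa,tqi->tai", w, P1, np.broadcast_to(N, dN.shape[:3]) + rho[:, :, None] * dN[:, :, :, 0])
        be_z = np.einsum("q,qa,tqi->tai", w, P1, rho[:, :, None] * dN[:, :, :, 1])
        be_r *= det[:, None, None]
        be_z *= det[:, None, None]
        t = self.triangles
        d = self.tri_dofs
        rows = np.repeat(t, 6, axis=1).ravel()
        cols = np.tile(d, (1, 3)).ravel()
        shape = (self.n_p1, self.n_p2)
        b_r = sp.coo_matrix((be_r.ravel(), (rows, cols)), shape=shape).tocsr()
        b_z = sp.coo_matrix((be_z.ravel(), (rows, cols)), shape=shape).tocsr()
        return b_r, b_z

    def assemble_p1_load(self, values) -> np.ndarray:
        """``int values * psi_q`` for P1 basis; values shape (nt, nq)."""
        bary, w = self.quad
        det, _ = self._geom()
        P1 = _p1_basis(bary)
        fe = np.einsum("q,tq,qa->ta", w, values, P1) * det[:, None]
        out = np.zeros(self.n_p1)
        np.add.at(out, self.triangles, fe)
        return out

    # -- boundary ----------------------------------------------------------
    def boundary_edge_data(self, tag: str):
        """Per-edge (dofs, endpoint coords, outward unit normal, length).

        ``dofs`` is (n_edges, 3): the two endpoint P2 dofs and the midpoint
        dof.  Normals point away from the adjacent triangle's centroid.
        """
        edges = self.boundary[tag]
        p = self.points
        # adjacency: map edge -> adjacent triangle centroid
        key = {}
        for ti, tri in enumerate(self.triangles):
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key[frozenset((int(a), int(b)))] = ti
        dofs = np.empty((len(edges), 3), dtype=np.int64)
        normals = np.empty((len(edges), 2))
        lengths = np.empty(len(edges))
        for k, (a, b) in enumerate(edges):
            fs = frozenset((int(a), int(b)))
            dofs[k] = (a, b, self.edge_midpoint[fs])
            tvec = p[b] - p[a]
            ln = np.hypot(*tvec)
            n = np.array([tvec[1], -tvec[0]]) / ln
            centroid = p[self.triangles[key[fs]]].mean(axis=0)
            mid = 0.5 * (p[a] + p[b])
            if np.dot(n, mid - centroid) < 0:
                n = -n
            normals[k] = n
            lengths[k] = ln
        return dofs, p[edges[:, 0]], p[edges[:, 1]], normals, lengths

    def assemble_boundary_vv(self, tag: str, weight_rho: bool = True):
        """Edge-mass matrices for penalty terms on a tagged boundary.

        Returns ``(M_edge, normals_per_dof_row)`` where ``M_edge`` is a list
        of per-edge 3x3 matrices ``int w phi_i phi_j ds`` (w = rho by
        default) together with edge dof triplets and unit normals.
        """
        dofs, pa, pb, normals, lengths = self.boundary_edge_data(tag)
        # 1D quadratic basis at Gauss points on [0,1]
        gq, gw = np.polynomial.legendre.leggauss(4)
        s = 0.5 * (gq + 1.0)
        gw = 0.5 * gw
        phi = np.stack([(1 - s) * (1 - 2 * s), s * (2 * s - 1), 4 * s * (1 - s)], axis=1)  # (nq,3)
        xq = pa[:, None, :] * (1 - s)[None, :, None] + pb[:, None, :] * s[None, :, None]
        w = xq[:, :, 0] if weight_rho else np.ones(xq.shape[:2])
        me = np.einsum("q,eq,qi,qj->eij", gw, w, phi, phi) * lengths[:, None, None]
        return dofs, normals, me

    def dof_values_on_quad(self, values_at_dofs: np.ndarray):
        """Interpolate a P2 coefficient vector to quadrature points (nt, nq)."""
        bary, _ = self.quad
        N, _ = _p2_basis(bary)
        return np.einsum("qi,ti->tq", N, values_at_dofs[self.tri_dofs])

    # -- point evaluation --------------------------------------------------
    def _get_finder(self):
        if self._finder is None:
            import matplotlib.tri as mtri

            tri = mtri.Triangulation(self.points[:, 0], self.points[:, 1], self.triangles)
            self._finder = (tri, tri.get_trifinder())
        return self._finder

    def locate(self, x: np.ndarray, y: np.ndarray):
        _, finder = self._get_finder()
        return finder(np.asarray(x, float), np.asarray(y, float))

    def evaluate_p2(self, coeffs: np.ndarray, x, y, fill=np.nan):
        """Point-evaluate a P2 field; points outside the mesh give ``fill``."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        tri_idx = self.locate(x, y)
        out = np.full(x.shape, fill, dtype=float)
        ok = tri_idx >= 0
        if not np.any(ok):
            return out
        ti = tri_idx[ok]
        verts = self.points[self.triangles[ti]]          # (m, 3, 2)
        d1 = verts[:, 1] - verts[:, 0]
        d2 = verts[:, 2] - verts[:, 0]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        rx = x[ok] - verts[:, 0, 0]
        ry = y[ok] - verts[:, 0, 1]
        l2 = (rx * d2[:, 1] - ry * d2[:, 0]) / det
        l3 = (ry * d1[:, 0] - rx * d1[:, 1]) / det
        bary = np.stack([1.0 - l2 - l3, l2, l3], axis=1)
        N, _ = _p2_basis(bary)
        out[ok] = np.einsum("mi,mi->m", N, coeffs[self.tri_dofs[ti]])
        return out


def build_space(mesh, quad=None) -> FeSpace:
    """Construct the P2/P1 space (edge midpoints, dof maps) from a mesh."""
    if quad is None:
        quad = TRI_QUAD_D9
    points = mesh.points
    triangles = mesh.triangles
    nv = points.shape[0]
    edge_midpoint = {}
    midcoords = []
    tri_dofs = np.empty((triangles.shape[0], 6), dtype=np.int64)
    tri_dofs[:, :3] = triangles
    nxt = nv
    for ti, tri in enumerate(triangles):
        for k, (a, b) in enumerate(((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0]))):
            fs = frozenset((int(a), int(b)))
            idx = edge_midpoint.get(fs)
            if idx is None:
                idx = nxt
                edge_midpoint[fs] = idx
                midcoords.append(0.5 * (points[a] + points[b]))
                nxt += 1
            tri_dofs[ti, 3 + k] = idx
    p2_points = np.vstack([points, np.array(midcoords)])
    return FeSpace(
        points=points,
        triangles=triangles,
        p2_points=p2_points,
        tri_dofs=tri_dofs,
        edge_midpoint=edge_midpoint,
        boundary=mesh.boundary,
        quad=quad,
    )


def tagged_p2_dofs(space: FeSpace, tags) -> np.ndarray:
    """All P2 dofs (vertices + midpoints) lying on the given boundary tags."""
    out = set()
    for tag in tags:
        for a, b in space.boundary[tag]:
            fs = frozenset((int(a), int(b)))
            out.update((int(a), int(b), space.edge_midpoint[fs]))
    return np.array(sorted(out), dtype=np.int64)


def solve_constrained(A: sp.spmatrix, rhs: np.ndarray, fixed: np.ndarray,
                      fixed_vals: np.ndarray | None = None) -> np.ndarray:
    """Direct solve of ``A u = rhs`` with prescribed values on ``fixed`` dofs."""
    n = A.shape[0]
    u = np.zeros(n)
    if fixed_vals is not None:
        u[fixed] = fixed_vals
    free = np.setdiff1d(np.arange(n), fixed)
    A = A.tocsr()
    rhs_f = rhs[free] - A[free][:, fixed] @ u[fixed]
    from scipy.sparse.linalg import spsolve

    u[free] = spsolve(A[free][:, free].tocsc(), rhs_f)
    return u
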