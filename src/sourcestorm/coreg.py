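"""Subject coordinate system and MEG/EEG-to-anatomy registration.

The subject coordinate system (SCS) is built from the three anatomical
fiducials: origin at the midpoint of the two preauricular points, +X through
the nasion within the plane they define, +Y toward the LPA, +Z up
(right-handed).  Device-to-anatomy registration first pair-matches the
fiducial triplets with a rigid Procrustes fit and can then be refined with
an iterated-closest-point (ICP) match of digitized head points onto the
scalp surface.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core_io import (EpochSet, Fiducials, Recording, SensorArray, SurfaceMesh,
                      Transform)

__all__ = ["Fiducials", "scs_from_fiducials", "align_fiducials", "icp_refine",
           "apply_transform", "rigid_fit"]


def scs_from_fiducials(fid: Fiducials) -> Transform:
    """Transform mapping the fiducials' source frame into the SCS."""
    origin = 0.5 * (fid.lpa + fid.rpa)
    x = fid.nasion - origin
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("nasion coincides with the ear midpoint")
    x = x / nx
    y = fid.lpa - origin
    y = y - (y @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("collinear fiducials")
    y = y / ny
    z = np.cross(x, y)
    R = np.stack([x, y, z])  # rows: SCS axes expressed in the source frame
    return Transform.from_rotation_translation(R, -R @ origin)


def rigid_fit(source: np.ndarray, target: np.ndarray,
              weights: np.ndarray | None = None) -> Transform:
    """Least-squares rigid transform mapping ``source`` points onto ``target``.

    Kabsch/SVD solution of the orthogonal Procrustes problem without scaling;
    reflections are excluded by sign-correcting the smallest singular vector.
    """
    P = np.asarray(source, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("source/target must be matching (n, 3) arrays")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu_p = w @ P
    mu_q = w @ Q
    H = (P - mu_p).T @ ((Q - mu_q) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return Transform.from_rotation_translation(R, mu_q - R @ mu_p)


def align_fiducials(fid_device: Fiducials, fid_anatomy: Fiducials) -> Transform:
    """Rigid transform taking device-frame fiducials onto anatomy-frame ones."""
    return rigid_fit(fid_device.as_array(), fid_anatomy.as_array())


def _closest_on_triangles(p, a, b, c):
    """Closest point on each triangle (a, b, c) to each point p; all (m, 3).

    Vectorized barycentric region walk (the standard point-triangle
    projection from computational geometry).
    """
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.clip(d1 / (d1 - d3), 0, 1)
        t_ac = np.clip(d2 / (d2 - d6), 0, 1)
        t_bc = np.clip((d4 - d3) / ((d4 - d3) + (d5 - d6)), 0, 1)
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom

    out = a + v[:, None] * ab + w[:, None] * ac          # interior default
    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out[on_bc] = b[on_bc] + t_bc[on_bc, None] * (c - b)[on_bc]
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out[on_ac] = a[on_ac] + t_ac[on_ac, None] * ac[on_ac]
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out[on_ab] = a[on_ab] + t_ab[on_ab, None] * ab[on_ab]
    at_c = (d6 >= 0) & (d5 <= d6)
    out[at_c] = c[at_c]
    at_b = (d3 >= 0) & (d4 <= d3)
    out[at_b] = b[at_b]
    at_a = (d1 <= 0) & (d2 <= 0)
    out[at_a] = a[at_a]
    return out


class _SurfaceLocator:
    """Closest-point-on-surface queries via a KDTree over triangle centroids."""

    def __init__(self, mesh: SurfaceMesh, k: int = 16):
        self.tri = mesh.vertices[mesh.faces]          # (m, 3, 3)
        self.k = min(k, len(self.tri))
        self.tree = cKDTree(self.tri.mean(axis=1))
        fn = np.cross(self.tri[:, 1] - self.tri[:, 0],
                      self.tri[:, 2] - self.tri[:, 0])
        self.face_normals = fn / np.maximum(
            np.linalg.norm(fn, axis=1, keepdims=True), 1e-300)

    def query(self, points: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Returns (closest points, distances, face normals at the matches)."""
        _, cand = self.tree.query(points, k=self.k)
        cand = cand.reshape(len(points), -1)
        n, k = cand.shape
        p = np.repeat(points, k, axis=0)
        t = self.tri[cand.ravel()]
        closest = _closest_on_triangles(p, t[:, 0], t[:, 1], t[:, 2])
        d2 = ((closest - p) ** 2).sum(axis=1).reshape(n, k)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        return (closest.reshape(n, k, 3)[rows, best],
                np.sqrt(d2[rows, best]),
                self.face_normals[cand[rows, best]])


def _point_to_plane_step(moved: np.ndarray, matched: np.ndarray,
                         normals: np.ndarray) -> Transform:
    """Small-angle rigid increment minimizing point-to-plane distances.

    Solves the linearized system ``n_i . (omega x p_i + t) = -n_i . (p_i - m_i)``
    for the rotation vector and translation.
    """
    A = np.hstack([np.cross(moved, normals), normals])
    b = -np.einsum("ij,ij->i", moved - matched, normals)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    omega, t = x[:3], x[3:]
    angle = np.linalg.norm(omega)
    if angle < 1e-15:
        R = np.eye(3)
    else:
        k = omega / angle
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
    return Transform.from_rotation_translation(R, t)


def _reorthonormalized(matrix: np.ndarray) -> Transform:
    """Project the rotation block back onto SO(3) (guards against the float
    drift of repeated matrix products)."""
    m = np.array(matrix, dtype=float)
    U, _, Vt = np.linalg.svd(m[:3, :3])
    m[:3, :3] = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    m[3] = (0.0, 0.0, 0.0, 1.0)
    return Transform(m)


def icp_refine(head_points: np.ndarray, scalp_mesh: SurfaceMesh,
               init: Transform | None = None, tol: float = 1e-7,
               max_iter: int = 100) -> tuple[Transform, float]:
    """Refine a registration by ICP of head points onto the scalp surface.

    Alternates closest-point-on-surface matching (point-to-triangle, so the
    match is not quantized to the mesh vertices) with a rigid update, until
    the RMS point-to-surface distance changes by less than ``tol`` meters or
    ``max_iter`` iterations.  The update is the linearized point-to-plane
    solve, which converges quickly along the shallow rotational valleys of
    head-like surfaces; when it fails to lower the RMS the point-to-point
    Procrustes update is used instead, and only RMS-lowering steps are
    accepted, so the RMS sequence over accepted iterations is non-increasing.

    Returns the refined transform (device -> anatomy, including ``init``)
    and the final RMS distance in meters.
    """
    pts = np.asarray(head_points, dtype=float).reshape(-1, 3)
    if len(pts) < 10:
        raise ValueError(f"ICP needs >= 10 head points, got {len(pts)}")
    T = Transform.identity() if init is None else init
    locator = _SurfaceLocator(scalp_mesh)

    def rms_dist(trans):
        _, dist, _ = locator.query(trans.apply(pts))
        return float(np.sqrt(np.mean(dist ** 2)))

    prev_mean = np.inf
    for _ in range(max_iter):
        moved = T.apply(pts)
        matched, dist, normals = locator.query(moved)
        cur = float(np.sqrt(np.mean(dist ** 2)))
        if prev_mean - cur < tol:
            break
        prev_mean = cur
        # point-to-plane update slides along the surface and converges fast
        # in the shallow rotational valleys of head-like shapes ...
        step = _point_to_plane_step(moved, matched, normals)
        T_try = _reorthonormalized(step.matrix @ T.matrix)
        if rms_dist(T_try) <= cur:
            T = T_try
        else:
            # ... falling back to the point-to-point Procrustes update, which
            # cannot increase the distance to the current matches, keeps the
            # accepted sequence monotone.
            T_pp = rigid_fit(pts, matched)
            if rms_dist(T_pp) <= cur:
                T = T_pp
            else:
                break
    _, dist, _ = locator.query(T.apply(pts))
    return T, float(np.sqrt(np.mean(dist ** 2)))


def apply_transform(obj, T: Transform):
    """Apply a rigid transform to any positioned object.

    Positions are mapped; MEG coil orientations and mesh normals are rotated
    only (norms preserved).
    """
    if isinstance(obj, np.ndarray):
        return T.apply(obj)
    if isinstance(obj, SurfaceMesh):
        out = obj.copy()
        out.vertices = T.apply(out.vertices)
        out.vertex_normals = T.rotate(out.vertex_normals)
        if out.landmarks:
            out.landmarks = {k: T.apply(np.asarray(v)) for k, v in out.landmarks.items()}
        return out
    if isinstance(obj, Fiducials):
        return Fiducials(nasion=T.apply(obj.nasion), lpa=T.apply(obj.lpa),
                         rpa=T.apply(obj.rpa))
    if isinstance(obj, SensorArray):
        channels = []
        for c in obj.channels:
            import dataclasses
            channels.append(dataclasses.replace(
                c, position=T.apply(c.position),
                orientation=None if c.orientation is None else T.rotate(c.orientation)))
        fid = None if obj.fiducials is None else apply_transform(obj.fiducials, T)
        hp = None if obj.head_points is None else T.apply(obj.head_points)
        return SensorArray(channels=channels, fiducials=fid, head_points=hp)
    if isinstance(obj, (Recording, EpochSet)):
        out = obj.copy()
        out.sensors = apply_transform(obj.sensors, T)
        return out
    raise TypeError(f"cannot transform object of type {type(obj)}")
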