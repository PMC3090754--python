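"""Region-of-interest (scout) analysis and cross-subject surface projection.

A scout is a labelled set of source locations on one subject's cortex whose
time series are aggregated into a single trace.  For group analysis, source
maps estimated on individual anatomies are projected onto a common surface:
per hemisphere the meshes are rigidly pre-aligned on their anatomical
landmarks, Laplacian-smoothed to their coarse shape, matched with ICP, and
the source amplitudes are carried over by Shepard (inverse-distance-power)
interpolation.  Shepard weights are convex, so projected values stay within
the input range and constants are preserved exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .coreg import icp_refine, rigid_fit
from .core_io import Fiducials, SurfaceMesh, Transform


@dataclass
class Scout:
    label: str
    vertices: np.ndarray
    seed: int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.int64)
        if self.vertices.size == 0:
            raise ValueError(f"scout {self.label!r} is empty")
        if len(np.unique(self.vertices)) != self.vertices.size:
            raise ValueError(f"scout {self.label!r} has duplicate vertices")
        if self.seed not in self.vertices:
            raise ValueError(f"scout {self.label!r}: seed not among its vertices")


@dataclass
class Atlas:
    name: str
    scouts: list[Scout]

    def __post_init__(self):
        labels = [s.label for s in self.scouts]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate scout labels in atlas")

    def __getitem__(self, label: str) -> Scout:
        for s in self.scouts:
            if s.label == label:
                return s
        raise KeyError(label)


def scout_to_json(atlas: Atlas, path) -> None:
    payload = {"name": atlas.name,
               "scouts": [{"label": s.label, "seed": int(s.seed),
                           "vertices": s.vertices.tolist()} for s in atlas.scouts]}
    Path(path).write_text(json.dumps(payload, indent=1))


def scout_from_json(path) -> Atlas:
    d = json.loads(Path(path).read_text())
    return Atlas(name=d["name"],
                 scouts=[Scout(label=s["label"], vertices=s["vertices"],
                               seed=s["seed"]) for s in d["scouts"]])


# ---------------------------------------------------------------------------
# scout time series
# ---------------------------------------------------------------------------

def scout_timeseries(estimate, scout: Scout, aggregate: str = "mean") -> np.ndarray:
    """Aggregate the scout's source rows into one time series.

    * ``mean``: plain average.
    * ``mean_signflip``: rows whose orientation points against the scout's
      mean orientation are negated first, so anatomically opposite banks of
      a sulcus do not cancel.
    * ``pca``: first principal component, rescaled to carry the scout's mean
      variance and sign-aligned with the mean trace.
    """
    rows = estimate.values[scout.vertices]
    if aggregate == "mean":
        return rows.mean(axis=0)
    if aggregate == "mean_signflip":
        src = estimate.source_space
        if src is None or getattr(src, "orientations", None) is None:
            raise ValueError("sign-flip aggregation needs source orientations")
        ori = src.orientations[scout.vertices]
        # reference axis = principal direction of the orientation cloud; the
        # plain mean cancels for exactly opposite sulcal banks
        _, vecs = np.linalg.eigh(ori.T @ ori)
        ref = vecs[:, -1]
        if ref @ ori.sum(axis=0) < 0:
            ref = -ref
        flips = np.where(ori @ ref < 0, -1.0, 1.0)
        return (rows * flips[:, None]).mean(axis=0)
    if aggregate == "pca":
        centered = rows - rows.mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        pc = Vt[0]
        var_scale = np.sqrt(np.mean(centered.var(axis=1)))
        pc = pc / max(pc.std(), 1e-300) * var_scale
        if pc @ rows.mean(axis=0) < 0:
            pc = -pc
        return pc
    raise ValueError(f"unknown aggregate {aggregate!r}")


# ---------------------------------------------------------------------------
# mesh smoothing
# ---------------------------------------------------------------------------

def _adjacency(mesh: SurfaceMesh) -> sparse.csr_matrix:
    f = mesh.faces
    i = np.concatenate([f[:, 0], f[:, 1], f[:, 1], f[:, 2], f[:, 2], f[:, 0]])
    j = np.concatenate([f[:, 1], f[:, 0], f[:, 2], f[:, 1], f[:, 0], f[:, 2]])
    data = np.ones(i.size)
    A = sparse.coo_matrix((data, (i, j)), shape=(mesh.n_vertices,) * 2).tocsr()
    A.data[:] = 1.0  # collapse duplicate edges
    return A


def _boundary_vertices(mesh: SurfaceMesh) -> np.ndarray:
    """Vertices on an open boundary (edges referenced by exactly one face)."""
    f = mesh.faces
    edges = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]),
                    axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def mesh_smooth(mesh: SurfaceMesh, iterations: int = 50,
                factor: float = 0.5) -> SurfaceMesh:
    """Iterative Laplacian smoothing: vertex += factor * (neighbor mean - vertex).

    Topology is unchanged; repeated application contracts a closed surface
    toward its coarse shape (a sphere shrinks by a few percent at the
    defaults).  Open-boundary and isolated vertices are pinned: letting a
    cut boundary contract would deform the shell and bias any registration
    performed on the smoothed surface.
    """
    if iterations == 0:
        return mesh.copy()
    A = _adjacency(mesh)
    deg = np.asarray(A.sum(axis=1)).ravel()
    pinned = deg == 0
    boundary = _boundary_vertices(mesh)
    pinned[boundary] = True
    deg[deg == 0] = 1.0
    V = mesh.vertices.copy()
    for _ in range(iterations):
        mean = A @ V / deg[:, None]
        mean[pinned] = V[pinned]
        V = V + factor * (mean - V)
    return SurfaceMesh(vertices=V, faces=mesh.faces.copy(), hemi=mesh.hemi,
                       landmarks=mesh.landmarks)


# ---------------------------------------------------------------------------
# Shepard interpolation
# ---------------------------------------------------------------------------

def shepard_interpolate(source_points: np.ndarray, source_values: np.ndarray,
                        query_points: np.ndarray, k: int = 8,
                        power: float = 2.0) -> np.ndarray:
    """Inverse-distance-power weighted mean of the k nearest sources.

    A query within 1e-12 m of a source returns that source's value exactly.
    ``source_values`` may be (n,) or (n, t).  Fewer than k sources triggers a
    warning and uses them all.
    """
    P = np.asarray(source_points, dtype=float).reshape(-1, 3)
    V = np.asarray(source_values, dtype=float)
    Q = np.asarray(query_points, dtype=float).reshape(-1, 3)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(P) < k:
        warnings.warn(f"only {len(P)} sources for k={k}; using all")
        k = len(P)
    tree = cKDTree(P)
    dist, idx = tree.query(Q, k=k)
    dist = np.atleast_2d(dist.reshape(len(Q), k))
    idx = idx.reshape(len(Q), k)
    exact = dist[:, 0] < 1e-12
    w = 1.0 / np.maximum(dist, 1e-12) ** power  # exact rows overridden below
    w /= w.sum(axis=1, keepdims=True)
    vals = V[idx]  # (q, k) or (q, k, t)
    out = np.einsum("qk,qk...->q...", w, vals)
    if exact.any():
        out[exact] = V[idx[exact, 0]]
    return out


# ---------------------------------------------------------------------------
# surface-to-surface projection
# ---------------------------------------------------------------------------

def _landmark_prealign(mesh_a: SurfaceMesh, mesh_b: SurfaceMesh) -> Transform:
    if not (mesh_a.landmarks and mesh_b.landmarks):
        return Transform.identity()
    common = sorted(set(mesh_a.landmarks) & set(mesh_b.landmarks))
    if len(common) < 3:
        return Transform.identity()
    src = np.stack([np.asarray(mesh_a.landmarks[c], dtype=float) for c in common])
    dst = np.stack([np.asarray(mesh_b.landmarks[c], dtype=float) for c in common])
    return rigid_fit(src, dst)


def _project_one(values, mesh_a, mesh_b, smooth_iter, smooth_factor, k, power):
    T0 = _landmark_prealign(mesh_a, mesh_b)
    sm_a = mesh_smooth(mesh_a, smooth_iter, smooth_factor)
    sm_b = mesh_smooth(mesh_b, smooth_iter, smooth_factor)
    # match only face-referenced vertices; isolated ones are off-surface
    used = np.zeros(sm_a.n_vertices, dtype=bool)
    used[sm_a.faces.ravel()] = True
    pts = T0.apply(sm_a.vertices[used])
    if len(pts) >= 10:
        T, _ = icp_refine(pts, sm_b, init=None)
        mapped = T.apply(T0.apply(mesh_a.vertices))
    else:
        mapped = T0.apply(mesh_a.vertices)
    return shepard_interpolate(mapped, values, mesh_b.vertices, k=k, power=power)


def surface_project(values: np.ndarray, src_space_a, src_space_b,
                    smooth_iterations: int = 50, smooth_factor: float = 0.5,
                    k: int = 8, power: float = 2.0) -> np.ndarray:
    """Project per-source values from subject A's surface onto surface B.

    Pipeline, per hemisphere when both source spaces carry hemisphere
    labels: landmark-based rigid pre-alignment, Laplacian smoothing of both
    surfaces, ICP of smoothed A onto smoothed B, then Shepard interpolation
    of the values at B's vertices.  ``values`` is (n_a,) or (n_a, t).
    """
    mesh_a = src_space_a.parent_mesh if hasattr(src_space_a, "parent_mesh") else src_space_a
    mesh_b = src_space_b.parent_mesh if hasattr(src_space_b, "parent_mesh") else src_space_b
    values = np.asarray(values, dtype=float)
    if values.shape[0] != mesh_a.n_vertices:
        raise ValueError("values row count must match surface A vertex count")

    if mesh_a.hemi is None or mesh_b.hemi is None:
        if mesh_a.hemi is None or mesh_b.hemi is None:
            warnings.warn("hemisphere labels missing; projecting as one surface")
        return _project_one(values, mesh_a, mesh_b, smooth_iterations,
                            smooth_factor, k, power)

    out_shape = (mesh_b.n_vertices,) + values.shape[1:]
    out = np.zeros(out_shape)
    for h in np.unique(mesh_b.hemi):
        sel_a = np.flatnonzero(mesh_a.hemi == h)
        sel_b = np.flatnonzero(mesh_b.hemi == h)
        if sel_a.size == 0:
            warnings.warn(f"hemisphere {h!r} missing on source surface")
            continue
        sub_a = _submesh(mesh_a, sel_a)
        sub_b = _submesh(mesh_b, sel_b)
        out[sel_b] = _project_one(values[sel_a], sub_a, sub_b,
                                  smooth_iterations, smooth_factor, k, power)
    return out


def _submesh(mesh: SurfaceMesh, sel: np.ndarray) -> SurfaceMesh:
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[sel] = np.arange(sel.size)
    fm = remap[mesh.faces]
    keep = (fm >= 0).all(axis=1)
    return SurfaceMesh(vertices=mesh.vertices[sel], faces=fm[keep],
                       landmarks=mesh.landmarks)
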