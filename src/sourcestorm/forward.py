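"""Sphere-based forward models and lead-field computation for MEG and EEG.

MEG uses the closed-form external magnetic field of a current dipole in a
spherically symmetric conductor (Sarvas' formula), which depends only on the
sphere center — not on conductivity — so MEG gains are conductivity-free.
A radial dipole produces exactly zero external field in this model.

EEG uses the concentric multilayer sphere: the electric potential is
expanded in Legendre harmonics and the per-degree radial coefficients are
obtained by solving the interface continuity conditions shell by shell.
For fast lead-field assembly the multilayer solution is approximated by
three dipoles in a homogeneous sphere (the Berg approximation), whose
parameters are fitted once per head model against the exact series.

The overlapping-spheres MEG model fits one sphere per sensor to the scalp
patch nearest that sensor, weighted by ``exp(-d / sigma)`` with
``sigma = 0.04 m``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .core_io import SensorArray, SurfaceMesh

MU0_OVER_4PI = 1e-7  # Tesla * meter / Ampere

#: brain / skull / scalp conductivities in S/m
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)
#: shell radii as fractions of the scalp radius (brain, skull, scalp)
DEFAULT_RADIUS_RATIOS = (0.88, 0.93, 1.0)


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class SphereModel:
    """Concentric sphere head model: 1 shell (MEG) or 3 shells (EEG)."""

    center: np.ndarray
    radii: tuple
    conductivities: tuple | None = None

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.radii = tuple(float(r) for r in np.atleast_1d(self.radii))
        if any(b <= a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be strictly increasing")
        if self.conductivities is not None:
            self.conductivities = tuple(float(s) for s in self.conductivities)
            if len(self.conductivities) != len(self.radii):
                raise ValueError("need one conductivity per shell")
            if any(s <= 0 for s in self.conductivities):
                raise ValueError("conductivities must be positive")

    @classmethod
    def three_shell(cls, center, scalp_radius: float,
                    ratios=DEFAULT_RADIUS_RATIOS,
                    conductivities=DEFAULT_CONDUCTIVITIES) -> "SphereModel":
        return cls(center=center, radii=tuple(scalp_radius * r for r in ratios),
                   conductivities=conductivities)


@dataclass
class OverlappingSpheresModel:
    """One single-shell sphere per MEG channel, keyed by channel name."""

    spheres: dict
    global_sphere: SphereModel

    def sphere_for(self, channel_name: str) -> SphereModel:
        return self.spheres.get(channel_name, self.global_sphere)


@dataclass
class BergParams:
    """Three-dipole homogeneous-sphere approximation of a multilayer model."""

    lambdas: np.ndarray   # eccentricity scalings, in (0, 1)
    magnitudes: np.ndarray
    rms_rel: float        # relative fit RMS against the exact series


@dataclass
class SourceSpace:
    """Dipole locations (and, when constrained, orientations) on a mesh."""

    positions: np.ndarray
    orientations: np.ndarray | None
    constrained: bool
    parent_mesh: SurfaceMesh | None = None
    vertex_map: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.constrained:
            if self.orientations is None:
                raise ValueError("constrained source space requires orientations")
            self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
            norms = np.linalg.norm(self.orientations, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError("zero orientation vector")
            self.orientations = self.orientations / norms

    @property
    def n_sources(self) -> int:
        return len(self.positions)


@dataclass
class LeadField:
    """Sensors x sources gain matrix plus references to its ingredients."""

    gain: np.ndarray
    row_channels: list[str]
    source_space: SourceSpace
    head_model: object = None

    @property
    def constrained(self) -> bool:
        return self.gain.shape[1] == self.source_space.n_sources

    def __post_init__(self):
        n = self.source_space.n_sources
        if self.gain.shape[1] not in (n, 3 * n):
            raise ValueError("gain column count must be n or 3n")
        if self.gain.shape[0] != len(self.row_channels):
            raise ValueError("gain row count must match channel names")


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

def fit_sphere(points: np.ndarray,
               weights: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Weighted least-squares sphere fit (center, radius).

    A linear algebraic fit provides the starting point; one geometric
    Gauss-Newton pass on the radial residuals refines it.  Exact for points
    sampled on a sphere.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(P) < 4:
        raise ValueError("sphere fit needs at least 4 points")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    sv = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1e-30):
        raise ValueError("points are coplanar; sphere is undetermined")

    sw = np.sqrt(w / w.sum())
    A = np.hstack([2 * P, np.ones((len(P), 1))]) * sw[:, None]
    b = (P ** 2).sum(axis=1) * sw
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(max(sol[3] + center @ center, 0.0)))

    # one Gauss-Newton step on f_i = |p_i - c| - r
    for _ in range(1):
        diff = P - center
        dist = np.linalg.norm(diff, axis=1)
        dist = np.maximum(dist, 1e-300)
        f = dist - radius
        J = np.hstack([-diff / dist[:, None], -np.ones((len(P), 1))])
        Jw = J * sw[:, None]
        step, *_ = np.linalg.lstsq(Jw, -f * sw, rcond=None)
        center = center + step[:3]
        radius = float(radius + step[3])
    return center, radius


def fit_overlapping_spheres(scalp_mesh: SurfaceMesh, sensors: SensorArray,
                            sigma: float = 0.04,
                            far_threshold: float = 0.3) -> OverlappingSpheresModel:
    """Fit one sphere per MEG channel to the nearby scalp patch.

    Scalp vertices are weighted by ``exp(-d / sigma)`` where ``d`` is the
    Euclidean distance from the scalp point closest to the sensor.  Sensors
    farther than ``far_threshold`` meters from the scalp fall back to the
    globally fitted sphere with a warning.
    """
    meg_idx = [i for i, k in enumerate(sensors.kinds()) if k.startswith("MEG")]
    if not meg_idx:
        raise ValueError("no MEG channels in sensor array")
    verts = scalp_mesh.vertices
    g_center, g_radius = fit_sphere(verts)
    global_sphere = SphereModel(center=g_center, radii=(g_radius,))
    tree = cKDTree(verts)
    spheres = {}
    for i in meg_idx:
        ch = sensors.channels[i]
        d_sensor, nearest = tree.query(ch.position)
        if d_sensor > far_threshold:
            warnings.warn(f"channel {ch.name}: {d_sensor:.2f} m from scalp, "
                          "using global sphere")
            spheres[ch.name] = global_sphere
            continue
        d = np.linalg.norm(verts - verts[nearest], axis=1)
        w = np.exp(-d / sigma)
        try:
            c, r = fit_sphere(verts, weights=w)
        except ValueError:
            c, r = g_center, g_radius
        spheres[ch.name] = SphereModel(center=c, radii=(r,))
    return OverlappingSpheresModel(spheres=spheres, global_sphere=global_sphere)


# ---------------------------------------------------------------------------
# MEG: Sarvas closed form
# ---------------------------------------------------------------------------

def meg_sphere_lead(sphere_center: np.ndarray, dipole_pos: np.ndarray,
                    sensor_pos: np.ndarray, sensor_ori: np.ndarray) -> np.ndarray:
    """Lead vector L so that ``B . n = Q . L`` for dipole moment Q (A m).

    Vectorized over sensors: ``sensor_pos``/``sensor_ori`` may be (k, 3).
    Positions are absolute; the sphere enters only through its center.
    """
    c = np.asarray(sphere_center, dtype=float)
    r0 = np.asarray(dipole_pos, dtype=float) - c
    r = np.atleast_2d(np.asarray(sensor_pos, dtype=float)) - c
    n = np.atleast_2d(np.asarray(sensor_ori, dtype=float))

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    if np.any(a < 1e-6):
        raise ValueError("sensor coincides with the dipole location")
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn < 1e-9):
        raise ValueError("sensor at the sphere center")

    ar = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn ** 2 - r0 @ r.T)
    # gradient of F with respect to the sensor position
    coef_r = a ** 2 / rn + ar / a + 2 * a + 2 * rn
    coef_r0 = a + 2 * rn + ar / a
    gradF = coef_r[:, None] * r - coef_r0[:, None] * r0

    nF = np.einsum("ij,ij->i", n, gradF)
    # B.n = Q . mu0/(4 pi F^2) [ F (r0 x n) - (gradF . n) (r0 x r) ]
    lead = (MU0_OVER_4PI / F[:, None] ** 2) * (
        F[:, None] * np.cross(np.broadcast_to(r0, r.shape), n)
        - nF[:, None] * np.cross(np.broadcast_to(r0, r.shape), r))
    return lead


def _meg_lead_dipoles(sphere_center, dipole_pos, sensor_pos, sensor_ori) -> np.ndarray:
    """Sarvas lead vectors for many dipoles and one fixed sensor: (n, 3)."""
    c = np.asarray(sphere_center, dtype=float)
    r0 = np.atleast_2d(np.asarray(dipole_pos, dtype=float)) - c
    r = np.asarray(sensor_pos, dtype=float) - c
    n = np.asarray(sensor_ori, dtype=float)

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    if np.any(a < 1e-6):
        raise ValueError("sensor coincides with a dipole location")
    rn = np.linalg.norm(r)
    ar = a_vec @ r
    F = a * (rn * a + rn ** 2 - r0 @ r)
    coef_r = a ** 2 / rn + ar / a + 2 * a + 2 * rn
    coef_r0 = a + 2 * rn + ar / a
    gradF = coef_r[:, None] * r - coef_r0[:, None] * r0
    nF = gradF @ n
    return (MU0_OVER_4PI / F[:, None] ** 2) * (
        F[:, None] * np.cross(r0, n) - nF[:, None] * np.cross(r0, r))


def meg_sphere_gain(sphere_center, dipole_pos, dipole_moment, sensor_pos,
                    sensor_ori, gradient_baseline=None) -> np.ndarray:
    """Magnetic field (T) projected on the sensor orientation(s).

    Magnetometers evaluate the Sarvas field once; gradiometers are
    synthesized as the difference of two magnetometer evaluations at the
    coil positions ``pos +- baseline/2`` divided by the baseline length.
    """
    q = np.asarray(dipole_moment, dtype=float)
    if gradient_baseline is None:
        lead = meg_sphere_lead(sphere_center, dipole_pos, sensor_pos, sensor_ori)
        out = lead @ q
    else:
        bl = np.asarray(gradient_baseline, dtype=float)
        blen = np.linalg.norm(bl)
        pos = np.atleast_2d(np.asarray(sensor_pos, dtype=float))
        lead_a = meg_sphere_lead(sphere_center, dipole_pos, pos + bl / 2, sensor_ori)
        lead_b = meg_sphere_lead(sphere_center, dipole_pos, pos - bl / 2, sensor_ori)
        out = ((lead_a - lead_b) @ q) / blen
    return out if np.asarray(sensor_pos).ndim > 1 else float(out[0])


# ---------------------------------------------------------------------------
# EEG: homogeneous-sphere closed form
# ---------------------------------------------------------------------------

def eeg_homogeneous_lead(center, radius: float, conductivity: float,
                         dipole_pos, electrode_pos) -> np.ndarray:
    """Closed-form lead vectors for a dipole in a homogeneous sphere.

    Returns (k, 3) so that the surface potential is ``lead @ moment``.
    Obtained by analytically summing the Legendre expansion of the
    Neumann-boundary solution with generating-function identities; this is a
    separate route from the per-degree multilayer solver and serves as its
    equal-conductivity cross-check.
    """
    c = np.asarray(center, dtype=float)
    rq = np.asarray(dipole_pos, dtype=float) - c
    re = np.atleast_2d(np.asarray(electrode_pos, dtype=float)) - c
    R = float(radius)
    re = re / np.linalg.norm(re, axis=1, keepdims=True) * R  # snap to surface

    b = np.linalg.norm(rq)
    if b >= R:
        raise ValueError("dipole outside the sphere")
    re_hat = re / R
    if b < 1e-12 * R:
        # central dipole: only the l=1 harmonic survives
        return 3.0 / (4 * np.pi * conductivity * R ** 2) * re_hat
    rq_hat = rq / b
    t = b / R
    u = re_hat @ rq_hat
    s = np.sqrt(1 - 2 * t * u + t * t)
    # sum_{n>=1} (2n+1) t^n Pn(u)       = 2 t (u - t)/s^3 + 1/s - 1
    # sum_{n>=1} (2n+1)/n t^n Pn'(u)    = 2 t/s^3 + t (s + 1)/(s (1 - t u + s))
    c_r = (2 * t * (u - t) / s ** 3 + 1.0 / s - 1.0) / t
    c_t = 2.0 / s ** 3 + (s + 1.0) / (s * (1 - t * u + s))
    lead = (c_r - u * c_t)[:, None] * rq_hat + c_t[:, None] * re_hat
    return lead / (4 * np.pi * conductivity * R ** 2)


# ---------------------------------------------------------------------------
# EEG: concentric multilayer series
# ---------------------------------------------------------------------------

def _legendre_p_and_dp(u: np.ndarray, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(u) and P_n'(u) for n = 1..n_max by stable upward recurrence."""
    u = np.asarray(u, dtype=float)
    P = np.empty((n_max + 1,) + u.shape)
    dP = np.empty_like(P)
    P[0], dP[0] = 1.0, 0.0
    if n_max >= 1:
        P[1], dP[1] = u, 1.0
    for n in range(2, n_max + 1):
        P[n] = ((2 * n - 1) * u * P[n - 1] - (n - 1) * P[n - 2]) / n
        dP[n] = dP[n - 2] + (2 * n - 1) * P[n - 1]
    return P[1:], dP[1:]


def multilayer_coefficients(radii, conductivities, n_terms: int,
                            normalized: bool = True) -> np.ndarray:
    """Surface-potential factors f_n for a dipole in the innermost shell.

    Radii are normalized to the outer radius.  For each Legendre degree n the
    potential in shell j is ``A_j rho^n + B_j rho^-(n+1)`` plus, in the inner
    shell, the primary term ``rho^-(n+1)``; continuity of the potential and
    of the radial current at each interface and a zero-current outer boundary
    give a small linear system.  f_n is the surface value ``A_L + B_L``, so
    the homogeneous single shell recovers ``(2n+1)/n``.
    """
    radii = np.asarray(radii, dtype=float)
    sig = np.asarray(conductivities, dtype=float)
    L = len(radii)
    rho = radii / radii[-1]
    out = np.empty(n_terms)
    for n in range(1, n_terms + 1):
        m = 2 * L - 1
        A = np.zeros((m, m))
        rhs = np.zeros(m)
        # unknown order: A_1, A_2, B_2, ..., A_L, B_L

        def a_idx(j):  # shell index j = 0..L-1
            return 0 if j == 0 else 2 * j - 1

        def b_idx(j):
            return 2 * j

        row = 0
        for j in range(L - 1):
            r = rho[j]
            # potential continuity
            A[row, a_idx(j)] = r ** n
            if j > 0:
                A[row, b_idx(j)] = r ** (-(n + 1))
            A[row, a_idx(j + 1)] = -r ** n
            A[row, b_idx(j + 1)] = -r ** (-(n + 1))
            rhs[row] = 0.0 if j > 0 else -(r ** (-(n + 1)))
            row += 1
            # radial current continuity
            A[row, a_idx(j)] = sig[j] * n * r ** (n - 1)
            if j > 0:
                A[row, b_idx(j)] = -sig[j] * (n + 1) * r ** (-(n + 2))
            A[row, a_idx(j + 1)] = -sig[j + 1] * n * r ** (n - 1)
            A[row, b_idx(j + 1)] = sig[j + 1] * (n + 1) * r ** (-(n + 2))
            rhs[row] = 0.0 if j > 0 else sig[j] * (n + 1) * r ** (-(n + 2))
            row += 1
        # outer Neumann boundary at rho = 1
        if L == 1:
            A[row, a_idx(0)] = n
            rhs[row] = n + 1
        else:
            A[row, a_idx(L - 1)] = n
            A[row, b_idx(L - 1)] = -(n + 1)
            rhs[row] = 0.0
        sol = np.linalg.solve(A, rhs)
        if L == 1:
            out[n - 1] = sol[0] + 1.0  # homogeneous: A_1 + primary at rho=1
        else:
            out[n - 1] = sol[a_idx(L - 1)] + sol[b_idx(L - 1)]
    return out


def eeg_multilayer_lead(sphere: SphereModel, dipole_pos, electrode_pos,
                        n_terms: int = 80) -> np.ndarray:
    """Exact (truncated series) lead vectors for the concentric multilayer
    sphere; potential = ``lead @ moment`` in Volts per A m."""
    if sphere.conductivities is None:
        raise ValueError("multilayer model requires conductivities")
    c = sphere.center
    R = sphere.radii[-1]
    rq = np.asarray(dipole_pos, dtype=float) - c
    re = np.atleast_2d(np.asarray(electrode_pos, dtype=float)) - c
    re = re / np.linalg.norm(re, axis=1, keepdims=True) * R
    b = np.linalg.norm(rq)
    if b >= sphere.radii[0]:
        raise ValueError("dipole outside the innermost shell")
    f_n = multilayer_coefficients(sphere.radii, sphere.conductivities, n_terms)
    sigma1 = sphere.conductivities[0]
    re_hat = re / R
    if b < 1e-12 * R:
        return f_n[0] / (4 * np.pi * sigma1 * R ** 2) * re_hat
    rq_hat = rq / b
    t = b / R
    u = re_hat @ rq_hat
    P, dP = _legendre_p_and_dp(u, n_terms)        # (n_terms, k)
    ns = np.arange(1, n_terms + 1)
    beta = t ** (ns - 1) * f_n                    # b^(n-1)/R^(n-1) * f_n
    c_r = np.einsum("n,n,nk->k", beta, ns.astype(float), P)
    c_t = np.einsum("n,nk->k", beta, dP)
    lead = (c_r - u * c_t)[:, None] * rq_hat + c_t[:, None] * re_hat
    return lead / (4 * np.pi * sigma1 * R ** 2)


def eeg_multilayer_potential(sphere: SphereModel, dipole_pos, dipole_moment,
                             electrode_pos, n_terms: int = 80) -> np.ndarray:
    """Scalp potential (V) of a dipole in the concentric multilayer sphere."""
    lead = eeg_multilayer_lead(sphere, dipole_pos, electrode_pos, n_terms)
    out = lead @ np.asarray(dipole_moment, dtype=float)
    return out if np.asarray(electrode_pos).ndim > 1 else float(out[0])


# ---------------------------------------------------------------------------
# Berg three-dipole approximation
# ---------------------------------------------------------------------------

def _fibonacci_directions(k: int) -> np.ndarray:
    i = np.arange(k) + 0.5
    phi = np.pi * (1 + 5 ** 0.5) * i
    z = 1 - 2 * i / k
    r = np.sqrt(1 - z ** 2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def berg_approximation(sphere: SphereModel, n_terms: int = 80,
                       n_eccentricities: int = 9,
                       n_electrodes: int = 64) -> BergParams:
    """Fit the three-dipole single-sphere approximation of the multilayer model.

    The multilayer potential of a dipole at ``r_q`` is approximated by the sum
    of three homogeneous-sphere dipoles at ``lambda_j r_q`` with moments
    ``mu_j m``.  The (lambda, mu) pairs are fitted by least squares over a
    design grid of dipole eccentricities (0.1-0.9 of the inner radius), both
    radial and tangential unit moments, and a spread of electrode directions;
    magnitudes are solved linearly inside a nonlinear search over lambdas.
    """
    if sphere.conductivities is None or len(sphere.radii) < 2:
        raise ValueError("Berg approximation requires a multilayer model")
    R = sphere.radii[-1]
    inner = sphere.radii[0]
    sigma1 = sphere.conductivities[0]
    electrodes = sphere.center + R * _fibonacci_directions(n_electrodes)
    eccs = np.linspace(0.1, 0.9, n_eccentricities) * inner
    moments = (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))

    targets, configs = [], []
    for b in eccs:
        pos = sphere.center + np.array([0.0, 0.0, b])
        lead = eeg_multilayer_lead(sphere, pos, electrodes, n_terms)
        for m in moments:
            targets.append(lead @ m)
            configs.append((pos, m))
    target = np.concatenate(targets)
    scale = float(np.sqrt(np.mean(target ** 2)))

    def design_matrix(lambdas):
        cols = []
        for lam in lambdas:
            col = []
            for pos, m in configs:
                p = sphere.center + lam * (pos - sphere.center)
                col.append(eeg_homogeneous_lead(sphere.center, R, sigma1, p,
                                                electrodes) @ m)
            cols.append(np.concatenate(col))
        return np.stack(cols, axis=1)

    def residual(lambdas):
        M = design_matrix(lambdas)
        mu, *_ = np.linalg.lstsq(M, target, rcond=None)
        return M @ mu - target

    # Greedy term-by-term fit: each new dipole explains the residual of the
    # previous ones.  This keeps the expansion identifiable — with equal
    # conductivities the first term already fits (lambda ~ 1, mu ~ 1) and the
    # remaining magnitudes stay negligible instead of splitting degenerately.
    lambdas: list[float] = []
    resid = target.copy()
    grid = np.linspace(0.05, 1 - 1e-6, 60)
    for _ in range(3):
        def one_term(lam_arr):
            col = design_matrix([*lambdas, float(lam_arr[0])])[:, -1]
            mu1 = (col @ resid) / (col @ col)
            return col * mu1 - resid

        best_lam = min(grid, key=lambda l: np.sum(one_term([l]) ** 2))
        sol1 = least_squares(one_term, [best_lam], bounds=(1e-3, 1 - 1e-6))
        lambdas.append(float(sol1.x[0]))
        M = design_matrix(lambdas)
        mu, *_ = np.linalg.lstsq(M, target, rcond=None)
        resid = target - M @ mu

    if np.sqrt(np.mean(resid ** 2)) / scale > 1e-5:
        sol = least_squares(residual, np.array(lambdas),
                            bounds=(1e-3, 1 - 1e-6), xtol=1e-12, ftol=1e-12)
        joint = np.sort(sol.x)
        if np.sum(residual(joint) ** 2) < np.sum(resid ** 2):
            lambdas = joint
    order = np.argsort(lambdas)
    lambdas = np.asarray(lambdas, dtype=float)[order]
    M = design_matrix(lambdas)
    mu, *_ = np.linalg.lstsq(M, target, rcond=None)
    rms_rel = float(np.sqrt(np.mean((M @ mu - target) ** 2)) / scale)
    if rms_rel > 0.05:
        raise RuntimeError(f"Berg fit did not converge: relative RMS {rms_rel:.3f}")
    return BergParams(lambdas=lambdas, magnitudes=mu, rms_rel=rms_rel)


def eeg_berg_lead(sphere: SphereModel, berg: BergParams, dipole_pos,
                  electrode_pos) -> np.ndarray:
    """Lead vectors from a fitted Berg approximation (fast EEG forward)."""
    R = sphere.radii[-1]
    sigma1 = sphere.conductivities[0]
    c = sphere.center
    rq = np.asarray(dipole_pos, dtype=float)
    out = None
    for lam, mu in zip(berg.lambdas, berg.magnitudes):
        p = c + lam * (rq - c)
        lead = mu * eeg_homogeneous_lead(c, R, sigma1, p, electrode_pos)
        out = lead if out is None else out + lead
    return out


# ---------------------------------------------------------------------------
# source space
# ---------------------------------------------------------------------------

def build_source_space(cortex_mesh: SurfaceMesh, target_n: int = 15000,
                       constrained: bool = True, seed: int = 0) -> SourceSpace:
    """Decimate the cortical mesh and place one dipole per retained vertex.

    Decimation is a seeded nearest-seed vertex clustering: ``target_n``
    vertices of the original mesh are kept as representatives, every other
    vertex collapses onto its nearest representative, and degenerate or
    duplicated faces are discarded.  Dipoles therefore sit exactly on
    original cortical vertices.  When ``constrained`` the dipole orientations
    are the decimated mesh's area-weighted vertex normals.
    """
    n = cortex_mesh.n_vertices
    if target_n <= 0:
        raise ValueError("target_n must be positive")
    if target_n > n:
        warnings.warn(f"target_n {target_n} exceeds vertex count {n}; using all")
        target_n = n
    if target_n == n:
        mesh = cortex_mesh.copy()
        vertex_map = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(n, size=target_n, replace=False))
        tree = cKDTree(cortex_mesh.vertices[keep])
        _, assign = tree.query(cortex_mesh.vertices)
        faces = assign[cortex_mesh.faces]
        ok = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
              & (faces[:, 0] != faces[:, 2]))
        faces = faces[ok]
        faces = np.unique(np.sort(faces, axis=1), axis=0) if len(faces) else faces
        used = np.zeros(target_n, dtype=bool)
        used[faces.ravel()] = True
        remap = -np.ones(target_n, dtype=np.int64)
        remap[used] = np.arange(used.sum())
        vertex_map = keep[used]
        mesh = SurfaceMesh(
            vertices=cortex_mesh.vertices[vertex_map],
            faces=remap[faces],
            hemi=None if cortex_mesh.hemi is None else cortex_mesh.hemi[vertex_map],
            landmarks=cortex_mesh.landmarks)

    normals = mesh.vertex_normals.copy()
    zero = np.linalg.norm(normals, axis=1) < 1e-12
    if zero.any():  # isolated vertices: fall back to the outward direction
        v = mesh.vertices[zero] - mesh.vertices.mean(axis=0)
        normals[zero] = v / np.linalg.norm(v, axis=1, keepdims=True)
    return SourceSpace(positions=mesh.vertices,
                       orientations=normals if constrained else None,
                       constrained=constrained, parent_mesh=mesh,
                       vertex_map=vertex_map)


# ---------------------------------------------------------------------------
# lead-field assembly
# ---------------------------------------------------------------------------

def compute_leadfield(head_model, source_space: SourceSpace,
                      sensors: SensorArray, eeg_method: str = "berg",
                      n_terms: int = 80) -> LeadField:
    """Assemble the channels x sources gain matrix.

    ``head_model`` is a SphereModel (single shell for MEG-only, three shells
    for EEG), an OverlappingSpheresModel (MEG), or a dict mapping sensor-kind
    prefixes {"MEG", "EEG"} to such models for mixed arrays.  EEG rows are
    average-referenced; constrained spaces contract the 3-vector leads with
    the dipole orientations.
    """
    kinds = sensors.kinds()
    has_eeg = any(k == "EEG" for k in kinds)
    has_meg = any(k.startswith("MEG") for k in kinds)

    if isinstance(head_model, dict):
        meg_model = head_model.get("MEG")
        eeg_model = head_model.get("EEG")
    elif isinstance(head_model, OverlappingSpheresModel):
        meg_model, eeg_model = head_model, None
    elif isinstance(head_model, SphereModel):
        if head_model.conductivities is not None and len(head_model.radii) >= 2:
            meg_model, eeg_model = head_model, head_model
        else:
            meg_model, eeg_model = head_model, None
    else:
        raise TypeError(f"unsupported head model {type(head_model)}")

    if has_eeg and eeg_model is None:
        raise ValueError("EEG channels present but head model has no "
                         "conductivity shells")
    if has_meg and meg_model is None:
        raise ValueError("MEG channels present but no MEG-capable head model")

    berg = None
    if has_eeg and eeg_method == "berg":
        berg = berg_approximation(eeg_model, n_terms=n_terms)

    pos = source_space.positions
    n_src = source_space.n_sources
    gain3 = np.zeros((len(kinds), n_src, 3))

    eeg_rows = [i for i, k in enumerate(kinds) if k == "EEG"]
    if eeg_rows:
        epos = np.stack([sensors.channels[i].position for i in eeg_rows])
        for j in range(n_src):
            if berg is not None:
                lead = eeg_berg_lead(eeg_model, berg, pos[j], epos)
            else:
                lead = eeg_multilayer_lead(eeg_model, pos[j], epos, n_terms)
            gain3[eeg_rows, j, :] = lead
        # average reference across the EEG rows
        gain3[eeg_rows] -= gain3[eeg_rows].mean(axis=0, keepdims=True)

    for i, k in enumerate(kinds):
        if not k.startswith("MEG"):
            continue
        ch = sensors.channels[i]
        sphere = (meg_model.sphere_for(ch.name)
                  if isinstance(meg_model, OverlappingSpheresModel) else meg_model)
        if k == "MEG_GRAD" and ch.gradient_baseline is not None:
            bl = np.asarray(ch.gradient_baseline, dtype=float)
            blen = np.linalg.norm(bl)
            la = _meg_lead_dipoles(sphere.center, pos, ch.position + bl / 2,
                                   ch.orientation)
            lb = _meg_lead_dipoles(sphere.center, pos, ch.position - bl / 2,
                                   ch.orientation)
            gain3[i] = (la - lb) / blen
        else:
            gain3[i] = _meg_lead_dipoles(sphere.center, pos, ch.position,
                                         ch.orientation)

    if source_space.constrained:
        gain = np.einsum("cjk,jk->cj", gain3, source_space.orientations)
    else:
        gain = gain3.reshape(len(kinds), 3 * n_src)
    return LeadField(gain=gain, row_channels=sensors.names,
                     source_space=source_space, head_model=head_model)
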