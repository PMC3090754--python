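"""Forward models: sphere fits, Sarvas MEG field, multilayer EEG potential,
Berg approximation, source-space decimation, lead-field assembly."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from sourcestorm import forward as fw
from sourcestorm import simulate as sim
from sourcestorm.forward import (OverlappingSpheresModel, SphereModel,
                                 berg_approximation, build_source_space,
                                 compute_leadfield, eeg_berg_lead,
                                 eeg_homogeneous_lead, eeg_multilayer_lead,
                                 eeg_multilayer_potential,
                                 fit_overlapping_spheres, fit_sphere,
                                 meg_sphere_gain, meg_sphere_lead)


def _sphere_points(center, radius, n, seed=0):
    rng = np.random.default_rng(seed)
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return np.asarray(center) + radius * d


# ---------------------------------------------------------------------------
# sphere fitting
# ---------------------------------------------------------------------------

class TestFitSphere:
    def test_exact_on_noiseless_points(self):
        c, r = fit_sphere(_sphere_points([0.01, 0, 0.05], 0.09, 200))
        assert np.allclose(c, [0.01, 0, 0.05], atol=1e-10)
        assert abs(r - 0.09) < 1e-10

    def test_noisy_fit_matches_nonlinear_oracle(self):
        """Oracle: full nonlinear least squares from multiple restarts."""
        rng = np.random.default_rng(1)
        pts = _sphere_points([0.01, -0.02, 0.03], 0.09, 500, seed=1)
        pts += 1e-3 * rng.standard_normal(pts.shape)
        c, r = fit_sphere(pts)

        def resid(x):
            return np.linalg.norm(pts - x[:3], axis=1) - x[3]

        best = None
        for s in range(5):
            x0 = np.r_[pts.mean(axis=0) + 0.01 * rng.standard_normal(3), 0.08]
            sol = least_squares(resid, x0)
            if best is None or sol.cost < best.cost:
                best = sol
        assert np.linalg.norm(c - best.x[:3]) < 1e-3   # spec: < 1 mm
        assert np.linalg.norm(c - [0.01, -0.02, 0.03]) < 1e-3

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="coplanar"):
            fit_sphere(pts)


class TestOverlappingSpheres:
    def test_spherical_scalp_reduces_to_global(self, head, sensors):
        model = fit_overlapping_spheres(head["scalp"], sensors)
        g = model.global_sphere
        for name, s in model.spheres.items():
            assert np.linalg.norm(s.center - g.center) < 1e-6
            assert abs(s.radii[0] - g.radii[0]) < 1e-6

    def test_ellipsoidal_scalp_local_fit_beats_global(self, head, sensors):
        scalp = head["scalp"]
        v = scalp.vertices * np.array([1.0, 0.9, 1.1])
        from sourcestorm.core_io import SurfaceMesh
        ell = SurfaceMesh(vertices=v, faces=scalp.faces)
        model = fit_overlapping_spheres(ell, sensors)
        g = model.global_sphere
        from scipy.spatial import cKDTree
        tree = cKDTree(v)
        centers = np.array([model.spheres[c.name].center
                            for c in sensors.channels if c.kind.startswith("MEG")])
        assert centers.std(axis=0).max() > 1e-4  # per-channel centers differ
        # weighted residual of the local fit <= global sphere's on each patch
        for c in sensors.channels:
            if not c.kind.startswith("MEG"):
                continue
            s = model.spheres[c.name]
            _, nearest = tree.query(c.position)
            d = np.linalg.norm(v - v[nearest], axis=1)
            w = np.exp(-d / 0.04)

            def wres(center, radius):
                return np.sum(w * (np.linalg.norm(v - center, axis=1) - radius) ** 2)

            assert wres(s.center, s.radii[0]) <= wres(g.center, g.radii[0]) * (1 + 1e-9)

    def test_far_sensor_falls_back_to_global(self, head, sensors):
        import dataclasses
        far = dataclasses.replace(sensors.channels[-1], name="FAR",
                                  position=np.array([1.0, 0, 0]))
        from sourcestorm.core_io import SensorArray
        arr = SensorArray(channels=list(sensors.channels) + [far])
        with pytest.warns(UserWarning, match="global sphere"):
            model = fit_overlapping_spheres(head["scalp"], arr)
        assert model.spheres["FAR"] is model.global_sphere

    def test_requires_meg_channels(self, head):
        from sourcestorm.core_io import ChannelInfo, SensorArray
        eeg_only = SensorArray(channels=[ChannelInfo(name="E1", kind="EEG")])
        with pytest.raises(ValueError, match="no MEG"):
            fit_overlapping_spheres(head["scalp"], eeg_only)


# ---------------------------------------------------------------------------
# MEG sphere field
# ---------------------------------------------------------------------------

class TestMegSphere:
    sensors_pos = _sphere_points([0, 0, 0], 0.12, 30, seed=2)

    def test_radial_dipole_is_silent(self):
        ori = self.sensors_pos / np.linalg.norm(self.sensors_pos, axis=1,
                                                keepdims=True)
        b = meg_sphere_gain((0, 0, 0), (0, 0, 0.07), (0, 0, 1.0),
                            self.sensors_pos, ori)
        assert np.abs(b).max() < 1e-20

    def test_radial_component_matches_primary_current_oracle(self):
        """The radial field outside a spherical conductor comes from the
        primary current alone: B_r = mu0/4pi (Q x (r - r0)) . r_hat / |r-r0|^3."""
        r0 = np.array([0.02, 0.01, 0.05])
        Q = np.array([2e-9, -1e-9, 0.5e-9])
        pos = self.sensors_pos
        ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        b = meg_sphere_gain((0, 0, 0), r0, Q, pos, ori)
        a = pos - r0
        oracle = 1e-7 * np.einsum("ij,ij->i", np.cross(Q, a), ori) \
            / np.linalg.norm(a, axis=1) ** 3
        assert np.allclose(b, oracle, rtol=1e-10, atol=1e-25)

    def test_linearity_in_moment(self):
        pos, ori = self.sensors_pos[:5], np.tile([1.0, 0, 0], (5, 1))
        b1 = meg_sphere_gain((0, 0, 0), (0.01, 0.02, 0.05), (0, 1e-9, 0), pos, ori)
        b2 = meg_sphere_gain((0, 0, 0), (0.01, 0.02, 0.05), (0, 2e-9, 0), pos, ori)
        assert np.allclose(b2, 2 * b1, rtol=1e-12)

    def test_field_is_divergence_free(self):
        """Numerical check: div B = 0 outside the conductor."""
        r0 = np.array([0.0, 0.02, 0.05])
        Q = np.array([1e-9, 0, 1e-9])

        def B(p):
            e = np.eye(3)
            return np.array([meg_sphere_gain((0, 0, 0), r0, Q, p[None, :],
                                             e[k][None, :])[0] for k in range(3)])

        p = np.array([0.05, 0.06, 0.10])
        h = 1e-5
        div = sum((B(p + h * np.eye(3)[k])[k] - B(p - h * np.eye(3)[k])[k]) / (2 * h)
                  for k in range(3))
        assert abs(div) < 1e-10 * np.linalg.norm(B(p)) / h

    def test_gradiometer_difference(self):
        pos = np.array([[0.0, 0, 0.12]])
        ori = np.array([[1.0, 0, 0]])
        bl = np.array([0.02, 0, 0])
        r0, Q = (0.01, 0.03, 0.05), (1e-9, 1e-9, 0)
        grad = meg_sphere_gain((0, 0, 0), r0, Q, pos, ori, gradient_baseline=bl)
        ba = meg_sphere_gain((0, 0, 0), r0, Q, pos + bl / 2, ori)
        bb = meg_sphere_gain((0, 0, 0), r0, Q, pos - bl / 2, ori)
        assert np.allclose(grad, (ba - bb) / 0.02)

    def test_sensor_at_dipole_rejected(self):
        with pytest.raises(ValueError, match="coincides"):
            meg_sphere_lead((0, 0, 0), (0, 0, 0.12), np.array([[0, 0, 0.12]]),
                            np.array([[1.0, 0, 0]]))


# ---------------------------------------------------------------------------
# EEG multilayer potential
# ---------------------------------------------------------------------------

class TestEegMultilayer:
    sphere = SphereModel(center=(0.0, 0.01, 0.0), radii=(0.088, 0.093, 0.1),
                         conductivities=(0.33, 0.0042, 0.33))

    def test_equal_conductivities_match_homogeneous_closed_form(self):
        """Oracle: analytic generating-function sums (separate code path)."""
        eq = SphereModel(center=self.sphere.center, radii=self.sphere.radii,
                         conductivities=(0.33, 0.33, 0.33))
        elec = np.asarray(eq.center) + 0.1 * fw._fibonacci_directions(50)
        rng = np.random.default_rng(3)
        for _ in range(5):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            dip = np.asarray(eq.center) + rng.uniform(0.01, 0.8) * 0.088 * d
            series = eeg_multilayer_lead(eq, dip, elec, n_terms=200)
            closed = eeg_homogeneous_lead(eq.center, 0.1, 0.33, dip, elec)
            assert np.abs(series - closed).max() < 1e-8 * np.abs(closed).max()

    def test_potential_integrates_to_zero_over_scalp(self):
        """Only l >= 1 harmonics are present, so the exact surface integral
        vanishes; a Gauss-Legendre x uniform-azimuth product rule integrates
        spherical harmonics up to the series truncation exactly."""
        x, w = np.polynomial.legendre.leggauss(100)
        phi = 2 * np.pi * np.arange(200) / 200
        ct, ph = np.meshgrid(x, phi, indexing="ij")
        st = np.sqrt(1 - ct ** 2)
        dirs = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=-1)
        elec = np.asarray(self.sphere.center) + 0.1 * dirs.reshape(-1, 3)
        v = eeg_multilayer_potential(self.sphere,
                                     np.asarray(self.sphere.center) + [0, 0, 0.05],
                                     (1e-9, 0, 1e-9), elec)
        integral = (v.reshape(100, 200).mean(axis=1) * w).sum()
        assert abs(integral) < 1e-10 * np.abs(v).max()

    def test_insulating_skull_kills_scalp_potential(self):
        ins = SphereModel(center=(0, 0, 0), radii=(0.088, 0.093, 0.1),
                          conductivities=(0.33, 1e-12, 0.33))
        ref = SphereModel(center=(0, 0, 0), radii=(0.088, 0.093, 0.1),
                          conductivities=(0.33, 0.33, 0.33))
        elec = 0.1 * fw._fibonacci_directions(30)
        v_ins = eeg_multilayer_potential(ins, (0, 0, 0.05), (1e-9, 0, 0), elec)
        v_ref = eeg_multilayer_potential(ref, (0, 0, 0.05), (1e-9, 0, 0), elec)
        assert np.abs(v_ins).max() < 1e-4 * np.abs(v_ref).max()

    def test_dipole_outside_inner_shell_rejected(self):
        with pytest.raises(ValueError, match="innermost"):
            eeg_multilayer_potential(self.sphere,
                                     np.asarray(self.sphere.center) + [0, 0, 0.09],
                                     (1e-9, 0, 0), np.array([[0, 0, 0.1]]))


class TestBerg:
    def test_heldout_accuracy_vs_exact_series(self):
        sphere = SphereModel.three_shell((0, 0, 0), 0.1)
        berg = berg_approximation(sphere)
        assert berg.rms_rel < 0.02
        rng = np.random.default_rng(4)
        elec = 0.1 * fw._fibonacci_directions(37)
        for _ in range(8):
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            dip = rng.uniform(0.05, 0.8) * 0.088 * d
            m = rng.standard_normal(3) * 1e-9
            exact = eeg_multilayer_lead(sphere, dip, elec, n_terms=120) @ m
            approx = eeg_berg_lead(sphere, berg, dip, elec) @ m
            rel = np.sqrt(np.mean((approx - exact) ** 2) / np.mean(exact ** 2))
            assert rel < 0.02

    def test_equal_conductivities_degenerate_to_one_term(self):
        eq = SphereModel(center=(0, 0, 0), radii=(0.088, 0.093, 0.1),
                         conductivities=(0.33, 0.33, 0.33))
        berg = berg_approximation(eq)
        mags = np.abs(berg.magnitudes)
        dominant = mags.max()
        others = np.sort(mags)[:-1]
        assert np.all(others < 1e-3 * dominant)


# ---------------------------------------------------------------------------
# source space
# ---------------------------------------------------------------------------

class TestSourceSpace:
    def test_decimation_hits_target_within_2pct(self, head):
        src = build_source_space(head["cortex"], target_n=300, seed=0)
        assert abs(src.n_sources - 300) <= 6
        assert src.constrained
        norms = np.linalg.norm(src.orientations, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_orientations_match_decimated_normals(self, head):
        src = build_source_space(head["cortex"], target_n=250, seed=1)
        normals = src.parent_mesh.vertex_normals
        dots = np.einsum("ij,ij->i", src.orientations, normals)
        assert np.all(dots > 0.99)

    def test_identity_decimation(self, head):
        n = head["cortex"].n_vertices
        src = build_source_space(head["cortex"], target_n=n)
        assert src.n_sources == n
        assert np.array_equal(src.vertex_map, np.arange(n))

    def test_oversized_target_warns_and_uses_all(self, head):
        n = head["cortex"].n_vertices
        with pytest.warns(UserWarning, match="exceeds"):
            src = build_source_space(head["cortex"], target_n=n + 100)
        assert src.n_sources == n

    def test_dipoles_sit_on_original_vertices(self, head):
        src = build_source_space(head["cortex"], target_n=200, seed=2)
        assert np.allclose(src.positions,
                           head["cortex"].vertices[src.vertex_map])


# ---------------------------------------------------------------------------
# lead-field assembly
# ---------------------------------------------------------------------------

class TestLeadfield:
    def test_shapes_and_average_reference(self, leadfield, sensors):
        n_src = leadfield.source_space.n_sources
        assert leadfield.gain.shape == (len(sensors.channels), n_src)
        eeg_rows = [i for i, c in enumerate(sensors.channels) if c.kind == "EEG"]
        col_means = leadfield.gain[eeg_rows].mean(axis=0)
        assert np.abs(col_means).max() < 1e-12 * np.abs(leadfield.gain[eeg_rows]).max()

    def test_unconstrained_has_3n_columns(self, sphere_model, head, sensors):
        src = build_source_space(head["cortex"], target_n=100, constrained=False)
        lf = compute_leadfield(sphere_model, src, sensors)
        assert lf.gain.shape[1] == 300

    def test_meg_rows_conductivity_invariant(self, head, sensors, source_space):
        center, radius = fit_sphere(head["scalp"].vertices)
        m1 = SphereModel.three_shell(center, radius,
                                     conductivities=(0.33, 0.0042, 0.33))
        m2 = SphereModel.three_shell(center, radius,
                                     conductivities=(0.1, 0.5, 0.9))
        lf1 = compute_leadfield(m1, source_space, sensors)
        lf2 = compute_leadfield(m2, source_space, sensors)
        meg_rows = [i for i, ch in enumerate(sensors.channels)
                    if ch.kind.startswith("MEG")]
        assert np.array_equal(lf1.gain[meg_rows], lf2.gain[meg_rows])

    def test_eeg_gain_attenuates_with_depth(self, sphere_model, head, sensors):
        src = build_source_space(head["cortex"], target_n=100, seed=3)
        lf = compute_leadfield(sphere_model, src, sensors)
        deep = fw.SourceSpace(
            positions=sphere_model.center
            + 0.5 * (src.positions - sphere_model.center),
            orientations=src.orientations, constrained=True)
        lf_deep = compute_leadfield(sphere_model, deep, sensors)
        eeg = [i for i, ch in enumerate(sensors.channels) if ch.kind == "EEG"]
        n_shallow = np.linalg.norm(lf.gain[eeg], axis=0)
        n_deep = np.linalg.norm(lf_deep.gain[eeg], axis=0)
        assert np.all(n_deep < n_shallow)

    def test_overlapping_spheres_match_single_sphere_on_sphere(
            self, head, sensors, source_space):
        over = fit_overlapping_spheres(head["scalp"], sensors)
        center, radius = fit_sphere(head["scalp"].vertices)
        single = SphereModel(center=center, radii=(radius,))
        lf_o = compute_leadfield(over, source_space, _meg_subarray(sensors))
        lf_s = compute_leadfield(single, source_space, _meg_subarray(sensors))
        rel = (np.abs(lf_o.gain - lf_s.gain).max()
               / np.abs(lf_s.gain).max())
        assert rel < 1e-6

    def test_eeg_with_meg_only_model_rejected(self, head, sensors, source_space):
        center, radius = fit_sphere(head["scalp"].vertices)
        single = SphereModel(center=center, radii=(radius,))
        with pytest.raises(ValueError, match="EEG"):
            compute_leadfield(single, source_space, sensors)

    def test_constrained_gain_is_orientation_contraction(
            self, sphere_model, head, sensors):
        src_c = build_source_space(head["cortex"], target_n=50, seed=4)
        src_u = fw.SourceSpace(positions=src_c.positions, orientations=None,
                               constrained=False)
        lf_c = compute_leadfield(sphere_model, src_c, sensors)
        lf_u = compute_leadfield(sphere_model, src_u, sensors)
        g3 = lf_u.gain.reshape(lf_u.gain.shape[0], -1, 3)
        contracted = np.einsum("cjk,jk->cj", g3, src_c.orientations)
        assert np.allclose(lf_c.gain, contracted, rtol=1e-10, atol=1e-25)


def _meg_subarray(sensors):
    from sourcestorm.core_io import SensorArray
    megs = [c for c in sensors.channels if c.kind.startswith("MEG")]
    return SensorArray(channels=megs)
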