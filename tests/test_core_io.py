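"""I/O layer: ASCII electrodes, meshes, HDF5 containers, epoching, database."""

import numpy as np
import pytest

from sourcestorm import core_io
from sourcestorm.core_io import (ChannelInfo, Event, FormatError, Recording,
                                 SensorArray, SurfaceMesh, Transform,
                                 epoch_from_events)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

class TestTransform:
    def test_identity_roundtrip(self):
        T = Transform.identity()
        pts = np.random.default_rng(0).standard_normal((5, 3))
        assert np.allclose(T.apply(pts), pts)

    def test_inverse_composition(self):
        rng = np.random.default_rng(1)
        from scipy.spatial.transform import Rotation
        R = Rotation.random(random_state=1).as_matrix()
        T = Transform.from_rotation_translation(R, rng.standard_normal(3))
        pts = rng.standard_normal((7, 3))
        assert np.allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-12)

    @pytest.mark.parametrize("matrix", [
        np.eye(3),                                  # wrong shape
        np.diag([2.0, 1, 1, 1]),                    # non-orthonormal rotation
        np.diag([-1.0, 1, 1, 1]),                   # reflection
    ])
    def test_invalid_matrices_rejected(self, matrix):
        with pytest.raises(ValueError):
            Transform(matrix)

    def test_bad_last_row_rejected(self):
        m = np.eye(4)
        m[3, 0] = 0.1
        with pytest.raises(ValueError):
            Transform(m)


# ---------------------------------------------------------------------------
# electrode ASCII
# ---------------------------------------------------------------------------

class TestElectrodeAscii:
    def test_single_line_meters(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("E1 0.1 0 0\n")
        arr = core_io.read_electrode_ascii(p)
        assert len(arr.channels) == 1
        assert arr.channels[0].kind == "EEG"
        assert np.allclose(arr.channels[0].position, [0.1, 0, 0])

    def test_millimeter_autoscale(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("E1 100 0 0\n")
        arr = core_io.read_electrode_ascii(p, unit_policy="auto")
        assert np.allclose(arr.channels[0].position, [0.1, 0, 0])

    def test_unit_policy_override(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("E1 100 0 0\n")
        arr = core_io.read_electrode_ascii(p, unit_policy="m")
        assert np.allclose(arr.channels[0].position, [100, 0, 0])

    def test_arity_error_names_line(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("E1 0.1 0\n")
        with pytest.raises(FormatError, match="line 1"):
            core_io.read_electrode_ascii(p)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("E1 0.1 0 0\nE1 0 0.1 0\n")
        with pytest.raises(ValueError, match="duplicate"):
            core_io.read_electrode_ascii(p)

    def test_fiducials_and_head_points(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("NAS 0.1 0 0\nLPA 0 0.07 0\nRPA 0 -0.07 0\n"
                     "Cz 0 0 0.09\nHP001 0.05 0.05 0.05\n")
        arr = core_io.read_electrode_ascii(p)
        assert arr.fiducials is not None
        assert np.allclose(arr.fiducials.nasion, [0.1, 0, 0])
        assert arr.head_points.shape == (1, 3)
        assert arr.names == ["Cz"]

    def test_implausible_radii_warn(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("E1 0.4 0 0\nE2 0 0.4 0\n")
        with pytest.warns(UserWarning, match="radius"):
            core_io.read_electrode_ascii(p, unit_policy="m")

    def test_roundtrip(self, tmp_path, sensors):
        p = tmp_path / "rt.txt"
        core_io.write_electrode_ascii(sensors, p)
        back = core_io.read_electrode_ascii(p, unit_policy="m")
        n_eeg = len([c for c in sensors.channels if c.kind == "EEG"])
        # MEG channels re-read as EEG kind (ASCII carries positions only)
        assert len(back.channels) == len(sensors.channels)
        pos0 = sensors.positions
        assert np.allclose(back.positions, pos0, atol=1e-9)


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

TETRA_V = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
TETRA_F = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])


class TestMeshIO:
    def test_tetrahedron_obj(self, tmp_path):
        p = tmp_path / "t.obj"
        core_io.write_mesh(SurfaceMesh(TETRA_V, TETRA_F), p)
        mesh = core_io.read_mesh(p)
        assert mesh.n_vertices == 4 and len(mesh.faces) == 4

    @pytest.mark.parametrize("fmt,suffix", [("obj", ".obj"), ("fs_ascii", ".asc")])
    def test_roundtrip_icosphere(self, tmp_path, fmt, suffix, head):
        mesh = head["scalp"]
        p = tmp_path / f"s{suffix}"
        core_io.write_mesh(mesh, p, format=fmt)
        back = core_io.read_mesh(p, format=fmt)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
        assert np.array_equal(back.faces, mesh.faces)

    def test_dangling_face_index_rejected(self):
        with pytest.raises(FormatError, match="range"):
            SurfaceMesh(TETRA_V, np.array([[0, 1, 9]]))

    def test_normals_unit_and_outward(self, head):
        mesh = head["scalp"]
        norms = np.linalg.norm(mesh.vertex_normals, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        # sphere centered at origin: normals align with radial direction
        radial = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
        assert np.allclose((mesh.vertex_normals * radial).sum(axis=1), 1.0, atol=1e-3)


# ---------------------------------------------------------------------------
# recording container
# ---------------------------------------------------------------------------

def _tiny_recording():
    channels = [ChannelInfo(name="A", kind="EEG"), ChannelInfo(name="B", kind="EEG")]
    data = np.arange(200, dtype=float).reshape(2, 100)
    events = [Event(0.1, 0.0, "stim"), Event(0.5, 0.05, "stim"), Event(0.8, 0, "resp")]
    return Recording(data=data, sfreq=100.0, t0=0.0,
                     sensors=SensorArray(channels=channels), events=events,
                     bad_segments=[(0.45, 0.55)])


class TestRecordingContainer:
    def test_lossless_roundtrip(self, tmp_path):
        rec = _tiny_recording()
        p = tmp_path / "r.h5"
        core_io.write_recording(rec, p)
        back = core_io.read_recording(p)
        assert np.array_equal(back.data, rec.data)  # bit-identical
        assert back.sfreq == rec.sfreq
        assert [e.label for e in back.events] == ["stim", "stim", "resp"]
        assert back.bad_segments == [(0.45, 0.55)]

    def test_missing_dataset_is_format_error(self, tmp_path):
        import h5py
        p = tmp_path / "bad.h5"
        with h5py.File(p, "w") as f:
            f.create_dataset("data", data=np.zeros((2, 10)))
            f.create_dataset("t0", data=0.0)
            f.attrs["meta"] = "{}"
        with pytest.raises(FormatError, match="sfreq"):
            core_io.read_recording(p)

    def test_epochs_roundtrip(self, tmp_path):
        rec = _tiny_recording()
        ep = epoch_from_events(rec, "stim", (-0.05, 0.1))
        p = tmp_path / "e.h5"
        core_io.write_epochs(ep, p)
        back = core_io.read_epochs(p)
        assert np.array_equal(back.epochs, ep.epochs)
        assert np.array_equal(back.rejected, ep.rejected)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

class TestEpoching:
    def test_sample_count_closed_interval(self):
        channels = [ChannelInfo(name="A", kind="EEG")]
        rec = Recording(data=np.zeros((1, 3000)), sfreq=1000.0, t0=0.0,
                        sensors=SensorArray(channels=channels),
                        events=[Event(1.0, 0, "x")])
        ep = epoch_from_events(rec, "x", (-0.2, 0.5))
        assert ep.epochs.shape == (1, 1, 701)

    def test_out_of_bounds_event_dropped_with_warning(self):
        rec = _tiny_recording()
        rec.events.append(Event(0.05, 0, "early"))
        with pytest.warns(UserWarning, match="dropped"):
            with pytest.raises(ValueError):
                epoch_from_events(rec, "early", (-0.2, 0.5))

    def test_bad_segment_flags_rejected(self):
        rec = _tiny_recording()
        ep = epoch_from_events(rec, "stim", (-0.05, 0.1))
        # second stim event at 0.5 s overlaps the (0.45, 0.55) bad segment
        assert list(ep.rejected) == [False, True]

    def test_no_matching_events(self):
        with pytest.raises(ValueError, match="no events"):
            epoch_from_events(_tiny_recording(), "nope", (-0.1, 0.1))


# ---------------------------------------------------------------------------
# events TSV
# ---------------------------------------------------------------------------

def test_events_tsv_roundtrip(tmp_path):
    events = [Event(0.1, 0.0, "a"), Event(0.25, 0.5, "b")]
    p = tmp_path / "ev.tsv"
    core_io.write_events_tsv(events, p)
    back = core_io.read_events_tsv(p)
    assert [(e.onset, e.duration, e.label) for e in back] == \
           [(0.1, 0.0, "a"), (0.25, 0.5, "b")]
    with pytest.raises(FormatError, match="missing"):
        q = tmp_path / "bad.tsv"
        q.write_text("onset\tlabel\n0.1\tx\n")
        core_io.read_events_tsv(q)


# ---------------------------------------------------------------------------
# study database
# ---------------------------------------------------------------------------

class TestStudyTree:
    def _make_db(self, root, subjects=("s01", "s02"), conditions=("pre", "post")):
        rec = _tiny_recording()
        for s in subjects:
            for c in conditions:
                d = root / s / c
                d.mkdir(parents=True)
                core_io.write_recording(rec, d / "raw.h5")
        return root

    def test_enumerates_nodes(self, tmp_path):
        root = self._make_db(tmp_path / "proto")
        tree = core_io.db_index(root)
        assert tree.subjects == ["s01", "s02"]
        assert tree.conditions("s01") == ["post", "pre"]
        assert len(tree.nodes) == 4
        assert tree.get("s01", "pre", "raw").kind == "recording"

    def test_empty_protocol(self, tmp_path):
        root = tmp_path / "empty"
        root.mkdir()
        tree = core_io.db_index(root)
        assert tree.subjects == []

    def test_duplicate_item_rejected(self, tmp_path):
        root = self._make_db(tmp_path / "proto", subjects=("s01",),
                             conditions=("c1",))
        tree = core_io.db_index(root)
        item = tree.get("s01", "c1", "raw")
        with pytest.raises(ValueError, match="duplicate"):
            tree.add_item("s01", "c1", item)

    def test_unknown_files_ignored_with_warning(self, tmp_path):
        root = self._make_db(tmp_path / "proto", subjects=("s01",),
                             conditions=("c1",))
        (root / "s01" / "c1" / "notes.xyz").write_text("hi")
        with pytest.warns(UserWarning, match="ignoring"):
            tree = core_io.db_index(root)
        assert set(tree.items("s01", "c1")) == {"raw"}
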