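"""Domain types, the three-level study database, and file format I/O.

All internal coordinates are SI: positions in meters, times in seconds,
magnetic fields in Tesla, electric potentials in Volts.  Millimeter
coordinates are accepted only at ASCII import, through an explicit
auto-scaling heuristic.

Supported on-disk formats
-------------------------
* electrode / head-point positions: generic ASCII ``name x y z``
* surface meshes: Wavefront OBJ and FreeSurfer ASCII triangle meshes
* recordings: an HDF5 container (datasets ``data``, ``sfreq``, ``t0`` plus a
  JSON attribute blob for channel metadata, events and bad segments)
* event tables: tab-separated values with columns onset, duration, label
* the study database: a ``protocol/subject/condition`` directory tree with
  JSON sidecars describing each stored item
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

logger = logging.getLogger("sourcestorm")

CHANNEL_KINDS = ("EEG", "MEG_MAG", "MEG_GRAD", "OTHER")
FIDUCIAL_NAMES = ("NAS", "LPA", "RPA")


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transform:
    """A 4x4 homogeneous rigid transform (rotation + translation, meters).

    The rotation block must be orthonormal with determinant +1 and the last
    row must be (0, 0, 0, 1); both are checked at construction.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"transform matrix must be 4x4, got {m.shape}")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block has negative determinant (reflection)")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last row must be (0, 0, 0, 1)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, R: np.ndarray, t: np.ndarray) -> "Transform":
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of points (or a single 3-vector)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        v = np.atleast_2d(np.asarray(vectors, dtype=float))
        out = v @ self.rotation.T
        return out[0] if np.asarray(vectors).ndim == 1 else out

    def compose(self, other: "Transform") -> "Transform":
        """Return self @ other (apply ``other`` first)."""
        return Transform(self.matrix @ other.matrix)

    def inverse(self) -> "Transform":
        R = self.rotation.T
        return Transform.from_rotation_translation(R, -R @ self.translation)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({"matrix": self.matrix.tolist()}, indent=1))

    @classmethod
    def from_json(cls, path) -> "Transform":
        return cls(np.asarray(json.loads(Path(path).read_text())["matrix"]))


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

@dataclass
class ChannelInfo:
    """One sensor: name, kind, position and (for MEG) coil orientation."""

    name: str
    kind: str = "EEG"
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray | None = None
    bad: bool = False
    gradient_baseline: np.ndarray | None = None  # planar-gradiometer coil offset (m)

    def __post_init__(self):
        if self.kind not in CHANNEL_KINDS:
            raise ValueError(f"unknown channel kind {self.kind!r}")
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.orientation is not None:
            o = np.asarray(self.orientation, dtype=float).reshape(3)
            n = np.linalg.norm(o)
            if self.kind.startswith("MEG"):
                if not np.isclose(n, 1.0, atol=1e-6):
                    raise ValueError(f"MEG channel {self.name}: orientation must be unit norm")
            self.orientation = o
        elif self.kind.startswith("MEG"):
            raise ValueError(f"MEG channel {self.name} requires a coil orientation")


@dataclass
class Fiducials:
    """Nasion and left/right preauricular points in some source frame."""

    nasion: np.ndarray
    lpa: np.ndarray
    rpa: np.ndarray

    def __post_init__(self):
        for name in ("nasion", "lpa", "rpa"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        pts = self.as_array()
        d = [np.linalg.norm(pts[i] - pts[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        if min(d) <= 0.01:
            raise ValueError("fiducials closer than 1 cm")
        area = 0.5 * np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        if area <= 1e-6:
            raise ValueError("fiducials are (near-)collinear")

    def as_array(self) -> np.ndarray:
        return np.stack([self.nasion, self.lpa, self.rpa])


@dataclass
class SensorArray:
    """An ordered set of channels plus optional fiducials and head points."""

    channels: list[ChannelInfo]
    fiducials: Fiducials | None = None
    head_points: np.ndarray | None = None

    def __post_init__(self):
        if len(self.channels) == 0:
            raise ValueError("SensorArray needs at least one channel")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate channel names: {dup}")
        if self.head_points is not None:
            self.head_points = np.asarray(self.head_points, dtype=float).reshape(-1, 3)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def positions(self) -> np.ndarray:
        return np.stack([c.position for c in self.channels])

    def kinds(self) -> list[str]:
        return [c.kind for c in self.channels]

    def pick(self, kind: str) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.kind == kind]

    def good_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.channels) if not c.bad]


# ---------------------------------------------------------------------------
# recordings and epochs
# ---------------------------------------------------------------------------

@dataclass
class Event:
    onset: float
    duration: float
    label: str

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("event duration must be >= 0")


@dataclass
class Recording:
    """Multichannel time series with channel metadata and events."""

    data: np.ndarray
    sfreq: float
    sensors: SensorArray
    t0: float = 0.0
    events: list[Event] = field(default_factory=list)
    bad_segments: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("recording data must be channels x samples")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.data.shape[0] != len(self.sensors.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.sensors.channels)} channels"
            )
        span = (self.t0, self.t0 + (self.data.shape[1] - 1) / self.sfreq)
        for ev in self.events:
            if not (span[0] <= ev.onset <= span[1]):
                raise ValueError(f"event {ev.label!r} at {ev.onset} s outside span {span}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy(), events=list(self.events),
                       bad_segments=list(self.bad_segments))


@dataclass
class EpochSet:
    """Trials x channels x samples, time-locked to an event onset."""

    epochs: np.ndarray
    times: np.ndarray
    sensors: SensorArray
    rejected: np.ndarray | None = None

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        self.times = np.asarray(self.times, dtype=float)
        if self.epochs.shape[2] != self.times.size:
            raise ValueError("epoch sample count does not match time axis")
        if self.epochs.shape[1] != len(self.sensors.channels):
            raise ValueError("epoch channel count does not match sensor array")
        if self.rejected is None:
            self.rejected = np.zeros(self.epochs.shape[0], dtype=bool)
        else:
            self.rejected = np.asarray(self.rejected, dtype=bool)
            if self.rejected.size != self.epochs.shape[0]:
                raise ValueError("rejected flags length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def sfreq(self) -> float:
        if self.times.size < 2:
            return 1.0
        return 1.0 / float(np.mean(np.diff(self.times)))

    def good(self) -> np.ndarray:
        return self.epochs[~self.rejected]

    def copy(self) -> "EpochSet":
        return EpochSet(self.epochs.copy(), self.times.copy(), self.sensors,
                        self.rejected.copy())


# ---------------------------------------------------------------------------
# surface meshes
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated surface with area-weighted vertex normals.

    ``hemi`` optionally labels each vertex 0 (left) / 1 (right) for
    per-hemisphere processing; ``landmarks`` may carry named anatomical
    reference points used for rigid pre-alignment.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray | None = None
    hemi: np.ndarray | None = None
    landmarks: dict | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("faces must be triangles (m x 3 indices)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise FormatError("face index out of range")
        if self.vertex_normals is None:
            self.vertex_normals = _area_weighted_normals(self.vertices, self.faces)
        else:
            self.vertex_normals = np.asarray(self.vertex_normals, dtype=float).reshape(-1, 3)
        if self.hemi is not None:
            self.hemi = np.asarray(self.hemi)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(),
                           self.vertex_normals.copy(),
                           None if self.hemi is None else self.hemi.copy(),
                           None if self.landmarks is None else dict(self.landmarks))


def _area_weighted_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Vertex normals as the normalized sum of incident-face area normals."""
    v = vertices
    if len(faces) == 0:
        return np.zeros_like(v)
    fn = np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]])
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, faces[:, k], fn)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return normals / norm


# ---------------------------------------------------------------------------
# electrode / head point ASCII
# ---------------------------------------------------------------------------

def read_electrode_ascii(path, unit_policy: str = "auto") -> SensorArray:
    """Read a generic ASCII electrode file (``name x y z`` per line).

    Lines may be whitespace- or comma-delimited; ``#`` starts a comment.
    Rows named NAS/LPA/RPA become fiducials, rows named ``HP*`` head points.
    With ``unit_policy='auto'`` coordinates are interpreted as millimeters
    (and scaled to meters) when the median coordinate magnitude exceeds
    0.5; ``'m'`` and ``'mm'`` force the respective unit.
    """
    if unit_policy not in ("auto", "m", "mm"):
        raise ValueError(f"unknown unit policy {unit_policy!r}")
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 4:
            raise FormatError(
                f"{path}: line {lineno}: expected 'name x y z', got {len(parts)} fields")
        name = parts[0]
        try:
            xyz = np.array([float(p) for p in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric coordinate") from exc
        rows.append((name, xyz))
    if not rows:
        raise FormatError(f"{path}: no electrode rows found")

    coords = np.stack([xyz for _, xyz in rows])
    scale = 1.0
    if unit_policy == "mm":
        scale = 1e-3
    elif unit_policy == "auto" and np.median(np.linalg.norm(coords, axis=1)) > 0.5:
        scale = 1e-3
        logger.info("%s: coordinates look like millimeters, scaling to meters", path)
    coords = coords * scale

    fid = {}
    channels, head_points = [], []
    for (name, _), xyz in zip(rows, coords):
        upper = name.upper()
        if upper in FIDUCIAL_NAMES:
            if upper in fid:
                raise FormatError(f"{path}: duplicate fiducial {name}")
            fid[upper] = xyz
        elif upper.startswith("HP"):
            head_points.append(xyz)
        else:
            channels.append(ChannelInfo(name=name, kind="EEG", position=xyz))

    fiducials = None
    if len(fid) == 3:
        fiducials = Fiducials(nasion=fid["NAS"], lpa=fid["LPA"], rpa=fid["RPA"])
    elif fid:
        warnings.warn(f"{path}: incomplete fiducial set {sorted(fid)} ignored")

    if not channels:
        raise FormatError(f"{path}: no channel rows (only fiducials/head points)")
    arr = SensorArray(channels=channels, fiducials=fiducials,
                      head_points=np.stack(head_points) if head_points else None)
    _check_scalp_radii(arr, path)
    return arr


def _check_scalp_radii(sensors: SensorArray, origin_label) -> None:
    """Warn when positions are implausible for a human head (unit slip guard)."""
    pts = sensors.positions
    if sensors.head_points is not None:
        pts = np.vstack([pts, sensors.head_points])
    r99 = float(np.percentile(np.linalg.norm(pts, axis=1), 99))
    if not (0.05 <= r99 <= 0.15):
        warnings.warn(
            f"{origin_label}: 99th-percentile point radius {r99:.3g} m is outside "
            "[0.05, 0.15] m; check coordinate units")


def write_electrode_ascii(sensors: SensorArray, path) -> None:
    lines = []
    if sensors.fiducials is not None:
        f = sensors.fiducials
        for name, p in (("NAS", f.nasion), ("LPA", f.lpa), ("RPA", f.rpa)):
            lines.append(f"{name} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    for c in sensors.channels:
        p = c.position
        lines.append(f"{c.name} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    if sensors.head_points is not None:
        for i, p in enumerate(sensors.head_points):
            lines.append(f"HP{i:04d} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def read_mesh(path, format: str | None = None) -> SurfaceMesh:
    """Read a triangle mesh from Wavefront OBJ or FreeSurfer ASCII."""
    path = Path(path)
    fmt = format or ("fs_ascii" if path.suffix in (".asc", ".srf") else "obj")
    if fmt == "obj":
        loaded = trimesh.load(str(path), file_type="obj", process=False)
        if isinstance(loaded, trimesh.Scene):
            geoms = list(loaded.geometry.values())
            if not geoms:
                raise FormatError(f"{path}: no geometry in OBJ")
            loaded = trimesh.util.concatenate(geoms)
        faces = np.asarray(loaded.faces)
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise FormatError(f"{path}: non-triangular faces")
        return SurfaceMesh(np.asarray(loaded.vertices), faces)
    if fmt == "fs_ascii":
        return _read_fs_ascii(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


def _read_fs_ascii(path) -> SurfaceMesh:
    """FreeSurfer ASCII surface: header comment, counts, vertex and face rows."""
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    try:
        nv, nf = (int(x) for x in lines[0].split()[:2])
        verts = np.array([[float(x) for x in ln.split()[:3]] for ln in lines[1:1 + nv]])
        faces = np.array([[int(x) for x in ln.split()[:3]] for ln in lines[1 + nv:1 + nv + nf]])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed FreeSurfer ASCII surface") from exc
    if len(verts) != nv or len(faces) != nf:
        raise FormatError(f"{path}: vertex/face count mismatch with header")
    return SurfaceMesh(verts, faces)


def write_mesh(mesh: SurfaceMesh, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("fs_ascii" if path.suffix in (".asc", ".srf") else "obj")
    if fmt == "obj":
        lines = [f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}" for v in mesh.vertices]
        lines += [f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}" for f in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "fs_ascii":
        lines = [f"#!ascii surface written by sourcestorm",
                 f"{mesh.n_vertices} {len(mesh.faces)}"]
        lines += [f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g} 0" for v in mesh.vertices]
        lines += [f"{f[0]} {f[1]} {f[2]} 0" for f in mesh.faces]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


# ---------------------------------------------------------------------------
# events TSV
# ---------------------------------------------------------------------------

def read_events_tsv(path) -> list[Event]:
    df = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration", "label"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing event columns {sorted(missing)}")
    return [Event(float(r.onset), float(r.duration), str(r.label))
            for r in df.itertuples(index=False)]


def write_events_tsv(events: list[Event], path) -> None:
    pd.DataFrame(
        {"onset": [e.onset for e in events],
         "duration": [e.duration for e in events],
         "label": [e.label for e in events]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# HDF5 recording container
# ---------------------------------------------------------------------------

def _sensors_to_dict(sensors: SensorArray) -> dict:
    d = {"channels": [
        {"name": c.name, "kind": c.kind, "position": c.position.tolist(),
         "orientation": None if c.orientation is None else c.orientation.tolist(),
         "bad": bool(c.bad),
         "gradient_baseline": (None if c.gradient_baseline is None
                               else np.asarray(c.gradient_baseline).tolist())}
        for c in sensors.channels]}
    if sensors.fiducials is not None:
        f = sensors.fiducials
        d["fiducials"] = {"nasion": f.nasion.tolist(), "lpa": f.lpa.tolist(),
                          "rpa": f.rpa.tolist()}
    if sensors.head_points is not None:
        d["head_points"] = sensors.head_points.tolist()
    return d


def _sensors_from_dict(d: dict) -> SensorArray:
    channels = [ChannelInfo(name=c["name"], kind=c["kind"], position=c["position"],
                            orientation=c["orientation"], bad=c["bad"],
                            gradient_baseline=c.get("gradient_baseline"))
                for c in d["channels"]]
    fid = d.get("fiducials")
    fiducials = Fiducials(**fid) if fid else None
    hp = d.get("head_points")
    return SensorArray(channels=channels, fiducials=fiducials,
                       head_points=None if hp is None else np.asarray(hp))


def write_recording(rec: Recording, path) -> None:
    """Write a Recording to the native HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("sfreq", data=float(rec.sfreq))
        f.create_dataset("t0", data=float(rec.t0))
        meta = {
            "sensors": _sensors_to_dict(rec.sensors),
            "events": [{"onset": e.onset, "duration": e.duration, "label": e.label}
                       for e in rec.events],
            "bad_segments": [list(map(float, s)) for s in rec.bad_segments],
        }
        f.attrs["meta"] = json.dumps(meta)
        f.attrs["kind"] = "recording"


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        for key in ("data", "sfreq", "t0"):
            if key not in f:
                raise FormatError(f"{path}: missing dataset {key!r}")
        data = f["data"][()]
        sfreq = float(f["sfreq"][()])
        t0 = float(f["t0"][()])
        meta = json.loads(f.attrs["meta"])
    sensors = _sensors_from_dict(meta["sensors"])
    if data.shape[0] != len(sensors.channels):
        raise FormatError(f"{path}: data rows != channel count")
    events = [Event(**e) for e in meta["events"]]
    bad_segments = [tuple(s) for s in meta["bad_segments"]]
    return Recording(data=data, sfreq=sfreq, t0=t0, sensors=sensors,
                     events=events, bad_segments=bad_segments)


def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.epochs)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("rejected", data=epochs.rejected.astype(np.uint8))
        f.attrs["meta"] = json.dumps({"sensors": _sensors_to_dict(epochs.sensors)})
        f.attrs["kind"] = "epochs"


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for key in ("epochs", "times", "rejected"):
            if key not in f:
                raise FormatError(f"{path}: missing dataset {key!r}")
        data = f["epochs"][()]
        times = f["times"][()]
        rejected = f["rejected"][()].astype(bool)
        meta = json.loads(f.attrs["meta"])
    return EpochSet(epochs=data, times=times, rejected=rejected,
                    sensors=_sensors_from_dict(meta["sensors"]))


def write_arrays(path, kind: str, meta: dict | None = None, **arrays) -> None:
    """Store named float arrays plus a JSON metadata blob (generic container)."""
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr))
        f.attrs["kind"] = kind
        f.attrs["meta"] = json.dumps(meta or {})


def read_arrays(path) -> tuple[str, dict, dict]:
    with h5py.File(path, "r") as f:
        kind = f.attrs.get("kind", "unknown")
        meta = json.loads(f.attrs.get("meta", "{}"))
        arrays = {name: f[name][()] for name in f}
    return str(kind), meta, arrays


def container_kind(path) -> str:
    with h5py.File(path, "r") as f:
        return str(f.attrs.get("kind", "unknown"))


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch_from_events(rec: Recording, label: str, window: tuple[float, float]) -> EpochSet:
    """Cut fixed-length epochs around every event with the given label.

    The window is a closed interval relative to event onset; the sample count
    is ``round((t_max - t_min) * sfreq) + 1``.  Events whose window falls
    outside the recording are dropped with a warning; epochs overlapping a
    bad segment are kept but flagged rejected.
    """
    t_min, t_max = window
    if not t_min < t_max:
        raise ValueError(f"window must have t_min < t_max, got {window}")
    matching = [e for e in rec.events if e.label == label]
    if not matching:
        raise ValueError(f"no events labeled {label!r}")
    n_samp = int(round((t_max - t_min) * rec.sfreq)) + 1
    times = t_min + np.arange(n_samp) / rec.sfreq

    trials, rejected = [], []
    for ev in matching:
        start = int(round((ev.onset + t_min - rec.t0) * rec.sfreq))
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            warnings.warn(
                f"event {label!r} at {ev.onset} s: window exceeds recording, dropped")
            continue
        trials.append(rec.data[:, start:stop])
        lo, hi = ev.onset + t_min, ev.onset + t_max
        bad = any(not (hi < s or lo > e) for s, e in rec.bad_segments)
        rejected.append(bad)
    if not trials:
        raise ValueError(f"all epochs for {label!r} fell outside the recording")
    return EpochSet(epochs=np.stack(trials), times=times, sensors=rec.sensors,
                    rejected=np.array(rejected, dtype=bool))


# ---------------------------------------------------------------------------
# study database
# ---------------------------------------------------------------------------

@dataclass
class StudyItem:
    name: str
    kind: str
    path: Path


@dataclass
class StudyTree:
    """Three-level study database: protocol -> subjects -> conditions -> items."""

    protocol: str
    root: Path
    nodes: dict = field(default_factory=dict)  # (subject, condition) -> {name: StudyItem}

    @property
    def subjects(self) -> list[str]:
        return sorted({s for s, _ in self.nodes})

    def conditions(self, subject: str) -> list[str]:
        return sorted({c for s, c in self.nodes if s == subject})

    def items(self, subject: str, condition: str) -> dict:
        return self.nodes.get((subject, condition), {})

    def get(self, subject: str, condition: str, name: str) -> StudyItem:
        return self.nodes[(subject, condition)][name]

    def add_item(self, subject: str, condition: str, item: StudyItem) -> None:
        node = self.nodes.setdefault((subject, condition), {})
        if item.name in node:
            raise ValueError(
                f"duplicate item {item.name!r} in {subject}/{condition}")
        node[item.name] = item


def db_index(root) -> StudyTree:
    """Index a ``protocol/subject/condition`` directory tree with JSON sidecars.

    Each data file ``X.h5`` may carry a sidecar ``X.json`` declaring at least
    its item kind; files without a recognized extension are ignored with a
    warning.  Duplicate item names within one node raise.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(root)
    tree = StudyTree(protocol=root.name, root=root)
    for subj_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for cond_dir in sorted(p for p in subj_dir.iterdir() if p.is_dir()):
            for f in sorted(cond_dir.iterdir()):
                if f.suffix == ".json":
                    continue
                if f.suffix not in (".h5", ".obj", ".asc", ".txt", ".tsv"):
                    warnings.warn(f"ignoring unrecognized file {f}")
                    continue
                sidecar = f.with_suffix(".json")
                if sidecar.exists():
                    kind = json.loads(sidecar.read_text()).get("kind", "unknown")
                elif f.suffix == ".h5":
                    kind = container_kind(f)
                else:
                    kind = {"obj": "surface", "asc": "surface",
                            "txt": "electrodes", "tsv": "events"}[f.suffix[1:]]
                tree.add_item(subj_dir.name, cond_dir.name,
                              StudyItem(name=f.stem, kind=kind, path=f))
    return tree
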