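"""Plug-in process registry and batch pipeline runner.

Processes are named, typed transformations (input kind -> output kind) with
a parameter schema; pipelines are ordered lists of (process, parameters)
applied to items selected from the study database.  Each output gets a JSON
provenance sidecar pinning the process name, parameters, input content
hashes, and seed, so re-running an identical pipeline reproduces identical
output hashes.
"""

from __future__ import annotations

import hashlib
import importlib.util
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import core_io
from .core_io import StudyItem, StudyTree

logger = logging.getLogger("sourcestorm")

#: item kinds known to the database
KINDS = ("recording", "epochs", "sources", "timefreq", "stat", "surface",
         "leadfield", "any")


@dataclass
class ProcessDef:
    """A registered process: typed callable with a validated parameter schema.

    ``schema`` maps parameter names to ``(type, default)`` pairs; defaults
    must pass their own type check.
    """

    name: str
    input_kind: str
    output_kind: str
    schema: dict
    fn: object

    def __post_init__(self):
        if self.input_kind not in KINDS or self.output_kind not in KINDS:
            raise ValueError(f"process {self.name!r}: unknown kind")
        for pname, spec in self.schema.items():
            if (not isinstance(spec, tuple)) or len(spec) != 2:
                raise ValueError(
                    f"process {self.name!r}: schema field {pname!r} must be "
                    "(type, default)")
            ptype, default = spec
            if default is not None and not isinstance(default, ptype):
                raise ValueError(
                    f"process {self.name!r}: default for {pname!r} fails its "
                    "type check")

    def resolve_params(self, params: dict) -> dict:
        out = {}
        for pname, (ptype, default) in self.schema.items():
            if pname in params:
                val = params[pname]
                if val is not None and not isinstance(val, ptype):
                    try:
                        val = ptype(val)
                    except Exception as exc:
                        raise ValueError(
                            f"{self.name}: parameter {pname!r} expects "
                            f"{ptype.__name__}") from exc
                out[pname] = val
            else:
                out[pname] = default
        unknown = set(params) - set(self.schema)
        if unknown:
            raise ValueError(f"{self.name}: unknown parameters {sorted(unknown)}")
        return out


_REGISTRY: dict[str, ProcessDef] = {}


def register_process(proc: ProcessDef) -> None:
    if proc.name in _REGISTRY:
        raise ValueError(f"process {proc.name!r} already registered")
    _REGISTRY[proc.name] = proc


def get_process(name: str) -> ProcessDef:
    if name not in _REGISTRY:
        raise KeyError(f"unknown process {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name]


def list_processes() -> list[str]:
    return sorted(_REGISTRY)


def clear_registry(keep_builtin: bool = True) -> None:
    _REGISTRY.clear()
    if keep_builtin:
        _register_builtin()


def discover_processes(directory) -> list[str]:
    """Import every ``*.py`` file in a plug-in directory; modules register
    their processes at import time.  Returns the names added."""
    before = set(_REGISTRY)
    for path in sorted(Path(directory).glob("*.py")):
        spec = importlib.util.spec_from_file_location(f"sourcestorm_plugin_{path.stem}",
                                                      path)
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
    return sorted(set(_REGISTRY) - before)


# ---------------------------------------------------------------------------
# pipelines
# ---------------------------------------------------------------------------

@dataclass
class PipelineStep:
    process: str
    params: dict = field(default_factory=dict)


@dataclass
class Pipeline:
    steps: list[PipelineStep]
    select: dict = field(default_factory=dict)  # subject/condition/item patterns

    def validate(self) -> None:
        prev_out = None
        for k, step in enumerate(self.steps):
            proc = get_process(step.process)
            proc.resolve_params(step.params)
            if prev_out is not None and proc.input_kind not in ("any", prev_out):
                raise ValueError(
                    f"step {k + 1} ({proc.name}): expects {proc.input_kind!r} "
                    f"but previous step produces {prev_out!r}")
            prev_out = proc.output_kind

    def to_yaml(self, path=None) -> str:
        payload = {"select": self.select,
                   "steps": [{"process": s.process, "params": s.params}
                             for s in self.steps]}
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "Pipeline":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        steps = [PipelineStep(process=s["process"], params=s.get("params") or {})
                 for s in d.get("steps", [])]
        return cls(steps=steps, select=d.get("select") or {})


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _match(pattern, value: str) -> bool:
    import fnmatch
    return pattern is None or fnmatch.fnmatch(value, pattern)


def run_pipeline(pipeline: Pipeline, db: StudyTree, dry_run: bool = False,
                 seed: int = 0) -> dict:
    """Execute a validated pipeline over the selected database items.

    Every step reads the previous step's in-memory object, and the final
    object is written next to the input with a provenance sidecar.  With
    ``dry_run`` the plan is returned without executing anything.
    """
    pipeline.validate()
    first = get_process(pipeline.steps[0].process)
    sel = pipeline.select
    targets = []
    for (subject, condition), items in sorted(db.nodes.items()):
        if not (_match(sel.get("subject"), subject)
                and _match(sel.get("condition"), condition)):
            continue
        for item in items.values():
            if first.input_kind in ("any", item.kind) and _match(sel.get("item"),
                                                                 item.name):
                targets.append((subject, condition, item))
    if not targets:
        raise ValueError("pipeline selection matched no database items")

    report = {"plan": [(s, c, it.name) for s, c, it in targets], "outputs": []}
    if dry_run:
        return report

    for subject, condition, item in targets:
        obj = _load_item(item)
        input_hash = _hash_file(item.path)
        for step in pipeline.steps:
            proc = get_process(step.process)
            params = proc.resolve_params(step.params)
            obj = proc.fn(obj, **params)
        last = get_process(pipeline.steps[-1].process)
        out_name = f"{item.name}_{'_'.join(s.process for s in pipeline.steps)}"
        out_path = item.path.parent / f"{out_name}.h5"
        _save_item(obj, last.output_kind, out_path)
        provenance = {
            "kind": last.output_kind,
            "pipeline": [{"process": s.process,
                          "params": get_process(s.process).resolve_params(s.params)}
                         for s in pipeline.steps],
            "input": str(item.path.name),
            "input_sha256": input_hash,
            "seed": seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "output_sha256": _hash_file(out_path),
        }
        out_path.with_suffix(".json").write_text(json.dumps(provenance, indent=1))
        db.add_item(subject, condition,
                    StudyItem(name=out_name, kind=last.output_kind, path=out_path))
        report["outputs"].append(str(out_path))
        logger.info("pipeline: %s/%s/%s -> %s", subject, condition, item.name,
                    out_path.name)
    return report


def _load_item(item: StudyItem):
    if item.kind == "recording":
        return core_io.read_recording(item.path)
    if item.kind == "epochs":
        return core_io.read_epochs(item.path)
    raise ValueError(f"cannot load item kind {item.kind!r}")


def _save_item(obj, kind: str, path) -> None:
    if kind == "recording":
        core_io.write_recording(obj, path)
    elif kind == "epochs":
        core_io.write_epochs(obj, path)
    else:
        import numpy as np
        core_io.write_arrays(path, kind, values=np.asarray(obj))


# ---------------------------------------------------------------------------
# built-in processes
# ---------------------------------------------------------------------------

def _register_builtin() -> None:
    from . import preprocess

    def _bandpass(obj, low, high, order):
        return preprocess.bandpass_filter(
            obj, preprocess.FilterSpec(low=low, high=high, order=order))

    register_process(ProcessDef(
        name="bandpass", input_kind="any", output_kind="epochs",
        schema={"low": (float, 1.0), "high": (float, 40.0), "order": (int, 4)},
        fn=_bandpass))
    register_process(ProcessDef(
        name="baseline", input_kind="epochs", output_kind="epochs",
        schema={"start": (float, -0.2), "end": (float, 0.0)},
        fn=lambda ep, start, end: preprocess.baseline_correct(ep, (start, end))))
    register_process(ProcessDef(
        name="resample", input_kind="any", output_kind="epochs",
        schema={"sfreq": (float, 250.0)},
        fn=lambda obj, sfreq: preprocess.resample(obj, sfreq)))
    register_process(ProcessDef(
        name="average", input_kind="epochs", output_kind="recording",
        schema={}, fn=lambda ep: preprocess.average_epochs(ep)))


_register_builtin()
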