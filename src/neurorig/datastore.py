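"""Hierarchical session storage: typed directories with human-readable
JSON indices, HDF5 array payloads with full timing/transform metadata.

Every directory carries a ``.index.json`` listing its children and their
metadata; indices are rewritten atomically (temp file + rename) so a
session is never left with an index that disagrees with its contents.
Arrays live one-per-file in HDF5 with the payload at ``/data``, metadata as
root attributes, and per-frame times at ``/frame_times`` for image series.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import h5py
import numpy as np

from neurorig.rig import Transform3D
from neurorig.signals import Frame, FrameSeries, Trace

__all__ = [
    "DirHandle",
    "DataStoreError",
    "init_session",
    "open_session",
    "open_dir",
    "store_task_result",
]

INDEX_NAME = ".index.json"


class DataStoreError(RuntimeError):
    pass


def _atomic_write_json(path: Path, doc: dict):
    tmp = path.with_name(path.name + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
    os.replace(tmp, path)


class DirHandle:
    """One directory in a session hierarchy."""

    def __init__(self, path: Path, session: "Session", dir_type: str = ""):
        self.path = Path(path)
        self.session = session
        self.dir_type = dir_type

    # -- index -------------------------------------------------------------
    @property
    def _index_path(self) -> Path:
        return self.path / INDEX_NAME

    def _read_index(self) -> dict:
        if not self._index_path.exists():
            return {"dir_type": self.dir_type, "metadata": {}, "children": {}}
        with open(self._index_path) as fh:
            return json.load(fh)

    def _write_index(self, doc: dict):
        _atomic_write_json(self._index_path, doc)

    @property
    def metadata(self) -> dict:
        return self._read_index().get("metadata", {})

    def set_metadata(self, **fields):
        doc = self._read_index()
        doc.setdefault("metadata", {}).update(fields)
        self._write_index(doc)

    def children(self) -> dict:
        return self._read_index().get("children", {})

    # -- directories ---------------------------------------------------------
    def create_child_dir(self, dir_type: str, name: str | None = None,
                         metadata: dict | None = None) -> "DirHandle":
        """Create a typed child directory, validating its required metadata.

        Name collisions are resolved by numeric suffixing (run_000, run_001,
        ...); the parent index is updated atomically.
        """
        metadata = dict(metadata or {})
        schema = self.session.dir_types.get(dir_type)
        if schema is None:
            raise DataStoreError(f"unregistered directory type {dir_type!r}")
        missing = [f for f in schema.get("required", []) if f not in metadata]
        if missing:
            raise DataStoreError(
                f"directory type {dir_type!r} requires metadata fields "
                f"{missing}")
        base = name or dir_type
        final = self._unique_name(base)
        child_path = self.path / final
        child_path.mkdir()
        child = DirHandle(child_path, self.session, dir_type)
        child._write_index({"dir_type": dir_type, "metadata": metadata,
                            "children": {}})
        doc = self._read_index()
        doc.setdefault("children", {})[final] = {
            "kind": "dir", "dir_type": dir_type, "metadata": metadata}
        self._write_index(doc)
        return child

    def _unique_name(self, base: str) -> str:
        existing = set(self.children()) | {p.name for p in self.path.iterdir()}
        if base not in existing:
            return base
        k = 0
        while f"{base}_{k:03d}" in existing:
            k += 1
        return f"{base}_{k:03d}"

    def child(self, name: str) -> "DirHandle":
        rec = self.children().get(name)
        if rec is None or rec.get("kind") != "dir":
            raise DataStoreError(f"no child directory {name!r} in {self.path}")
        return DirHandle(self.path / name, self.session, rec.get("dir_type", ""))

    # -- arrays --------------------------------------------------------------
    def write_array(self, name: str, payload, metadata: dict | None = None) -> str:
        """Store a Trace, FrameSeries or raw ndarray as one HDF5 file.

        Returns the record name actually used (suffixing applies on
        collision).  Metadata is written as HDF5 root attributes together
        with a content checksum used to detect corruption on read-back.
        """
        metadata = dict(metadata or {})
        if isinstance(payload, Trace):
            data = payload.samples
            metadata.update(payload_kind="trace", rate=payload.rate,
                            t0=payload.t0, units=payload.units,
                            channel=payload.channel)
            frame_times = None
            transforms = None
        elif isinstance(payload, FrameSeries):
            data = payload.stack()
            metadata.update(payload_kind="frame_series",
                            objective=payload[0].objective,
                            exposure=payload[0].exposure)
            frame_times = payload.times
            transforms = np.stack([f.transform.matrix for f in payload])
        else:
            data = np.asarray(payload)
            metadata.setdefault("payload_kind", "array")
            frame_times = None
            transforms = None
        if data.dtype.kind == "f" and not np.all(np.isfinite(data)):
            raise DataStoreError(f"payload {name!r} contains non-finite values")

        final = self._unique_name(name)
        fpath = self.path / f"{final}.h5"
        checksum = hashlib.sha256(np.ascontiguousarray(data).tobytes()).hexdigest()
        with h5py.File(fpath, "w") as hf:
            hf.create_dataset("data", data=data)
            if frame_times is not None:
                hf.create_dataset("frame_times", data=frame_times)
            if transforms is not None:
                hf.create_dataset("transforms", data=transforms)
            for k, v in metadata.items():
                if v is None:
                    continue
                hf.attrs[k] = v
            hf.attrs["sha256"] = checksum
        doc = self._read_index()
        doc.setdefault("children", {})[final] = {
            "kind": "dataset", "file": fpath.name, "metadata": metadata}
        self._write_index(doc)
        return final

    def read_array(self, name: str):
        """Read a record back as (payload, metadata).

        Traces and frame series are reconstructed with their sampling and
        transform metadata; a checksum mismatch raises DataStoreError.
        """
        rec = self.children().get(name)
        if rec is None or rec.get("kind") != "dataset":
            raise DataStoreError(f"no dataset record {name!r} in {self.path}")
        fpath = self.path / rec["file"]
        with h5py.File(fpath, "r") as hf:
            data = hf["data"][()]
            meta = {k: v for k, v in hf.attrs.items()}
            stored = meta.pop("sha256", None)
            actual = hashlib.sha256(
                np.ascontiguousarray(data).tobytes()).hexdigest()
            if stored is not None and stored != actual:
                raise DataStoreError(
                    f"checksum mismatch reading {name!r} from {fpath}")
            kind = meta.get("payload_kind", "array")
            if kind == "trace":
                payload = Trace(data, float(meta["rate"]),
                                float(meta.get("t0", 0.0)),
                                str(meta.get("units", "")),
                                str(meta.get("channel", "")))
            elif kind == "frame_series":
                times = hf["frame_times"][()]
                tmats = hf["transforms"][()]
                payload = FrameSeries([
                    Frame(pixels=data[i], transform=Transform3D(tmats[i]),
                          objective=str(meta.get("objective", "")),
                          t_start=float(times[i]),
                          exposure=float(meta.get("exposure", 0.0)))
                    for i in range(data.shape[0])])
            else:
                payload = data
        return payload, meta

    # -- consistency -----------------------------------------------------------
    def fsck(self) -> list[str]:
        """Check that the index matches on-disk contents, recursively.

        Returns a list of problem descriptions (empty means consistent).
        """
        problems = []
        idx = self._read_index()
        children = idx.get("children", {})
        on_disk = {p.name for p in self.path.iterdir()
                   if p.name != INDEX_NAME and not p.name.endswith(".tmp")}
        expected = set()
        for name, rec in children.items():
            if rec.get("kind") == "dir":
                expected.add(name)
                if not (self.path / name).is_dir():
                    problems.append(f"{self.path}: indexed dir {name!r} missing")
                else:
                    problems += DirHandle(self.path / name, self.session,
                                          rec.get("dir_type", "")).fsck()
            else:
                expected.add(rec["file"])
                if not (self.path / rec["file"]).is_file():
                    problems.append(
                        f"{self.path}: indexed dataset {name!r} missing")
        stray = on_disk - expected
        if stray:
            problems.append(f"{self.path}: unindexed entries {sorted(stray)}")
        return problems


class Session:
    """Root of a storage hierarchy plus its directory-type schemas."""

    def __init__(self, root: Path, dir_types: dict):
        self.root_path = Path(root)
        self.dir_types = dir_types

    @property
    def root(self) -> DirHandle:
        return DirHandle(self.root_path, self, dir_type="session")


def init_session(root, dir_type_definitions: dict | None = None) -> DirHandle:
    """Create (or reopen) a session root with directory-type schemas.

    ``dir_type_definitions`` maps a type name (day, slice, cell,
    protocol_run, ...) to {"required": [field, ...]}.  Re-initializing an
    existing session keeps its data and refreshes the schema registry.
    """
    root = Path(root)
    dir_types = dict(dir_type_definitions or {})
    for name, schema in dir_types.items():
        if not isinstance(schema, dict) or not isinstance(
                schema.get("required", []), list):
            raise DataStoreError(f"malformed directory type definition {name!r}")
    try:
        root.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataStoreError(f"cannot create session root {root}: {exc}") from exc
    session = Session(root, dir_types)
    handle = session.root
    idx_path = root / INDEX_NAME
    if idx_path.exists():
        doc = handle._read_index()
        doc["dir_types"] = dir_types
        handle._write_index(doc)
    else:
        handle._write_index({"dir_type": "session", "metadata": {},
                             "children": {}, "dir_types": dir_types})
    return handle


def open_session(root) -> DirHandle:
    """Open an existing session root, restoring its directory-type schemas."""
    root = Path(root)
    idx_path = root / INDEX_NAME
    if not idx_path.exists():
        raise DataStoreError(f"{root} is not a session (no {INDEX_NAME})")
    with open(idx_path) as fh:
        doc = json.load(fh)
    return Session(root, doc.get("dir_types", {})).root


def open_dir(path) -> DirHandle:
    """Open any directory inside a session as a DirHandle."""
    path = Path(path)
    if not (path / INDEX_NAME).exists():
        raise DataStoreError(f"{path} has no {INDEX_NAME}")
    # walk up to find the session root (the index holding dir_types)
    node = path
    while True:
        with open(node / INDEX_NAME) as fh:
            doc = json.load(fh)
        if "dir_types" in doc or node.parent == node or \
                not (node.parent / INDEX_NAME).exists():
            break
        node = node.parent
    session = Session(node, doc.get("dir_types", {}))
    return DirHandle(path, session)


def store_task_result(session_dir: DirHandle, spec, result) -> DirHandle:
    """Persist an executed task's per-device payloads under a new run dir."""
    session_dir.session.dir_types.setdefault("protocol_run", {"required": []})
    meta = {"duration": spec.duration, "status": result.status}
    if spec.protocol.get("parameters"):
        meta["parameters"] = spec.protocol["parameters"]
    run = session_dir.create_child_dir("protocol_run", name="run",
                                       metadata=meta)
    for dev, payload in result.data.items():
        if not isinstance(payload, dict):
            continue
        for key, value in payload.items():
            if isinstance(value, (Trace, FrameSeries)):
                run.write_array(f"{dev}.{key}", value,
                                metadata={"device": dev})
    return run
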