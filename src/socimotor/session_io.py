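"""Reading and writing sensor recordings and session manifests.

A dyadic session consists of six sensor streams — left wrist, right
wrist and torso for each of the two agents (child and clinician) —
recorded synchronously at a common sampling rate (128 Hz by default).
Each stream is a CSV with columns ``time, wx, wy, wz``: time in seconds
and triaxial angular velocity in deg/s.  The manifest (YAML or JSON)
carries subject metadata and the map from (agent, placement) to file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import (
    AlignmentError,
    FormatError,
    InputError,
    ManifestError,
    SamplingError,
)

logger = logging.getLogger(__name__)

AGENTS = ("child", "clinician")
PLACEMENTS = ("left_wrist", "right_wrist", "torso")
#: canonical ordering of the six sensors in matrices (child block first)
SENSOR_ORDER = [(a, p) for a in AGENTS for p in PLACEMENTS]

# absolute tolerance on |dt - 1/fs|, in seconds
_DT_TOL = 1e-6


@dataclass
class SensorStream:
    """One sensor's triaxial angular-velocity record.

    ``w`` has shape (n, 3) holding (Vx, Vy, Vz) in deg/s; ``t`` holds
    sample timestamps in seconds, strictly increasing and uniform.
    """

    agent: str
    placement: str
    fs: float
    t: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        if self.agent not in AGENTS:
            raise ManifestError(f"unknown agent {self.agent!r}")
        if self.placement not in PLACEMENTS:
            raise ManifestError(f"unknown placement {self.placement!r}")
        if self.fs <= 0:
            raise ManifestError("sampling rate must be positive")
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[1] != 3:
            raise FormatError("w must have shape (n, 3)")
        if len(self.t) != len(self.w):
            raise FormatError("time and velocity lengths differ")

    def __len__(self):
        return len(self.t)

    def slice(self, start: int, stop: int) -> "SensorStream":
        return replace(self, t=self.t[start:stop], w=self.w[start:stop])


@dataclass
class TaskSegment:
    name: str
    task_type: str  # socio_motor | abstract | emotional
    start_s: float
    end_s: float


@dataclass
class SessionManifest:
    """Metadata for one dyadic recording session."""

    subject_id: str
    sex: str  # M | F
    age: float
    group_label: str  # NT | ASD
    visit: int = 1
    ados_module: int | None = None
    ados_total: int | None = None
    task_segments: list[TaskSegment] = field(default_factory=list)
    sensor_files: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ManifestError(f"sex must be M or F, got {self.sex!r}")
        if self.group_label not in ("NT", "ASD"):
            raise ManifestError(f"group_label must be NT or ASD")
        if self.visit < 1:
            raise ManifestError("visit must be >= 1")


@dataclass
class RunConfig:
    """Analysis configuration shared across the pipeline.

    ``window_samples`` of 1000 corresponds to ~7.8 s at 128 Hz, the
    window size at which binary spike trains are treated as locally
    stationary.  ``te_history_k`` is the embedded history length for
    transfer entropy (20 by default); source history ``te_history_l``
    defaults to the target history.  ``apen_m='auto'`` sets the
    template length to the rounded mean inter-spike interval (capped
    at 10).
    """

    window_samples: int = 1000
    apen_m: int | str = "auto"
    apen_r: float = 0.5
    log_base: float = 2.0
    te_history_k: int = 20
    te_history_l: int | None = None
    seed: int = 0
    hand: str = "left"
    mms_flank_mode: str = "flank_minima"  # or "min_to_min_mean"
    amplitude_floor: float = 0.0
    allow_undersampled: bool = False
    gamma_floor_n: int = 30
    emd_bins: int = 32
    ami_max_lag: int = 64
    ami_bins: int = 16

    def __post_init__(self):
        if self.window_samples < 64:
            raise InputError("window_samples must be >= 64")
        if self.te_history_k < 1:
            raise InputError("te_history_k must be >= 1")
        if self.log_base <= 1:
            raise InputError("log_base must be > 1")
        if self.hand not in ("left", "right"):
            raise InputError("hand must be left or right")

    @property
    def hand_placement(self) -> str:
        return "left_wrist" if self.hand == "left" else "right_wrist"

    @property
    def te_l(self) -> int:
        return self.te_history_k if self.te_history_l is None else self.te_history_l


def read_sensor_csv(path, agent: str, placement: str, fs: float = 128.0) -> SensorStream:
    """Read one sensor CSV (columns time, wx, wy, wz) into a stream.

    Raises :class:`FormatError` on a malformed header and
    :class:`SamplingError` (with the gap index) when successive
    timestamps deviate from 1/fs beyond tolerance — e.g. a skipped
    sample.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    required = ["time", "wx", "wy", "wz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[required]
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError(f"{path}: non-numeric values in data columns")
    t = df["time"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        bad = np.flatnonzero(np.abs(dt - 1.0 / fs) > _DT_TOL)
        if bad.size:
            i = int(bad[0])
            raise SamplingError(
                f"{path}: non-uniform sampling at row {i} -> {i + 1} "
                f"(dt={dt[i]:.6f} s, expected {1.0 / fs:.6f} s)",
                gap_index=i,
            )
    return SensorStream(agent=agent, placement=placement, fs=fs,
                        t=t, w=df[["wx", "wy", "wz"]].to_numpy(dtype=float))


def write_sensor_csv(path, stream: SensorStream) -> None:
    df = pd.DataFrame({
        "time": stream.t,
        "wx": stream.w[:, 0],
        "wy": stream.w[:, 1],
        "wz": stream.w[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.17g")


def _parse_manifest_dict(doc: dict, base_dir) -> SessionManifest:
    try:
        segs = [
            TaskSegment(s["name"], s["task_type"], float(s["start_s"]), float(s["end_s"]))
            for s in doc.get("task_segments", []) or []
        ]
        files = {}
        for entry in doc["sensor_files"]:
            key = (entry["agent"], entry["placement"])
            if key in files:
                raise ManifestError(f"duplicate sensor entry {key}")
            files[key] = str(base_dir / entry["path"]) if base_dir else entry["path"]
        return SessionManifest(
            subject_id=str(doc["subject_id"]),
            sex=doc["sex"],
            age=float(doc["age"]),
            group_label=doc["group_label"],
            visit=int(doc.get("visit", 1)),
            ados_module=doc.get("ados_module"),
            ados_total=doc.get("ados_total"),
            task_segments=segs,
            sensor_files=files,
        )
    except KeyError as exc:
        raise ManifestError(f"manifest missing field {exc}") from exc


def read_manifest(path) -> SessionManifest:
    """Read a YAML or JSON session manifest (by file extension)."""
    from pathlib import Path

    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ManifestError(f"{path}: manifest root must be a mapping")
    return _parse_manifest_dict(doc, path.parent)


def write_manifest(path, manifest: SessionManifest) -> None:
    from pathlib import Path

    path = Path(path)
    doc = {
        "subject_id": manifest.subject_id,
        "sex": manifest.sex,
        "age": manifest.age,
        "group_label": manifest.group_label,
        "visit": manifest.visit,
        "ados_module": manifest.ados_module,
        "ados_total": manifest.ados_total,
        "task_segments": [
            {"name": s.name, "task_type": s.task_type,
             "start_s": s.start_s, "end_s": s.end_s}
            for s in manifest.task_segments
        ],
        "sensor_files": [
            {"agent": a, "placement": p, "path": str(Path(f).name)}
            for (a, p), f in manifest.sensor_files.items()
        ],
    }
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def load_session(manifest_path) -> tuple[SessionManifest, dict[tuple[str, str], SensorStream]]:
    """Load a manifest plus its six sensor streams, aligned in time.

    Streams are truncated to the common overlapping interval (their
    timestamps are authoritative); truncation is logged.  Exactly six
    (agent, placement) entries are required, and a zero-length overlap
    raises :class:`AlignmentError`.
    """
    manifest = read_manifest(manifest_path)
    if len(manifest.sensor_files) != 6:
        raise ManifestError(
            f"expected exactly 6 sensor files, got {len(manifest.sensor_files)}")
    missing = set(SENSOR_ORDER) - set(manifest.sensor_files)
    if missing:
        raise ManifestError(f"manifest missing sensors: {sorted(missing)}")

    streams = {
        key: read_sensor_csv(path, agent=key[0], placement=key[1])
        for key, path in manifest.sensor_files.items()
    }
    t0 = max(s.t[0] for s in streams.values())
    t1 = min(s.t[-1] for s in streams.values())
    if t1 < t0:
        raise AlignmentError("sensor streams share no overlapping interval")
    aligned = {}
    for key in SENSOR_ORDER:
        s = streams[key]
        lo = int(np.searchsorted(s.t, t0 - _DT_TOL, side="left"))
        hi = int(np.searchsorted(s.t, t1 + _DT_TOL, side="right"))
        if lo > 0 or hi < len(s):
            logger.info("truncating %s/%s: dropped %d leading, %d trailing samples",
                        key[0], key[1], lo, len(s) - hi)
        aligned[key] = s.slice(lo, hi)
    n = {len(s) for s in aligned.values()}
    if len(n) != 1:
        # off-by-one from float grids; trim to shortest
        m = min(n)
        aligned = {k: s.slice(0, m) for k, s in aligned.items()}
    return manifest, aligned


def save_session(out_dir, manifest: SessionManifest,
                 streams: dict[tuple[str, str], SensorStream],
                 manifest_name: str = "manifest.yaml"):
    """Write manifest + six CSVs under ``out_dir``; returns manifest path."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for (agent, placement), stream in streams.items():
        fname = f"{manifest.subject_id}_v{manifest.visit}_{agent}_{placement}.csv"
        write_sensor_csv(out_dir / fname, stream)
        files[(agent, placement)] = fname
    manifest = replace(manifest, sensor_files=files)
    mpath = out_dir / manifest_name
    write_manifest(mpath, manifest)
    return mpath
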