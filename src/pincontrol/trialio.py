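"""Canonical trial file format and ingestion.

A trial is stored as a CSV (one row per sample: time, per-plate forces and
moments, marker coordinates) plus a JSON sidecar holding metadata, units,
limb roles, support heights, seed, configuration hash and software
version.  CSV floats are written with shortest-round-trip repr, so a
write/read cycle is bit-exact.  C3D ingestion is optional and requires the
``ezc3d`` extra.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .common import Condition, Group, Limb, SchemaError, Side
from .kinematics import MarkerSet
from .kinetics import PlateWrench

SCHEMA_VERSION = 1
_PLATE_COLS = ["Fx", "Fy", "Fz", "Mx", "My", "Mz"]


@dataclass
class TrialRecording:
    """One quiet-standing trial: two plate wrenches, markers, metadata."""

    subject_id: str
    group: Group
    condition: Condition
    fs: float
    duration: float
    left_wrench: PlateWrench
    right_wrench: PlateWrench
    markers: MarkerSet
    limb_roles: dict[Side, Limb]
    support_heights: dict[Side, float] = field(
        default_factory=lambda: {Side.LEFT: 0.0, Side.RIGHT: 0.0}
    )
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.condition = Condition(self.condition)
        self.limb_roles = {Side(k): Limb(v) for k, v in self.limb_roles.items()}
        self.support_heights = {
            Side(k): float(v) for k, v in self.support_heights.items()
        }
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.left_wrench.n_samples
        if self.right_wrench.n_samples != n or self.markers.n_samples != n:
            raise ValueError(
                "plate and marker series must share the sample count"
            )
        roles = set(self.limb_roles.values())
        if roles != {Limb.CONSTRAINED, Limb.UNCONSTRAINED}:
            raise ValueError(
                "limb_roles must assign exactly one side to each of "
                "constrained_prosthetic and unconstrained_intact"
            )

    @property
    def n_samples(self) -> int:
        return self.left_wrench.n_samples

    def wrench(self, side: Side) -> PlateWrench:
        return self.left_wrench if Side(side) is Side.LEFT else self.right_wrench

    def side_of(self, role: Limb) -> Side:
        for side, r in self.limb_roles.items():
            if r is Limb(role):
                return side
        raise KeyError(role)

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


def _config_hash(meta: dict) -> str:
    blob = json.dumps(meta, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_trial(recording: TrialRecording, path) -> Path:
    """Write the canonical CSV + JSON sidecar; returns the CSV path."""
    from . import __version__

    path = Path(path)
    cols: dict[str, np.ndarray] = {"time": recording.time()}
    for side, prefix in ((Side.LEFT, "left"), (Side.RIGHT, "right")):
        w = recording.wrench(side)
        for i, c in enumerate(_PLATE_COLS):
            arr = w.force[:, i] if i < 3 else w.moment[:, i - 3]
            cols[f"{prefix}_{c}"] = arr
    for j, label in enumerate(recording.markers.labels):
        for k, ax in enumerate("xyz"):
            cols[f"{label}_{ax}"] = recording.markers.positions[:, j, k]
    pd.DataFrame(cols).to_csv(path, index=False)

    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "units": {"length": "m", "force": "N", "moment": "N.m", "time": "s"},
        "subject_id": recording.subject_id,
        "group": recording.group.value,
        "condition": recording.condition.value,
        "fs": recording.fs,
        "duration": recording.duration,
        "limb_roles": {s.value: r.value for s, r in recording.limb_roles.items()},
        "support_heights": {
            s.value: h for s, h in recording.support_heights.items()
        },
        "surface_heights": {
            "left": recording.left_wrench.surface_height,
            "right": recording.right_wrench.surface_height,
        },
        "marker_labels": list(recording.markers.labels),
        "software_version": __version__,
        "meta": recording.meta,
    }
    sidecar["config_hash"] = _config_hash(recording.meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trial(path) -> TrialRecording:
    """Read a canonical CSV + sidecar trial, validating the schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise SchemaError(f"missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unrecognized schema_version {sidecar.get('schema_version')!r}"
        )
    units = sidecar.get("units", {})
    expected_units = {"length": "m", "force": "N", "moment": "N.m", "time": "s"}
    for key, val in expected_units.items():
        if units.get(key) != val:
            raise SchemaError(
                f"unit mismatch for {key}: expected {val!r}, got {units.get(key)!r}"
            )

    df = pd.read_csv(path, float_precision="round_trip")
    n = len(df)
    if "time" not in df.columns:
        raise SchemaError("missing column time")

    def col(name: str) -> np.ndarray:
        if name not in df.columns:
            raise SchemaError(f"missing column {name}")
        return df[name].to_numpy(dtype=float)

    wrenches = {}
    for prefix in ("left", "right"):
        data = np.column_stack([col(f"{prefix}_{c}") for c in _PLATE_COLS])
        wrenches[prefix] = PlateWrench(
            force=data[:, :3],
            moment=data[:, 3:],
            surface_height=float(
                sidecar.get("surface_heights", {}).get(prefix, 0.0)
            ),
            fs=float(sidecar["fs"]),
            name=prefix,
        )

    labels = sidecar.get("marker_labels", [])
    if labels:
        pos = np.empty((n, len(labels), 3))
        for j, label in enumerate(labels):
            for k, ax in enumerate("xyz"):
                pos[:, j, k] = col(f"{label}_{ax}")
    else:
        pos = np.empty((n, 0, 3))
    markers = MarkerSet(labels=list(labels), positions=pos,
                        fs=float(sidecar["fs"]))

    return TrialRecording(
        subject_id=sidecar["subject_id"],
        group=sidecar["group"],
        condition=sidecar["condition"],
        fs=float(sidecar["fs"]),
        duration=float(sidecar["duration"]),
        left_wrench=wrenches["left"],
        right_wrench=wrenches["right"],
        markers=markers,
        limb_roles=sidecar["limb_roles"],
        support_heights=sidecar.get(
            "support_heights", {"left": 0.0, "right": 0.0}
        ),
        meta=sidecar.get("meta", {}),
    )


def read_trial_c3d(path, **metadata) -> TrialRecording:
    """Ingest a C3D file with two analog force-plate channel groups.

    Requires the optional ``ezc3d`` dependency.  Analog channels must be
    named ``<prefix><component>`` (e.g. ``Fx1`` .. ``Mz2``); point data
    become the marker set.  Trial metadata (subject_id, group, condition,
    limb_roles, ...) that C3D does not carry is supplied as keyword
    arguments.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "C3D ingestion requires the optional dependency ezc3d "
            "(pip install pincontrol[c3d])"
        ) from exc

    c3d = ezc3d.c3d(str(path))
    point_rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    labels = [
        lab.strip() for lab in c3d["parameters"]["POINT"]["LABELS"]["value"]
    ]
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    positions = np.transpose(pts[:3], (2, 1, 0)).astype(float)

    analog_labels = [
        lab.strip() for lab in c3d["parameters"]["ANALOG"]["LABELS"]["value"]
    ]
    analogs = c3d["data"]["analogs"][0]  # (n_channels, n_analog_frames)
    analog_rate = float(c3d["parameters"]["ANALOG"]["RATE"]["value"][0])
    step = int(round(analog_rate / point_rate))

    def channel(name: str) -> np.ndarray:
        try:
            i = analog_labels.index(name)
        except ValueError:
            raise SchemaError(f"missing analog channel {name}") from None
        return analogs[i, ::step].astype(float)

    wrenches = []
    for plate in (1, 2):
        data = np.column_stack(
            [channel(f"{c}{plate}") for c in _PLATE_COLS]
        )
        wrenches.append(
            PlateWrench(force=data[:, :3], moment=data[:, 3:], fs=point_rate)
        )

    markers = MarkerSet(labels=labels, positions=positions, fs=point_rate)
    n = markers.n_samples
    defaults = {
        "subject_id": "c3d",
        "group": Group.AB_FREE,
        "condition": Condition.EO,
        "limb_roles": {
            Side.LEFT: Limb.CONSTRAINED, Side.RIGHT: Limb.UNCONSTRAINED
        },
    }
    defaults.update(metadata)
    return TrialRecording(
        fs=point_rate,
        duration=n / point_rate,
        left_wrench=wrenches[0],
        right_wrench=wrenches[1],
        markers=markers,
        **defaults,
    )
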