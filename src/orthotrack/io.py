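"""File formats: pose CSV, readings CSV with provenance header, config files.

All angle columns are suffixed ``_deg``; positions are metres. Readings CSVs
carry ``#``-prefixed metadata lines (package version, seed, config hash) so
every output is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import RigidPose
from .simulator import ScenarioConfig

logger = logging.getLogger("orthotrack")

POSE_COLUMNS = ["timestamp", "body_id", "qw", "qx", "qy", "qz", "tx", "ty", "tz"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class PoseRecord:
    """One tracked pose sample: time, body, scalar-first quaternion, metres."""

    timestamp: float
    body_id: str
    qw: float
    qx: float
    qy: float
    qz: float
    tx: float
    ty: float
    tz: float

    def pose(self) -> RigidPose:
        return RigidPose(np.array([self.qw, self.qx, self.qy, self.qz]),
                         np.array([self.tx, self.ty, self.tz]))


def write_pose_csv(records: list[PoseRecord], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=POSE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_pose_csv(path) -> list[PoseRecord]:
    """Read pose samples; quaternions are validated and renormalised.

    A quaternion whose norm deviates from 1 by more than 1e-6 is an error;
    deviations beyond 1e-9 are renormalised with a logged warning.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"cannot parse pose CSV {path}: {exc}") from exc
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"pose CSV {path} missing columns {missing}")
    records = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        q = np.array([row.qw, row.qx, row.qy, row.qz], dtype=float)
        if not np.isfinite(q).all():
            raise ParseError(f"{path}:{line_no}: non-finite quaternion")
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-6:
            raise ParseError(
                f"{path}:{line_no}: quaternion norm {norm:.8f} differs from 1 beyond 1e-6"
            )
        if abs(norm - 1.0) > 1e-9:
            logger.warning("%s:%d: renormalising quaternion (norm %.9f)", path, line_no, norm)
            q = q / norm
        records.append(PoseRecord(
            float(row.timestamp), str(row.body_id), *q,
            float(row.tx), float(row.ty), float(row.tz),
        ))
    return records


def latest_poses(records: list[PoseRecord]) -> dict[str, RigidPose]:
    """Most recent pose per body id."""
    latest: dict[str, PoseRecord] = {}
    for r in records:
        if r.body_id not in latest or r.timestamp >= latest[r.body_id].timestamp:
            latest[r.body_id] = r
    return {bid: r.pose() for bid, r in latest.items()}


# ---------------------------------------------------------------------------
# Landmark recordings (wand points)


def read_points_csv(path) -> dict[str, np.ndarray]:
    """Read named lab-frame points: columns ``name, x, y, z`` (metres)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot parse points CSV {path}: {exc}") from exc
    for c in ("name", "x", "y", "z"):
        if c not in df.columns:
            raise ParseError(f"points CSV {path} missing column {c!r}")
    points = {}
    for i, row in df.iterrows():
        if str(row["name"]) in points:
            raise ParseError(f"{path}:{i + 2}: duplicate point name {row['name']!r}")
        xyz = np.array([row.x, row.y, row.z], dtype=float)
        if not np.isfinite(xyz).all():
            raise ParseError(f"{path}:{i + 2}: non-finite coordinates")
        points[str(row["name"])] = xyz
    return points


# ---------------------------------------------------------------------------
# Readings tables


def config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_readings_csv(df: pd.DataFrame, path, config: ScenarioConfig | None = None) -> None:
    """Write a paired-readings table with a ``#`` provenance header."""
    header = [f"# orthotrack {__version__}"]
    if config is not None:
        header.append(f"# seed={config.seed} config_hash={config_hash(config)}")
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text("\n".join(header) + "\n" + buf.getvalue())


def read_readings_csv(path, required: tuple[str, ...] = ("scenario_id", "replicate")) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise ParseError(f"cannot parse readings CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"readings CSV {path} missing columns {missing}")
    value_cols = [c for c in df.columns if c.endswith("_deg")]
    if not value_cols:
        raise ParseError(f"readings CSV {path} has no *_deg angle columns")
    bad = df[value_cols].isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise ParseError(f"readings CSV {path}: missing value near data row {row + 1}")
    return df


# ---------------------------------------------------------------------------
# Scenario configuration


def load_config(path) -> ScenarioConfig:
    """Load a scenario config from YAML (or JSON, a YAML subset)."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParseError(f"config {path} must be a mapping")
    known = set(ScenarioConfig(seed=0).to_dict())
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"config {path} has unknown keys {sorted(unknown)}")
    try:
        return ScenarioConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"config {path}: {exc}") from exc


def save_config(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
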