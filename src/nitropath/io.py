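"""CSV schemas, configuration loading and run manifests.

Two plain-text schemas carry all reactor data:

* cycle/batch profile — ``time_min,nh4_mgN_L,no2_mgN_L,no3_mgN_L`` plus
  optional ``cod_mg_L`` and ``do_mg_L`` columns (mg/L, '.' decimal, UTF-8);
* daily campaign — ``day,phase,inf_nh4,inf_no2,inf_no3,inf_cod,eff_nh4,
  eff_no2,eff_no3,eff_cod`` with TN derived as NH4+NO2+NO3.

Floats are written with 12 significant digits so a write/read round trip is
lossless well below analytical precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .apportionment import BatchProfile, CycleEndpoints

__all__ = [
    "SchemaError",
    "read_cycle_csv",
    "write_cycle_csv",
    "read_campaign_csv",
    "write_campaign_csv",
    "endpoints_from_profile",
    "load_yaml_config",
    "RunManifest",
    "write_manifest",
]

_FLOAT_FMT = "%.12g"

PROFILE_REQUIRED = ("time_min", "nh4_mgN_L", "no2_mgN_L", "no3_mgN_L")
PROFILE_OPTIONAL = ("cod_mg_L", "do_mg_L")
CAMPAIGN_COLUMNS = (
    "day", "phase",
    "inf_nh4", "inf_no2", "inf_no3", "inf_cod",
    "eff_nh4", "eff_no2", "eff_no3", "eff_cod",
)


class SchemaError(ValueError):
    """A CSV file does not match the expected schema."""


def _numeric(frame: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based plus header line
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at line {row}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax()) + 2
            raise SchemaError(f"{path}: missing value in column {col!r} at line {row}")
        frame[col] = converted
    return frame


def read_cycle_csv(path) -> BatchProfile:
    """Parse a cycle/batch profile CSV into a time-sorted profile."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    frame = pd.read_csv(path)
    missing = [c for c in PROFILE_REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    cols = list(PROFILE_REQUIRED) + [c for c in PROFILE_OPTIONAL if c in frame.columns]
    frame = _numeric(frame, cols, path)
    frame = frame.sort_values("time_min", kind="stable").reset_index(drop=True)
    if frame["time_min"].duplicated().any():
        t = frame.loc[frame["time_min"].duplicated(), "time_min"].iloc[0]
        raise SchemaError(f"{path}: duplicate time point {t} in column 'time_min'")
    return BatchProfile(
        time=frame["time_min"].to_numpy(),
        nh4=frame["nh4_mgN_L"].to_numpy(),
        no2=frame["no2_mgN_L"].to_numpy(),
        no3=frame["no3_mgN_L"].to_numpy(),
        cod=frame["cod_mg_L"].to_numpy() if "cod_mg_L" in frame.columns else None,
    )


def write_cycle_csv(profile, path) -> Path:
    """Write a profile (BatchProfile or schema-conforming DataFrame)."""
    frame = profile.to_frame() if isinstance(profile, BatchProfile) else profile
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_campaign_csv(path) -> pd.DataFrame:
    """Parse a daily campaign CSV; derives influent/effluent TN columns."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    frame = pd.read_csv(path)
    missing = [c for c in CAMPAIGN_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    numeric_cols = [c for c in CAMPAIGN_COLUMNS if c not in ("phase",)]
    frame = _numeric(frame, numeric_cols, path)
    frame["inf_tn"] = frame["inf_nh4"] + frame["inf_no2"] + frame["inf_no3"]
    frame["eff_tn"] = frame["eff_nh4"] + frame["eff_no2"] + frame["eff_no3"]
    return frame


def write_campaign_csv(campaign: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    campaign.loc[:, list(CAMPAIGN_COLUMNS)].to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def endpoints_from_profile(profile: BatchProfile) -> CycleEndpoints:
    """Cycle endpoints = first and last rows of a react-phase profile."""
    return CycleEndpoints(
        nh4_initial=float(profile.nh4[0]),
        no2_initial=float(profile.no2[0]),
        no3_initial=float(profile.no3[0]),
        nh4_final=float(profile.nh4[-1]),
        no2_final=float(profile.no2[-1]),
        no3_final=float(profile.no3[-1]),
    )


def load_yaml_config(path) -> dict:
    """Load a YAML configuration file into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: top-level config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one CLI run: version, config, seeds, digests."""

    tool: str
    version: str
    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""
    notes: dict = field(default_factory=dict)

    def digest(self, role: str, path) -> None:
        store = self.inputs if role == "input" else self.outputs
        p = Path(path)
        store[str(p)] = _sha256(p)


def write_manifest(manifest: RunManifest, path) -> Path:
    """Serialise a manifest as JSON next to the run's primary output."""
    manifest.timestamp = manifest.timestamp or datetime.now(timezone.utc).isoformat()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return asdict(obj)
        return str(obj)

    path.write_text(json.dumps(asdict(manifest), indent=2, default=default) + "\n")
    return path
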