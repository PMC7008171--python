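"""CSV readers/writers and run manifests.

Schemas:

* plasma CSV      — subject_id, route, time_h, conc_ug_L, dose_mg
                    (empty conc_ug_L marks a censored sample)
* dissolution CSV — time_min, pct_dissolved, medium, volume_ml, dose_mg
* validation CSV  — metric, observed, simulated
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .disposition import PlasmaCurve
from .dissolution import DissolutionProfile
from .parameters import ParameterSet, Route, serialize

__all__ = [
    "read_plasma_csv",
    "write_plasma_csv",
    "read_dissolution_csv",
    "write_dissolution_csv",
    "read_validation_csv",
    "RunManifest",
    "write_manifest",
]

log = logging.getLogger("odfpbpk")

PLASMA_COLUMNS = ["subject_id", "route", "time_h", "conc_ug_L", "dose_mg"]
DISSOLUTION_COLUMNS = ["time_min", "pct_dissolved", "medium", "volume_ml", "dose_mg"]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_plasma_csv(path) -> list[PlasmaCurve]:
    """Read plasma curves grouped by (subject_id, route), times sorted.

    Non-monotone input times are sorted with a warning; duplicate
    (subject, route, time) rows are an error naming the offending lines.
    """
    df = pd.read_csv(path)
    _require_columns(df, PLASMA_COLUMNS, path)
    dup = df.duplicated(subset=["subject_id", "route", "time_h"], keep=False)
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{path}: duplicate (subject, route, time) rows at lines {lines}")
    curves = []
    for (subj, route), g in df.groupby(["subject_id", "route"], sort=True):
        if not g["time_h"].is_monotonic_increasing:
            log.warning("%s: times for %s/%s not sorted; sorting", path, subj, route)
            g = g.sort_values("time_h")
        doses = g["dose_mg"].unique()
        if doses.size != 1:
            raise ValueError(f"{path}: inconsistent dose for {subj}/{route}")
        curves.append(PlasmaCurve(
            times=g["time_h"].to_numpy(float),
            concentrations=g["conc_ug_L"].to_numpy(float),
            dose=float(doses[0]), route=Route(route), subject_id=str(subj)))
    return curves


def write_plasma_csv(path, curves: Iterable[PlasmaCurve]) -> None:
    rows = []
    for c in curves:
        for t, y in zip(c.times, c.concentrations):
            rows.append({"subject_id": c.subject_id, "route": c.route.value,
                         "time_h": t, "conc_ug_L": y, "dose_mg": c.dose})
    pd.DataFrame(rows, columns=PLASMA_COLUMNS).to_csv(path, index=False)


def read_dissolution_csv(path) -> list[DissolutionProfile]:
    df = pd.read_csv(path)
    _require_columns(df, DISSOLUTION_COLUMNS, path)
    profiles = []
    for medium, g in df.groupby("medium", sort=True):
        g = g.sort_values("time_min")
        profiles.append(DissolutionProfile(
            times=g["time_min"].to_numpy(float),
            dissolved_fraction=g["pct_dissolved"].to_numpy(float) / 100.0,
            medium_label=str(medium),
            medium_volume=float(g["volume_ml"].iloc[0]),
            initial_dose_mass=float(g["dose_mg"].iloc[0])))
    return profiles


def write_dissolution_csv(path, profiles: Iterable[DissolutionProfile]) -> None:
    rows = []
    for p in profiles:
        for t, f in zip(p.times, p.dissolved_fraction):
            rows.append({"time_min": t, "pct_dissolved": 100.0 * f,
                         "medium": p.medium_label, "volume_ml": p.medium_volume,
                         "dose_mg": p.initial_dose_mass})
    pd.DataFrame(rows, columns=DISSOLUTION_COLUMNS).to_csv(path, index=False)


def read_validation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["metric", "observed", "simulated"], path)
    return df


@dataclasses.dataclass
class RunManifest:
    """Provenance record sufficient to re-execute a run bit-identically."""

    command: str
    parameters: Optional[ParameterSet] = None
    seed: Optional[int] = None
    software_version: str = ""
    timestamp: str = ""

    def to_json(self) -> str:
        from . import __version__

        return json.dumps({
            "command": self.command,
            "parameters": (json.loads(serialize(self.parameters))
                           if self.parameters else None),
            "seed": self.seed,
            "software_version": self.software_version or __version__,
            "timestamp": self.timestamp
            or datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }, indent=2)


def write_manifest(out_path, manifest: RunManifest) -> Path:
    """Write ``manifest.json`` beside the given output path."""
    out_path = Path(out_path)
    target = out_path.parent / "manifest.json"
    target.write_text(manifest.to_json() + "\n", encoding="utf-8")
    return target
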