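"""Tabular I/O, schema validation and run manifests."""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .microdialysis import PROBE_SITES

__all__ = ["read_concentration_csv", "write_concentration_csv", "RunManifest",
           "ParseError"]

REQUIRED_COLUMNS = (
    "animal_id", "species", "drug", "probe_site", "phase",
    "t_start_h", "t_end_h", "conc_mg_L",
)
#: ug/mL is numerically identical to mg/L; accept it as a column alias.
UNIT_ALIASES = {"conc_ug_mL": "conc_mg_L", "c_in_ug_mL": "c_in_mg_L"}
PHASES = ("retrodialysis", "pk")


class ParseError(ValueError):
    """A concentration table violates the documented long-format schema."""


def read_concentration_csv(path) -> pd.DataFrame:
    """Read and validate a long-format dialysate concentration table.

    Columns: animal_id, species, drug, probe_site, phase (retrodialysis or
    pk), t_start_h, t_end_h, conc_mg_L and, for retrodialysis rows,
    c_in_mg_L.  ug/mL column aliases are normalized (1 ug/mL = 1 mg/L).
    Rejects negative concentrations, inverted intervals and overlapping
    intervals within one animal/probe/drug/phase series.
    """
    frame = pd.read_csv(path)
    frame = frame.rename(columns=UNIT_ALIASES)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if "c_in_mg_L" not in frame.columns:
        frame["c_in_mg_L"] = np.nan
    bad_phase = sorted(set(frame["phase"]) - set(PHASES))
    if bad_phase:
        raise ParseError(f"{path}: unknown phase value(s) {bad_phase}")
    bad_site = sorted(set(frame["probe_site"]) - set(PROBE_SITES))
    if bad_site:
        raise ParseError(f"{path}: unknown probe_site value(s) {bad_site}")
    for column in ("t_start_h", "t_end_h", "conc_mg_L"):
        if not np.issubdtype(frame[column].dtype, np.number):
            raise ParseError(f"{path}: column {column} is not numeric")
    if (frame["conc_mg_L"] < 0).any():
        rows = frame.index[frame["conc_mg_L"] < 0].tolist()
        raise ParseError(f"{path}: negative concentration in row(s) {rows}")
    if (frame["t_end_h"] <= frame["t_start_h"]).any():
        rows = frame.index[frame["t_end_h"] <= frame["t_start_h"]].tolist()
        raise ParseError(f"{path}: t_end_h <= t_start_h in row(s) {rows}")
    retro = frame["phase"] == "retrodialysis"
    if retro.any() and frame.loc[retro, "c_in_mg_L"].isna().any():
        rows = frame.index[retro & frame["c_in_mg_L"].isna()].tolist()
        raise ParseError(f"{path}: retrodialysis row(s) {rows} lack c_in_mg_L")
    for key, group in frame.groupby(["animal_id", "probe_site", "drug", "phase"]):
        ordered = group.sort_values("t_start_h")
        overlap = ordered["t_start_h"].values[1:] < ordered["t_end_h"].values[:-1] - 1e-12
        if overlap.any():
            rows = ordered.index[1:][overlap].tolist()
            raise ParseError(
                f"{path}: overlapping collection intervals for {key} in row(s) {rows}"
            )
    return frame


def write_concentration_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


@dataclass
class RunManifest:
    """Record of one CLI run: command, inputs, seed and output checksums."""

    command: str
    arguments: dict
    seed: int | None
    software_version: str
    started_utc: str
    finished_utc: str = ""
    outputs: dict = field(default_factory=dict)   # path -> sha256

    @classmethod
    def start(cls, command: str, arguments: dict, seed: int | None, version: str):
        return cls(command, arguments, seed, version,
                   datetime.now(timezone.utc).isoformat())

    def add_output(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[str(path)] = digest

    def write(self, path) -> None:
        """Atomically write the manifest (all outputs must be registered)."""
        self.finished_utc = datetime.now(timezone.utc).isoformat()
        path = Path(path)
        payload = json.dumps(asdict(self), indent=2)
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as handle:
                handle.write(payload)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
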