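"""Run logs: one record per major loop plus per-particle outcomes.

Serialized as JSONL: a header line carrying the schema tag and run metadata,
then one JSON object per major-loop record (time, raw input, command,
positions). Outcomes round-trip as part of the header-trailer structure so a
saved log replays and re-scores identically.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MajorRecord", "RunLog", "LogSchemaError", "write_log", "read_log", "write_outcomes_csv"]

LOG_SCHEMA = "swarmsteer.runlog/1"

STATUS_NAMES = {0: "active", 1: "exited", 2: "stuck"}


class LogSchemaError(ValueError):
    """Log file schema/version mismatch."""


@dataclass
class MajorRecord:
    t: float
    raw: np.ndarray  # (2,) dimensionless user input
    command: np.ndarray  # (2,) mT/m
    positions: np.ndarray  # (N, 2) m


@dataclass
class RunLog:
    records: list[MajorRecord] = field(default_factory=list)
    outcomes: pd.DataFrame | None = None  # particle, status, exit_outlet, exit_time
    metadata: dict = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        if self.outcomes is not None:
            return len(self.outcomes)
        return len(self.records[0].positions) if self.records else 0

    def raw_input_at(self, major_index: int) -> np.ndarray | None:
        if 0 <= major_index < len(self.records):
            return self.records[major_index].raw
        return None


def write_log(log: RunLog, path) -> None:
    with open(path, "w") as fh:
        header = {"schema": LOG_SCHEMA, "metadata": log.metadata}
        if log.outcomes is not None:
            header["outcomes"] = {
                "status": log.outcomes["status"].tolist(),
                "exit_outlet": [
                    o if isinstance(o, str) else None for o in log.outcomes["exit_outlet"]
                ],
                "exit_time": [
                    None if pd.isna(t) else float(t) for t in log.outcomes["exit_time"]
                ],
            }
        fh.write(json.dumps(header) + "\n")
        for rec in log.records:
            fh.write(
                json.dumps(
                    {
                        "t": rec.t,
                        "raw": np.asarray(rec.raw, float).tolist(),
                        "command": np.asarray(rec.command, float).tolist(),
                        "positions": np.asarray(rec.positions, float).tolist(),
                    }
                )
                + "\n"
            )


def read_log(path) -> RunLog:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise LogSchemaError(f"{path}: empty log file")
    header = json.loads(lines[0])
    if header.get("schema") != LOG_SCHEMA:
        raise LogSchemaError(
            f"{path}: unsupported log schema {header.get('schema')!r}, expected {LOG_SCHEMA!r}"
        )
    records = []
    for line in lines[1:]:
        if not line.strip():
            continue
        d = json.loads(line)
        records.append(
            MajorRecord(
                t=float(d["t"]),
                raw=np.asarray(d["raw"], float),
                command=np.asarray(d["command"], float),
                positions=np.asarray(d["positions"], float),
            )
        )
    outcomes = None
    if "outcomes" in header:
        o = header["outcomes"]
        outcomes = pd.DataFrame(
            {
                "particle": np.arange(len(o["status"])),
                "status": o["status"],
                "exit_outlet": o["exit_outlet"],
                "exit_time": [np.nan if t is None else t for t in o["exit_time"]],
            }
        )
    return RunLog(records, outcomes, header.get("metadata", {}))


def write_outcomes_csv(log: RunLog, path) -> None:
    if log.outcomes is None:
        raise ValueError("log has no outcomes to write")
    log.outcomes.to_csv(path, index=False)
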