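"""Readers and writers for the package's CSV/JSON interchange formats.

Event tables and traces are CSV (tabular, like trap exports and plate
readers); fitted-parameter records are JSON.  Every JSON artifact embeds
the package version and the seed that produced it, so outputs are
traceable.  Schema violations report the offending column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .fitting import ForceBin, GroupSummary, MoleculeFit
from .model import TrapConstants
from .simulate import EVENT_COLUMNS, TrapTrace

TRACE_COLUMNS = ["time_s", "bead_A_nm", "bead_B_nm", "stage_nm"]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {', '.join(missing)}")


def write_events(events: pd.DataFrame, path) -> None:
    _check_columns(events, EVENT_COLUMNS, "event table")
    events.to_csv(path, index=False, float_format="%.12g")


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, EVENT_COLUMNS, f"event table {path}")
    bad = df.index[df["duration_s"] <= 0]
    if len(bad):
        raise SchemaError(f"event table {path}: non-positive duration_s at row {bad[0]}")
    return df


def write_trace(trace: TrapTrace, path) -> None:
    """Trace as CSV plus a JSON sidecar (<path>.json) holding the trap
    constants and, if present, the ground-truth event block."""
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": trace.time,
            "bead_A_nm": trace.bead_A,
            "bead_B_nm": trace.bead_B,
            "stage_nm": trace.stage,
        }
    ).to_csv(path, index=False, float_format="%.12g")
    side = {
        "package_version": __version__,
        "consts": dataclasses.asdict(trace.consts),
    }
    if trace.truth is not None:
        side["truth"] = trace.truth.to_dict(orient="list")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))


def read_trace(path) -> TrapTrace:
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, TRACE_COLUMNS, f"trace {path}")
    sidecar = path.with_suffix(path.suffix + ".json")
    consts = TrapConstants()
    truth = None
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        consts = TrapConstants(**side["consts"])
        if "truth" in side:
            truth = pd.DataFrame(side["truth"])
    return TrapTrace(
        time=df["time_s"].to_numpy(),
        bead_A=df["bead_A_nm"].to_numpy(),
        bead_B=df["bead_B_nm"].to_numpy(),
        stage=df["stage_nm"].to_numpy(),
        consts=consts,
        truth=truth,
    )


def _fit_record(fit: MoleculeFit) -> dict:
    d = dataclasses.asdict(fit)
    d["bins"] = [dataclasses.asdict(b) if not isinstance(b, dict) else b for b in fit.bins]
    return d


def write_fits(
    fits: Sequence[MoleculeFit],
    path,
    summary: Optional[GroupSummary] = None,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    payload = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": None
        if config is None
        else hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16],
        "molecules": [_fit_record(f) for f in fits],
        "summary": None if summary is None else dataclasses.asdict(summary),
    }

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(payload, indent=1, default=default))


def read_fits(path):
    payload = json.loads(Path(path).read_text())
    fits = []
    for rec in payload["molecules"]:
        rec = dict(rec)
        rec["bins"] = [ForceBin(**b) for b in rec["bins"]]
        fits.append(MoleculeFit(**rec))
    summary = payload.get("summary")
    return fits, (GroupSummary(**summary) if summary else None)
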