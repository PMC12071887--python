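"""File round-tripping: trace/trajectory/dataset CSVs, protocol and
parameter-table JSON/YAML, run manifests. Concentrations are stored in nM
internally; other units are converted at parse time and the unit is
always serialized."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .doseresponse import DoseResponseDataset
from .errors import UnitError
from .model import PhenotypeTrajectory, STATE_NAMES
from .params import HillParams
from .protocol import StimulusProtocol
from .trace import Trace

FLOAT_FMT = "%.12g"

_UNIT_TO_NM = {"pM": 1e-3, "nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}


def to_nanomolar(value: float, unit: str) -> float:
    try:
        return float(value) * _UNIT_TO_NM[unit]
    except KeyError:
        raise UnitError(f"unknown concentration unit {unit!r}") from None


# ---------------------------------------------------------------- traces

def write_trace(trace: Trace, path, sidecar=True) -> None:
    path = Path(path)
    trace.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)
    if sidecar and trace.annotations:
        path.with_suffix(".json").write_text(
            json.dumps(trace.annotations, indent=1)
        )


def read_trace(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if "t" not in df.columns:
        raise ValueError(f"{path}: trace CSV needs a 't' column")
    ann = {}
    side = path.with_suffix(".json")
    if side.exists():
        ann = json.loads(side.read_text())
    return Trace.from_frame(df, ann)


# ----------------------------------------------------------- trajectories

def write_trajectory(traj: PhenotypeTrajectory, path) -> None:
    traj.frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trajectory_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("t", *STATE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trajectory CSV missing columns {missing}")
    return df


# -------------------------------------------------------------- protocols

def write_protocol(protocol: StimulusProtocol, path) -> None:
    path = Path(path)
    payload = protocol.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1))


def read_protocol(path) -> StimulusProtocol:
    path = Path(path)
    text = path.read_text()
    data = (
        yaml.safe_load(text)
        if path.suffix in (".yaml", ".yml")
        else json.loads(text)
    )
    events = []
    for e in data.get("events", []):
        conc = to_nanomolar(e.get("conc", 0.0), e.get("unit", "nM"))
        events.append(
            dict(t=float(e["t"]), kind=e["kind"],
                 species=e.get("species", ""), conc=conc)
        )
    return StimulusProtocol(
        events=events,
        t_end=float(data["t_end"]),
        sample_dt=float(data.get("sample_dt", 0.1)),
        name=data.get("name", path.stem),
    )


# --------------------------------------------------------- parameter tables

def write_parameter_table(table: dict, path) -> None:
    payload = {
        name: {
            "k_max": p.k_max, "half_conc": p.half_conc, "h": p.h,
            "mode": p.mode, "unit": p.unit,
        }
        for name, p in table.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_parameter_table(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    table = {}
    for name, d in data.items():
        half = to_nanomolar(d["half_conc"], d.get("unit", "nM"))
        table[name] = HillParams(
            k_max=float(d["k_max"]), half_conc=half, h=float(d["h"]),
            mode=d.get("mode", "activation"), unit="nM",
        )
    return table


# ---------------------------------------------------------------- datasets

def write_dose_response(ds: DoseResponseDataset, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# unit: {ds.unit}; response_kind: {ds.response_kind}\n")
        df = pd.DataFrame({"dose": ds.doses, "response": ds.responses})
        if ds.sd is not None:
            df["sd"] = ds.sd
        if ds.n is not None:
            df["n"] = ds.n
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def read_dose_response(path) -> DoseResponseDataset:
    path = Path(path)
    unit, kind = "nM", "k"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for part in first.lstrip("#").split(";"):
            if ":" in part:
                key, val = (s.strip() for s in part.split(":", 1))
                if key == "unit":
                    unit = val
                elif key == "response_kind":
                    kind = val
    df = pd.read_csv(path, comment="#")
    scale = to_nanomolar(1.0, unit)
    return DoseResponseDataset(
        doses=df["dose"].to_numpy() * scale,
        responses=df["response"].to_numpy(),
        sd=df["sd"].to_numpy() if "sd" in df else None,
        response_kind=kind,
        unit="nM",
    )


# ---------------------------------------------------------------- manifests

def write_manifest(path, command: str, inputs=None, outputs=None,
                   seed=None, parameters=None) -> None:
    from . import __version__

    payload = {
        "command": command,
        "inputs": {k: str(v) for k, v in (inputs or {}).items()},
        "outputs": {k: str(v) for k, v in (outputs or {}).items()},
        "seed": seed,
        "parameters": parameters or {},
        "package_version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, HillParams):
        return obj.__dict__
    return str(obj)
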