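"""File contracts: trace CSVs, trial manifests and report JSON.

CSV dialect: UTF-8, comma-separated, mandatory header row, '.' decimal,
times in seconds as floats. Floats round-trip losslessly (shortest-repr
serialisation).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError
from .simulate import Cohort
from .traces import Trace
from .units import WaterConditions

__all__ = [
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_cohort",
    "write_report",
    "sha256_file",
]

MANIFEST_COLUMNS = [
    "trial_id", "animal_id", "group_psu", "salinity_psu", "temp_C",
    "chamber_volume_L", "animal_mass_g", "trial_type", "start_po2_kpa",
    "trace_file",
]


def write_trace(trace: Trace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "o2_value": trace.o2,
            "o2_unit": trace.unit,
            "phase": trace.phase,
        }
    )
    # %.17g guarantees float64 round-trips exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path, cond: WaterConditions) -> Trace:
    """Read a trace CSV; hard errors name the first offending row."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"time_s", "o2_value", "o2_unit"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"trace {path}: missing columns {sorted(missing)}")
    units = df["o2_unit"].unique()
    if len(units) != 1:
        raise DomainError(f"trace {path}: mixed o2 units {list(units)}")
    time_s = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(time_s) <= 0)
    if bad.size:
        # offending sample is bad[0]+1 (0-based); +2 for header and 1-based rows
        raise DomainError(
            f"trace {path}: time not strictly increasing at row {bad[0] + 3}"
        )
    phase = df["phase"].to_numpy(dtype=object) if "phase" in df.columns else None
    return Trace(
        time_s=time_s,
        o2=df["o2_value"].to_numpy(dtype=float),
        unit=str(units[0]),
        cond=cond,
        phase=phase,
    )


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a trial manifest; checks every trace file exists."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ConfigError(f"manifest {path} is empty")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"manifest {path}: missing columns {sorted(missing)}")
    base = path.parent
    absent = [
        str(row.trial_id)
        for row in df.itertuples()
        if not (base / str(row.trace_file)).exists()
    ]
    if absent:
        raise ConfigError(
            f"manifest {path}: trace files missing for trials {absent}"
        )
    return df


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a simulated cohort in the pipeline's file dialects."""
    outdir = Path(outdir)
    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_csv(outdir / "manifest.csv", index=False)
    cohort.truth.to_csv(outdir / "ground_truth.csv", index=False)
    for row in cohort.manifest.itertuples():
        write_trace(cohort.traces[row.trial_id], outdir / str(row.trace_file))
    write_report(cohort.params, outdir / "sim_params.json")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_report(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
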