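"""Readers and writers for the package's plain-text data dialects.

Every tabular file is a CSV with a ``#``-prefixed metadata header block of
``key=value`` lines above the column header, so each dataset is a single,
diff-able artifact.  Floats are written with shortest round-trip
representation (repr), so read→write→read is lossless.

Schemas
-------
elastic  : q_invA, temperature_K, counts, count_err  (+ run_type, monitor)
reduced  : q_invA, temperature_K, intensity, intensity_err, mask
growth   : time_h, density, condition_nacl_M, condition_phase
events   : event_id, syto9_au, pi_au [, truth_label]
oxygen   : time_min, o2_umol_per_L  (+ cell_count, volume_L)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import EventTable, GrowthCurve, OxygenTrace
from .reduction import ElasticScanSet, ReducedScan

__all__ = [
    "read_table",
    "write_table",
    "read_metadata",
    "to_record",
    "write_records",
]

_SCHEMAS = {
    "elastic": ["q_invA", "temperature_K", "counts", "count_err"],
    "reduced": ["q_invA", "temperature_K", "intensity", "intensity_err", "mask"],
    "growth": ["time_h", "density", "condition_nacl_M", "condition_phase"],
    "events": ["event_id", "syto9_au", "pi_au"],
    "oxygen": ["time_min", "o2_umol_per_L"],
}


def _fmt(x) -> str:
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    return str(x)


def _write_csv(path, metadata: dict, columns: list, rows) -> None:
    lines = [f"# {k}={_fmt(v)}" for k, v in metadata.items()]
    lines.append(",".join(columns))
    for row in rows:
        lines.append(",".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path) -> dict:
    """Parse the '#'-prefixed key=value header block of a dialect CSV."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_frame(path, schema_name: str) -> tuple:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = _SCHEMAS[schema_name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing column(s) {missing} for schema {schema_name!r}"
        )
    return meta, df


def _numeric(df, col, path) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{Path(path).name}: non-numeric value in column {col!r} at row {row}"
        )
    return values.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# per-schema readers
# ---------------------------------------------------------------------------


def _read_elastic(path) -> ElasticScanSet:
    meta, df = _read_frame(path, "elastic")
    q_all = _numeric(df, "q_invA", path)
    t_all = _numeric(df, "temperature_K", path)
    q = np.unique(q_all)
    temps = np.unique(t_all)
    file_q_order = df["q_invA"].drop_duplicates().to_numpy(dtype=float)
    if np.any(np.diff(file_q_order) < 0):
        row = int(np.flatnonzero(np.diff(file_q_order) < 0)[0]) + 1
        raise ValueError(
            f"{Path(path).name}: q values decrease at q block {row} "
            f"(q grid must be strictly increasing)"
        )
    counts = np.full((q.size, temps.size), np.nan)
    errs = np.full((q.size, temps.size), np.nan)
    qi = np.searchsorted(q, q_all)
    ti = np.searchsorted(temps, t_all)
    counts[qi, ti] = _numeric(df, "counts", path)
    errs[qi, ti] = _numeric(df, "count_err", path)
    if np.any(~np.isfinite(counts)):
        raise ValueError(f"{Path(path).name}: incomplete (q, temperature) grid")
    return ElasticScanSet(
        run_type=meta.get("run_type", "sample"),
        q=q,
        temperature=temps,
        counts=counts,
        count_err=errs,
        monitor=float(meta.get("monitor", 1.0)),
    )


def _read_reduced(path) -> ReducedScan:
    meta, df = _read_frame(path, "reduced")
    q_all = _numeric(df, "q_invA", path)
    t_all = _numeric(df, "temperature_K", path)
    q = np.unique(q_all)
    temps = np.unique(t_all)
    inten = np.full((q.size, temps.size), np.nan)
    err = np.full((q.size, temps.size), np.nan)
    mask = np.zeros((q.size, temps.size), dtype=bool)
    qi = np.searchsorted(q, q_all)
    ti = np.searchsorted(temps, t_all)
    inten[qi, ti] = _numeric(df, "intensity", path)
    err[qi, ti] = _numeric(df, "intensity_err", path)
    mask[qi, ti] = _numeric(df, "mask", path).astype(bool)
    provenance = [v for k, v in sorted(meta.items()) if k.startswith("prov.")]
    return ReducedScan(
        q=q,
        temperature=temps,
        intensity=inten,
        intensity_err=err,
        mask=mask,
        provenance=provenance or ["read_table"],
    )


def _read_growth(path) -> GrowthCurve:
    meta, df = _read_frame(path, "growth")
    time = _numeric(df, "time_h", path)
    density = _numeric(df, "density", path)
    if np.any(np.diff(time) <= 0):
        row = int(np.flatnonzero(np.diff(time) <= 0)[0]) + 1
        raise ValueError(
            f"{Path(path).name}: time_h not strictly increasing at row {row}"
        )
    condition = {}
    if df["condition_nacl_M"].notna().any():
        condition["nacl_M"] = float(df["condition_nacl_M"].iloc[0])
    phase = df["condition_phase"].iloc[0]
    if pd.notna(phase):
        condition["phase"] = str(phase)
    for key, value in meta.items():
        if key.startswith("condition."):
            condition[key.split(".", 1)[1]] = value
    return GrowthCurve(time=time, density=density, time_unit="h", condition=condition)


def _read_events(path) -> EventTable:
    _, df = _read_frame(path, "events")
    syto = _numeric(df, "syto9_au", path)
    pi = _numeric(df, "pi_au", path)
    for name, arr in (("syto9_au", syto), ("pi_au", pi)):
        if np.any(arr <= 0):
            event = int(df["event_id"].iloc[int(np.argmax(arr <= 0))])
            raise ValueError(
                f"{Path(path).name}: non-positive {name} at event {event}"
            )
    truth = None
    if "truth_label" in df.columns:
        truth = df["truth_label"].to_numpy()
    return EventTable(syto9=syto, pi=pi, truth_label=truth)


def _read_oxygen(path) -> OxygenTrace:
    meta, df = _read_frame(path, "oxygen")
    return OxygenTrace(
        time=_numeric(df, "time_min", path),
        o2=_numeric(df, "o2_umol_per_L", path),
        cell_count=float(meta.get("cell_count", 1e8)),
        volume=float(meta.get("volume_L", 1.0)),
    )


_READERS = {
    "elastic": _read_elastic,
    "reduced": _read_reduced,
    "growth": _read_growth,
    "events": _read_events,
    "oxygen": _read_oxygen,
}


def read_table(path, schema_name: str):
    """Read a dialect CSV into its domain type, enforcing invariants.

    ``schema_name`` is one of {elastic, reduced, growth, events, oxygen}.
    Violations raise ValueError naming the offending column or row.
    """
    if schema_name not in _READERS:
        raise ValueError(
            f"unknown schema {schema_name!r}; choose from {sorted(_READERS)}"
        )
    return _READERS[schema_name](path)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_elastic(scan: ElasticScanSet, path) -> None:
    meta = {"schema": "elastic", "run_type": scan.run_type, "monitor": scan.monitor}
    for i, step in enumerate(scan.provenance):
        meta[f"prov.{i}"] = step
    rows = [
        (scan.q[i], scan.temperature[j], scan.counts[i, j], scan.count_err[i, j])
        for i in range(scan.n_q)
        for j in range(scan.n_temperature)
    ]
    _write_csv(path, meta, _SCHEMAS["elastic"], rows)


def _write_reduced(scan: ReducedScan, path) -> None:
    meta = {"schema": "reduced"}
    for i, step in enumerate(scan.provenance):
        meta[f"prov.{i}"] = step
    rows = [
        (
            scan.q[i],
            scan.temperature[j],
            scan.intensity[i, j],
            scan.intensity_err[i, j],
            int(scan.mask[i, j]),
        )
        for i in range(scan.n_q)
        for j in range(scan.n_temperature)
    ]
    _write_csv(path, meta, _SCHEMAS["reduced"], rows)


def _write_growth(curve: GrowthCurve, path) -> None:
    meta = {"schema": "growth", "time_unit": "h"}
    for key, value in curve.condition.items():
        if key not in ("nacl_M", "phase"):
            meta[f"condition.{key}"] = value
    nacl = curve.condition.get("nacl_M", "")
    phase = curve.condition.get("phase", "")
    t = curve.time_in("h")
    rows = [(t[i], curve.density[i], nacl, phase) for i in range(len(curve))]
    _write_csv(path, meta, _SCHEMAS["growth"], rows)


def _write_events(events: EventTable, path) -> None:
    meta = {"schema": "events"}
    columns = list(_SCHEMAS["events"])
    has_truth = events.truth_label is not None
    if has_truth:
        columns.append("truth_label")
    rows = []
    for i in range(len(events)):
        row = [i, events.syto9[i], events.pi[i]]
        if has_truth:
            row.append(events.truth_label[i])
        rows.append(row)
    _write_csv(path, meta, columns, rows)


def _write_oxygen(trace: OxygenTrace, path) -> None:
    meta = {
        "schema": "oxygen",
        "cell_count": trace.cell_count,
        "volume_L": trace.volume,
    }
    rows = [(trace.time[i], trace.o2[i]) for i in range(len(trace))]
    _write_csv(path, meta, _SCHEMAS["oxygen"], rows)


_WRITERS = {
    ElasticScanSet: _write_elastic,
    ReducedScan: _write_reduced,
    GrowthCurve: _write_growth,
    EventTable: _write_events,
    OxygenTrace: _write_oxygen,
}


def write_table(obj, path) -> None:
    """Write a domain object to its dialect CSV (dispatch on type)."""
    for cls, writer in _WRITERS.items():
        if isinstance(obj, cls):
            writer(obj, path)
            return
    raise TypeError(f"no writer for objects of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# JSON result records
# ---------------------------------------------------------------------------


def to_record(obj):
    """Convert a results dataclass (possibly holding numpy arrays) to plain
    JSON-serializable python structures."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_record(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return to_record(obj.tolist())
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return v if np.isfinite(v) else None  # NaN/inf -> null for valid JSON
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): to_record(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_record(v) for v in obj]
    return obj


def write_records(records: dict, path) -> None:
    """Write a dict of result records as deterministic, sorted-key JSON."""
    Path(path).write_text(
        json.dumps(to_record(records), indent=2, sort_keys=True, allow_nan=False) + "\n"
    )
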