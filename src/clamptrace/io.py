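"""CSV/YAML readers and writers for clamp study datasets.

Layout
------
* Subject table: one CSV with columns
  ``id, group, weight_kg, height_cm, vat_kg, sat_kg, muscle_kg``
  (the three mass covariates optional; empty cell = missing).
* Time series: one CSV per subject with columns
  ``t_min, glucose_mmol_l, insulin_pmol_l, nefa_mmol_l, glucose_ttr,
  glycerol_umol_l, glycerol_ttr, gir_mg_kg_min``.
  One row per time; any measurement cell may be empty (missing sample).
  Non-empty ``gir_mg_kg_min`` cells record pump-rate changes: the rate is
  held constant until the next recorded change (step function).
* Protocol: YAML mapping of :class:`~clamptrace.core.ClampProtocol` fields;
  a defaults file ships with the package.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .core import (
    CHANNELS,
    ClampProtocol,
    GIRProfile,
    Group,
    SampleSeries,
    Subject,
)

__all__ = [
    "LoadError",
    "read_protocol",
    "write_protocol",
    "read_subject_table",
    "write_subject_table",
    "read_series",
    "write_series",
    "load_subject_dataset",
]

SERIES_COLUMNS = ("t_min",) + CHANNELS + ("gir_mg_kg_min",)
SUBJECT_COLUMNS = ("id", "group", "weight_kg", "height_cm", "vat_kg", "sat_kg", "muscle_kg")


class LoadError(ValueError):
    """Structured load failure naming the offending file/row."""

    def __init__(self, message: str, path: str | Path | None = None, row: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f", row {row}]" if row is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.row = row


# -- protocol ---------------------------------------------------------------

def read_protocol(path: str | Path | None = None) -> ClampProtocol:
    """Read a protocol YAML; with no path, the packaged defaults."""
    if path is None:
        text = resources.files("clamptrace.data").joinpath("default_protocol.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    known = {f.name for f in dataclasses.fields(ClampProtocol)}
    unknown = set(raw) - known
    if unknown:
        raise LoadError(f"unknown protocol keys: {sorted(unknown)}", path)
    for key in ("basal_window", "low_window", "high_window"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    return ClampProtocol(**raw)


def write_protocol(protocol: ClampProtocol, path: str | Path) -> None:
    d = dataclasses.asdict(protocol)
    for key in ("basal_window", "low_window", "high_window"):
        d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# -- subject table ----------------------------------------------------------

def read_subject_table(path: str | Path) -> list[Subject]:
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    unknown = set(df.columns) - set(SUBJECT_COLUMNS)
    if unknown:
        raise LoadError(f"unknown subject columns: {sorted(unknown)}", path)
    missing = {"id", "group", "weight_kg", "height_cm"} - set(df.columns)
    if missing:
        raise LoadError(f"missing required subject columns: {sorted(missing)}", path)
    subjects = []
    for i, row in df.iterrows():
        try:
            subjects.append(
                Subject(
                    id=str(row["id"]),
                    group=Group(row["group"]),
                    weight_kg=float(row["weight_kg"]),
                    height_cm=float(row["height_cm"]),
                    vat_kg=_opt(row.get("vat_kg")),
                    sat_kg=_opt(row.get("sat_kg")),
                    muscle_kg=_opt(row.get("muscle_kg")),
                )
            )
        except (ValueError, KeyError) as exc:
            raise LoadError(str(exc), path, row=int(i) + 2) from exc
    return subjects


def write_subject_table(subjects: Iterable[Subject], path: str | Path) -> None:
    rows = [
        {
            "id": s.id,
            "group": s.group.value,
            "weight_kg": s.weight_kg,
            "height_cm": s.height_cm,
            "vat_kg": s.vat_kg,
            "sat_kg": s.sat_kg,
            "muscle_kg": s.muscle_kg,
        }
        for s in subjects
    ]
    pd.DataFrame(rows, columns=SUBJECT_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    return float(value)


# -- time series ------------------------------------------------------------

def read_series(path: str | Path) -> SampleSeries:
    """Read one subject's clamp time series CSV.

    Raises :class:`LoadError` (naming the row) for unknown columns,
    non-monotone/duplicate times, or negative concentrations.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    unknown = set(df.columns) - set(SERIES_COLUMNS)
    if unknown:
        raise LoadError(f"unknown series columns: {sorted(unknown)}", path)
    if "t_min" not in df.columns:
        raise LoadError("missing t_min column", path)
    t = df["t_min"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        bad = int(np.flatnonzero(~np.isfinite(t))[0])
        raise LoadError("missing/invalid sample time", path, row=bad + 2)
    d = np.diff(t)
    if np.any(d <= 0):
        bad = int(np.flatnonzero(d <= 0)[0]) + 1
        kind = "duplicate" if d[bad - 1] == 0 else "non-monotone"
        raise LoadError(f"{kind} sample time t={t[bad]}", path, row=bad + 2)
    channels = {}
    for name in CHANNELS:
        col = df[name].to_numpy(dtype=float) if name in df.columns else np.full_like(t, np.nan)
        neg = np.isfinite(col) & (col < 0)
        if np.any(neg):
            bad = int(np.flatnonzero(neg)[0])
            raise LoadError(f"negative value in {name}: {col[bad]}", path, row=bad + 2)
        channels[name] = col
    if "gir_mg_kg_min" in df.columns:
        g = df["gir_mg_kg_min"].to_numpy(dtype=float)
        ok = np.isfinite(g)
        gir = GIRProfile(t[ok], g[ok])
    else:
        gir = GIRProfile([], [])
    return SampleSeries(t_min=t, gir=gir, **channels)


def write_series(series: SampleSeries, path: str | Path) -> None:
    """Write the series CSV; exact inverse of :func:`read_series`."""
    t = series.t_min
    gir_col = np.full_like(t, np.nan)
    if len(series.gir):
        # pump-change times must appear as rows; merge if absent
        extra = np.setdiff1d(series.gir.times, t)
        if extra.size:
            t = np.sort(np.concatenate([t, extra]))
        gir_col = np.full_like(t, np.nan)
        idx = np.searchsorted(t, series.gir.times)
        gir_col[idx] = series.gir.rates
    data = {"t_min": t}
    for name in CHANNELS:
        y = getattr(series, name)
        if t.size != series.t_min.size:
            col = np.full_like(t, np.nan)
            col[np.searchsorted(t, series.t_min)] = y
            data[name] = col
        else:
            data[name] = y
    data["gir_mg_kg_min"] = gir_col
    # %.17g guarantees bit-exact float round trips
    pd.DataFrame(data, columns=SERIES_COLUMNS).to_csv(path, index=False, float_format="%.17g")


# -- dataset ----------------------------------------------------------------

def load_subject_dataset(
    subjects_csv: str | Path,
    series_dir: str | Path,
    protocol: ClampProtocol | None = None,
) -> list[tuple[Subject, SampleSeries]]:
    """Load a whole study: subject table + one series CSV per subject id.

    Series files are looked up as ``<series_dir>/<id>.csv``. Returns
    validated (Subject, SampleSeries) pairs in subject-table order.
    """
    subjects = read_subject_table(subjects_csv)
    series_dir = Path(series_dir)
    out = []
    for s in subjects:
        f = series_dir / f"{s.id}.csv"
        if not f.exists():
            raise LoadError(f"no series file for subject {s.id}", f)
        out.append((s, read_series(f)))
    return out
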