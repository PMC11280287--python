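"""CSV/YAML readers and writers for every pipeline input.

All CSVs are comma-separated UTF-8 with a mandatory header row; the header
names carry the units so no reader ever converts anything. Reader∘writer
round trips are lossless at full float precision (writers use repr-style
formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    DispositionRecord,
    FranzCellConfig,
    IntegrityRecord,
    PoreSet,
    ReceptorSeries,
    RheoSweep,
    validate_config,
)
from .errors import SchemaError, ValidationError

__all__ = [
    "read_receptor_csv",
    "write_receptor_csv",
    "read_pores_csv",
    "write_pores_csv",
    "read_integrity_csv",
    "write_integrity_csv",
    "read_disposition_csv",
    "write_disposition_csv",
    "read_rheology_csv",
    "write_rheology_csv",
    "load_config",
    "dump_config",
]

RECEPTOR_COLUMNS = ("replicate", "time_h", "conc_ug_per_ml")
PORES_COLUMNS = ("group", "pore_id", "area_um2", "depth_um", "spacing_um", "intensity")
INTEGRITY_COLUMNS = ("group", "replicate", "vs_mv", "tewl_g_m2h")
DISPOSITION_COLUMNS = ("group", "replicate", "epidermis_ug_cm2", "dermis_ug_cm2", "q24_ug_cm2")
RHEOLOGY_COLUMNS = ("kind", "x", "g_prime_pa", "g_double_prime_pa")

_CONFIG_KEYS = {
    "receptor_volume",
    "sample_volume",
    "permeation_area",
    "donor_concentration",
    "skin_thickness",
    "clearance",
    "donor_dose",
    "donor_volume",
    "fixed_voltage",
    "load_resistance",
}


def _read_table(path, required, numeric, optional_numeric=()):
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SchemaError(f"{path}: could not parse CSV: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    for col in numeric + tuple(c for c in optional_numeric if c in df.columns):
        # pandas' fast CSV float path can be off by 1 ulp; parse with the
        # exact Python parser so writer/reader round trips are lossless
        converted = pd.to_numeric(df[col], errors="coerce")
        strict = col in numeric
        bad = converted.isna() & df[col].notna() if not strict else converted.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise SchemaError(f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = df[col].map(lambda s: float(s) if isinstance(s, str) else np.nan)
    return df


def read_receptor_csv(path) -> list[ReceptorSeries]:
    """Read receptor.csv (replicate,time_h,conc_ug_per_ml) into per-replicate series.

    Times are sorted ascending within each replicate; duplicate
    (replicate, time) rows are rejected.
    """
    df = _read_table(path, RECEPTOR_COLUMNS, ("time_h", "conc_ug_per_ml"))
    series = []
    for rep, sub in df.groupby("replicate", sort=True):
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy()
        if np.any(np.diff(times) == 0):
            raise ValidationError(f"{path}: duplicate sampling time for replicate {rep!r}")
        series.append(
            ReceptorSeries(
                replicate_id=str(rep),
                times=times,
                concentrations=sub["conc_ug_per_ml"].to_numpy(),
            )
        )
    if not series:
        raise ValidationError(f"{path}: no data rows")
    return series


def write_receptor_csv(path, series: list[ReceptorSeries]) -> None:
    rows = [
        {"replicate": s.replicate_id, "time_h": t, "conc_ug_per_ml": c}
        for s in series
        for t, c in zip(s.times, s.concentrations)
    ]
    _write_rows(path, rows, RECEPTOR_COLUMNS)


def read_pores_csv(path) -> list[PoreSet]:
    """Read pores.csv into one :class:`PoreSet` per group.

    depth/spacing/intensity cells may be empty (pore not measured for that
    metric); area is mandatory per pore.
    """
    df = _read_table(
        path,
        ("group", "pore_id", "area_um2"),
        ("area_um2",),
        optional_numeric=("depth_um", "spacing_um", "intensity"),
    )
    for col in ("depth_um", "spacing_um", "intensity"):
        if col not in df.columns:
            df[col] = np.nan
        else:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    out = []
    for group, sub in df.groupby("group", sort=True):
        out.append(PoreSet(group=str(group), records=sub.reset_index(drop=True)))
    if not out:
        raise ValidationError(f"{path}: no data rows")
    return out


def write_pores_csv(path, pore_sets: list[PoreSet]) -> None:
    rows = []
    for ps in pore_sets:
        for i, rec in ps.records.iterrows():
            rows.append(
                {
                    "group": ps.group,
                    "pore_id": rec.get("pore_id", i + 1),
                    "area_um2": rec["area_um2"],
                    "depth_um": rec["depth_um"],
                    "spacing_um": rec["spacing_um"],
                    "intensity": rec["intensity"],
                }
            )
    _write_rows(path, rows, PORES_COLUMNS)


def read_integrity_csv(path) -> list[IntegrityRecord]:
    df = _read_table(path, INTEGRITY_COLUMNS, ("vs_mv", "tewl_g_m2h"))
    return [
        IntegrityRecord(
            group=str(r["group"]),
            replicate_id=str(r["replicate"]),
            vs_mv=float(r["vs_mv"]),
            tewl=float(r["tewl_g_m2h"]),
        )
        for _, r in df.iterrows()
    ]


def write_integrity_csv(path, records: list[IntegrityRecord]) -> None:
    rows = [
        {
            "group": r.group,
            "replicate": r.replicate_id,
            "vs_mv": r.vs_mv,
            "tewl_g_m2h": r.tewl,
        }
        for r in records
    ]
    _write_rows(path, rows, INTEGRITY_COLUMNS)


def read_disposition_csv(path) -> list[DispositionRecord]:
    df = _read_table(
        path, DISPOSITION_COLUMNS, ("epidermis_ug_cm2", "dermis_ug_cm2", "q24_ug_cm2")
    )
    return [
        DispositionRecord(
            group=str(r["group"]),
            replicate_id=str(r["replicate"]),
            epidermis=float(r["epidermis_ug_cm2"]),
            dermis=float(r["dermis_ug_cm2"]),
            q24=float(r["q24_ug_cm2"]),
        )
        for _, r in df.iterrows()
    ]


def write_disposition_csv(path, records: list[DispositionRecord]) -> None:
    rows = [
        {
            "group": r.group,
            "replicate": r.replicate_id,
            "epidermis_ug_cm2": r.epidermis,
            "dermis_ug_cm2": r.dermis,
            "q24_ug_cm2": r.q24,
        }
        for r in records
    ]
    _write_rows(path, rows, DISPOSITION_COLUMNS)


def read_rheology_csv(path) -> list[RheoSweep]:
    df = _read_table(path, RHEOLOGY_COLUMNS, ("x", "g_prime_pa", "g_double_prime_pa"))
    sweeps = []
    for kind, sub in df.groupby("kind", sort=True):
        sub = sub.sort_values("x")
        sweeps.append(
            RheoSweep(
                kind=str(kind),
                x=sub["x"].to_numpy(),
                g_prime=sub["g_prime_pa"].to_numpy(),
                g_double_prime=sub["g_double_prime_pa"].to_numpy(),
            )
        )
    if not sweeps:
        raise ValidationError(f"{path}: no data rows")
    return sweeps


def write_rheology_csv(path, sweeps: list[RheoSweep]) -> None:
    rows = [
        {"kind": s.kind, "x": x, "g_prime_pa": gp, "g_double_prime_pa": gpp}
        for s in sweeps
        for x, gp, gpp in zip(s.x, s.g_prime, s.g_double_prime)
    ]
    _write_rows(path, rows, RHEOLOGY_COLUMNS)


def load_config(path) -> FranzCellConfig:
    """Load a Franz-cell config from YAML or JSON and validate it."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        cfg = FranzCellConfig(**raw)
    except TypeError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    return validate_config(cfg)


def dump_config(path, cfg: FranzCellConfig) -> None:
    data = {
        k: getattr(cfg, k)
        for k in sorted(_CONFIG_KEYS)
        if getattr(cfg, k) is not None
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _fmt(value):
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return ""
        return repr(float(value))
    return str(value)


def _write_rows(path, rows, columns) -> None:
    lines = [",".join(columns)]
    for row in rows:
        lines.append(",".join(_fmt(row[c]) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")
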