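"""Domain types shared by every stage of the IVPT pipeline.

Units are fixed at this boundary and never converted silently downstream:
times in hours, volumes in mL, amounts in µg, lengths in cm (skin) or µm
(pores), areas in sq·cm (cell) or sq·µm (pores), voltages in mV,
resistances in kΩ, TEWL in g/m²h, moduli in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "FranzCellConfig",
    "ReceptorSeries",
    "PermeationProfile",
    "SteadyStateFit",
    "TransportParams",
    "PoreSet",
    "IntegrityRecord",
    "DispositionRecord",
    "RheoSweep",
    "validate_config",
]

#: Fixed circuit voltage of the skin-resistance measurement circuit (mV).
DEFAULT_FIXED_VOLTAGE_MV = 100.0
#: Load resistance of the skin-resistance measurement circuit (kΩ).
DEFAULT_LOAD_RESISTANCE_KOHM = 100.0

RHEO_KINDS = ("amplitude", "frequency", "thixotropy")


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class FranzCellConfig:
    """Physical constants of one Franz diffusion-cell experiment.

    Parameters
    ----------
    receptor_volume : float
        Receptor chamber volume V (mL).
    sample_volume : float
        Withdrawn-and-replaced aliquot volume Vi (mL).
    permeation_area : float
        Effective skin permeation area A (sq·cm).
    donor_concentration : float
        Drug concentration in the donor vehicle C (µg/mL).
    skin_thickness : float
        Membrane (dermatomed skin) thickness h (cm).
    clearance : float
        Systemic drug clearance Cl (mL/h), used for the plasma-level
        extrapolation.
    donor_dose : float, optional
        Total drug amount loaded in the donor chamber (µg).
    donor_volume : float, optional
        Applied donor volume (mL); when given together with
        ``donor_dose`` the two are cross-checked against
        ``donor_concentration`` to 1%.
    fixed_voltage : float
        Source voltage Vo of the resistance circuit (mV).
    load_resistance : float
        Load resistance RL of the resistance circuit (kΩ).
    """

    receptor_volume: float
    sample_volume: float
    permeation_area: float
    donor_concentration: float
    skin_thickness: float
    clearance: float
    donor_dose: float | None = None
    donor_volume: float | None = None
    fixed_voltage: float = DEFAULT_FIXED_VOLTAGE_MV
    load_resistance: float = DEFAULT_LOAD_RESISTANCE_KOHM


def validate_config(cfg: FranzCellConfig) -> FranzCellConfig:
    """Apply circuit defaults and check every config invariant.

    Returns the (possibly completed) config; raises
    :class:`~ivpt.errors.ValidationError` naming the offending field.
    """
    updates = {}
    if cfg.fixed_voltage is None:
        updates["fixed_voltage"] = DEFAULT_FIXED_VOLTAGE_MV
    if cfg.load_resistance is None:
        updates["load_resistance"] = DEFAULT_LOAD_RESISTANCE_KOHM
    if updates:
        cfg = replace(cfg, **updates)

    required = (
        "receptor_volume",
        "sample_volume",
        "permeation_area",
        "donor_concentration",
        "skin_thickness",
        "clearance",
        "fixed_voltage",
        "load_resistance",
    )
    for name in required:
        value = getattr(cfg, name)
        if value is None or not np.isfinite(value) or value <= 0:
            raise ValidationError(f"{name} must be strictly positive, got {value!r}")
    for name in ("donor_dose", "donor_volume"):
        value = getattr(cfg, name)
        if value is not None and (not np.isfinite(value) or value <= 0):
            raise ValidationError(f"{name} must be strictly positive, got {value!r}")

    if cfg.sample_volume >= cfg.receptor_volume:
        raise ValidationError("sample volume exceeds receptor volume")

    if cfg.donor_dose is not None and cfg.donor_volume is not None:
        implied = cfg.donor_concentration * cfg.donor_volume
        if abs(cfg.donor_dose - implied) > 0.01 * implied:
            raise ValidationError(
                f"donor_dose {cfg.donor_dose} µg inconsistent with "
                f"donor_concentration × donor_volume = {implied} µg (>1%)"
            )
    return cfg


@dataclass(frozen=True)
class ReceptorSeries:
    """Receptor-chamber concentrations of one replicate over time.

    ``times`` (h) are strictly increasing; a 0 h sample is allowed and
    carried (the sampling schedule starts at 0 h). Concentrations are in
    µg/mL and must be non-negative.
    """

    replicate_id: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.times, "times")
        c = _as_float_array(self.concentrations, "concentrations")
        if len(t) != len(c):
            raise ValidationError(
                f"replicate {self.replicate_id!r}: times and concentrations differ in length"
            )
        if len(t) == 0:
            raise ValidationError(f"replicate {self.replicate_id!r}: empty series")
        if np.any(t < 0):
            raise ValidationError(f"replicate {self.replicate_id!r}: negative time")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"replicate {self.replicate_id!r}: times must be strictly increasing"
            )
        if np.any(c < 0):
            raise ValidationError(f"replicate {self.replicate_id!r}: negative concentration")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PermeationProfile:
    """Cumulative permeated amount per unit area Q (µg/sq·cm) vs time (h).

    Q is not forced to be non-decreasing: assay noise may produce local
    dips, and the steady-state fit must see them.
    """

    times: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        t = _as_float_array(self.times, "times")
        q = _as_float_array(self.q, "q")
        if len(t) != len(q):
            raise ValidationError("times and q differ in length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "q", q)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SteadyStateFit:
    """Selected terminal linear segment of a permeation profile.

    ``slope`` is the steady-state flux per area J (µg/sq·cm/h);
    ``lag_time`` is the x-intercept −intercept/slope clamped to ≥ 0, with
    the unclamped value kept in ``lag_time_raw`` (a negative raw lag is
    possible with noise and is flagged rather than hidden).
    """

    segment_start_index: int
    segment_end_index: int
    slope: float
    intercept: float
    r_squared: float
    lag_time: float
    lag_time_raw: float

    @property
    def lag_is_negative(self) -> bool:
        return self.lag_time_raw < 0

    @property
    def n_points(self) -> int:
        return self.segment_end_index - self.segment_start_index + 1


@dataclass(frozen=True)
class TransportParams:
    """Derived transport parameters of one replicate (or one group mean).

    kp : permeability coefficient (cm/h); d : diffusion coefficient
    (sq·cm/h); css : predicted steady-state plasma concentration (µg/L);
    n_dense : channels per sq·cm under dense packing; j_dense : flux of the
    densely packed 1 sq·cm area (µg/sq·cm/h); required_area : array area
    (sq·cm) needed to reach a target plasma level.
    """

    kp: float
    d: float | None = None
    css: float | None = None
    n_dense: int | None = None
    j_dense: float | None = None
    required_area: float | None = None


@dataclass(frozen=True)
class PoreSet:
    """Per-pore microchannel measurements for one treatment group.

    ``records`` columns: ``area_um2``, ``depth_um``, ``spacing_um``,
    ``intensity`` (PPI, arbitrary units). depth/spacing/intensity may be
    NaN (not measured for that pore) and are excluded listwise per metric.
    ``n_expected`` is the needle count on the array; fewer records than
    expected is allowed (missed pores).
    """

    group: str
    records: pd.DataFrame
    n_expected: int | None = None

    _COLUMNS = ("area_um2", "depth_um", "spacing_um", "intensity")

    def __post_init__(self):
        df = pd.DataFrame(self.records).copy()
        for col in self._COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        for col in ("area_um2", "depth_um", "spacing_um"):
            bad = df[col].dropna() <= 0
            if bad.any():
                raise ValidationError(f"group {self.group!r}: non-positive {col}")
        if (df["intensity"].dropna() < 0).any():
            raise ValidationError(f"group {self.group!r}: negative intensity")
        if self.n_expected is not None and self.n_expected < 1:
            raise ValidationError("n_expected must be >= 1")
        object.__setattr__(self, "records", df)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def areas(self) -> np.ndarray:
        return self.records["area_um2"].dropna().to_numpy()

    @property
    def depths(self) -> np.ndarray:
        return self.records["depth_um"].dropna().to_numpy()

    @property
    def spacings(self) -> np.ndarray:
        return self.records["spacing_um"].dropna().to_numpy()

    @property
    def intensities(self) -> np.ndarray:
        return self.records["intensity"].dropna().to_numpy()


@dataclass(frozen=True)
class IntegrityRecord:
    """One skin-integrity measurement: voltage drop (mV) and TEWL (g/m²h)."""

    group: str
    replicate_id: str
    vs_mv: float
    tewl: float

    def __post_init__(self):
        if self.vs_mv < 0:
            raise ValidationError("voltage drop must be non-negative")
        if self.tewl <= 0:
            raise ValidationError("tewl must be positive")


@dataclass(frozen=True)
class DispositionRecord:
    """Per-replicate skin disposition (µg/sq·cm): epidermis, dermis, Q24."""

    group: str
    replicate_id: str
    epidermis: float
    dermis: float
    q24: float

    def __post_init__(self):
        for name in ("epidermis", "dermis", "q24"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    @property
    def qs(self) -> float:
        """Total skin deposition Qs = epidermis + dermis (µg/sq·cm)."""
        return self.epidermis + self.dermis


@dataclass(frozen=True)
class RheoSweep:
    """One oscillatory rheometry sweep.

    ``kind`` is 'amplitude' (x = strain %), 'frequency' (x = angular
    frequency rad/s) or 'thixotropy' (x = time s). x strictly increasing,
    moduli positive (Pa).
    """

    kind: str
    x: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray

    def __post_init__(self):
        if self.kind not in RHEO_KINDS:
            raise ValidationError(f"unknown sweep kind {self.kind!r}; expected one of {RHEO_KINDS}")
        x = _as_float_array(self.x, "x")
        gp = _as_float_array(self.g_prime, "g_prime")
        gpp = _as_float_array(self.g_double_prime, "g_double_prime")
        if not (len(x) == len(gp) == len(gpp)):
            raise ValidationError("sweep columns differ in length")
        if np.any(np.diff(x) <= 0):
            raise ValidationError("sweep x must be strictly increasing")
        if np.any(gp <= 0) or np.any(gpp <= 0):
            raise ValidationError("moduli must be positive")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "g_prime", gp)
        object.__setattr__(self, "g_double_prime", gpp)

    def __len__(self) -> int:
        return len(self.x)
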