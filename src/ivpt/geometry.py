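"""Descriptive and derived statistics of microneedle-created skin pores.

All pore dimensions arrive as measurements (SEM / confocal / pore-uniformity
outputs); this module never touches images. Areas are in sq·µm, depths and
spacings in µm, the Pore Permeability Index (PPI) in arbitrary units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import PoreSet
from .errors import ValidationError
from .integrity import two_sample_ttest
from .permeation import UM2_PER_CM2

__all__ = [
    "GeometrySummary",
    "area_fractions",
    "penetration_efficiency",
    "depth_fraction",
    "uniformity_summary",
    "compare_spacing",
    "summarize_pores",
]


@dataclass(frozen=True)
class GeometrySummary:
    """Per-group pore geometry summary.

    Means/SDs of area, depth, spacing and intensity (NaN when the metric
    was not measured); total channel area of the array (sq·cm); pore area
    as % of the needle base area and of the skin permeation area.
    """

    group: str
    n_pores: int
    mean_area_um2: float
    sd_area_um2: float
    mean_depth_um: float
    sd_depth_um: float
    mean_spacing_um: float
    sd_spacing_um: float
    mean_intensity: float
    sd_intensity: float
    n_zero_intensity: int
    total_channel_area_cm2: float | None = None
    fraction_of_base_area: float | None = None
    fraction_of_permeation_area: float | None = None
    depth_fraction_of_length: float | None = None
    penetration_efficiency: float | None = None


def area_fractions(
    pores: PoreSet,
    base_side_um: float,
    permeation_area_cm2: float,
    n_channels: int,
) -> dict:
    """Pore-area fractions and total channel area of one array.

    * fraction_of_base_area: mean pore area as % of the (square) needle
      base area ``base_side_um``².
    * total_channel_area: mean pore area × channel count, reported in both
      sq·µm and sq·cm (÷10⁸).
    * fraction_of_permeation_area: total channel area as % of the Franz
      cell permeation area.
    """
    if len(pores.areas) == 0:
        raise ValidationError(f"group {pores.group!r}: no pore areas")
    if base_side_um <= 0:
        raise ValidationError("base side must be positive")
    if n_channels < 1:
        raise ValidationError("channel count must be >= 1")
    mean_area = float(np.mean(pores.areas))
    total_um2 = mean_area * n_channels
    return {
        "mean_area_um2": mean_area,
        "fraction_of_base_area": 100.0 * mean_area / base_side_um**2,
        "total_channel_area_um2": total_um2,
        "total_channel_area_cm2": total_um2 / UM2_PER_CM2,
        "fraction_of_permeation_area": 100.0 * total_um2 / (permeation_area_cm2 * UM2_PER_CM2),
    }


def penetration_efficiency(observed: int, expected: int) -> float:
    """Percent of array needles that produced a detectable channel."""
    if expected == 0:
        raise ValidationError("expected channel count must be >= 1")
    if observed > expected:
        warnings.warn(
            f"observed channels ({observed}) exceed needles on array ({expected})",
            stacklevel=2,
        )
    return 100.0 * observed / expected


def depth_fraction(mean_depth_um: float, needle_length_um: float) -> float:
    """Mean channel depth as % of the microneedle length."""
    if needle_length_um <= 0:
        raise ValidationError("needle length must be positive")
    return 100.0 * mean_depth_um / needle_length_um


def uniformity_summary(pores: PoreSet) -> dict:
    """Descriptive statistics of per-pore PPI values.

    Zero-intensity pores (needles that pierced but did not open a
    conductive channel) are counted separately but included in n and in
    the mean/SD, matching how pore-uniformity reports tabulate them.
    """
    intensities = pores.intensities
    if len(intensities) == 0:
        raise ValidationError(f"group {pores.group!r}: no intensity values")
    n = len(intensities)
    return {
        "mean": float(np.mean(intensities)),
        "sd": float(np.std(intensities, ddof=1)) if n > 1 else 0.0,
        "n": n,
        "n_zero": int(np.sum(intensities == 0)),
    }


def compare_spacing(a: PoreSet, b: PoreSet, equal_var: bool = True):
    """Two-sample t-test on inter-pore spacing between two groups."""
    xa, xb = a.spacings, b.spacings
    if len(xa) < 2 or len(xb) < 2:
        raise ValidationError("need >= 2 spacing values per group")
    return two_sample_ttest(xa, xb, equal_var=equal_var)


def summarize_pores(
    pores: PoreSet,
    base_side_um: float | None = None,
    permeation_area_cm2: float | None = None,
    needle_length_um: float | None = None,
    n_channels: int | None = None,
) -> GeometrySummary:
    """Full geometry summary of one group; derived fields only when their
    inputs are supplied."""

    def stats(values):
        if len(values) == 0:
            return np.nan, np.nan
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return float(np.mean(values)), sd

    mean_area, sd_area = stats(pores.areas)
    mean_depth, sd_depth = stats(pores.depths)
    mean_spacing, sd_spacing = stats(pores.spacings)
    intensities = pores.intensities
    mean_int, sd_int = stats(intensities)

    total = frac_base = frac_perm = None
    if base_side_um is not None and permeation_area_cm2 is not None and n_channels:
        fr = area_fractions(pores, base_side_um, permeation_area_cm2, n_channels)
        total = fr["total_channel_area_cm2"]
        frac_base = fr["fraction_of_base_area"]
        frac_perm = fr["fraction_of_permeation_area"]
    depth_frac = None
    if needle_length_um is not None and len(pores.depths) > 0:
        depth_frac = depth_fraction(mean_depth, needle_length_um)
    pen_eff = None
    if pores.n_expected:
        pen_eff = penetration_efficiency(len(pores), pores.n_expected)

    return GeometrySummary(
        group=pores.group,
        n_pores=len(pores),
        mean_area_um2=mean_area,
        sd_area_um2=sd_area,
        mean_depth_um=mean_depth,
        sd_depth_um=sd_depth,
        mean_spacing_um=mean_spacing,
        sd_spacing_um=sd_spacing,
        mean_intensity=mean_int,
        sd_intensity=sd_int,
        n_zero_intensity=int(np.sum(intensities == 0)) if len(intensities) else 0,
        total_channel_area_cm2=total,
        fraction_of_base_area=frac_base,
        fraction_of_permeation_area=frac_perm,
        depth_fraction_of_length=depth_frac,
        penetration_efficiency=pen_eff,
    )
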