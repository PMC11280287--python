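"""Skin-integrity analysis: electrical resistance, TEWL summaries, and the
group-comparison statistics used throughout the pipeline (Student's t,
one-way ANOVA with Tukey's HSD post hoc).

The resistance circuit drives a fixed AC voltage Vo through the skin in
series with a load resistor RL and reads the drop Vs across the tissue:

    Rs = Vs·RL / ( A·(Vo − Vs) )        [kΩ/sq·cm]

Rs grows without bound as Vs → Vo (intact, highly resistive skin) and is 0
for Vs = 0 (fully shunted barrier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import FranzCellConfig, IntegrityRecord
from .errors import ValidationError

__all__ = [
    "skin_resistance",
    "resistance_summary",
    "two_sample_ttest",
    "group_tests",
    "TTestResult",
    "GroupTestReport",
]


def skin_resistance(vs_mv: float, cfg: FranzCellConfig) -> float:
    """Electrical resistance of the skin (kΩ/sq·cm) from the voltage drop."""
    vo, rl, area = cfg.fixed_voltage, cfg.load_resistance, cfg.permeation_area
    if vs_mv < 0:
        raise ValidationError("voltage drop must be non-negative")
    if vs_mv >= vo:
        raise ValidationError("voltage drop exceeds source")
    return vs_mv * rl / (area * (vo - vs_mv))


def resistance_summary(records: list[IntegrityRecord], cfg: FranzCellConfig) -> dict:
    """Per-group mean ± SD (n−1) of skin resistance and TEWL."""
    groups: dict[str, dict] = {}
    for rec in records:
        groups.setdefault(rec.group, {"rs": [], "tewl": []})
        groups[rec.group]["rs"].append(skin_resistance(rec.vs_mv, cfg))
        groups[rec.group]["tewl"].append(rec.tewl)
    out = {}
    for group, vals in groups.items():
        rs = np.asarray(vals["rs"])
        tewl = np.asarray(vals["tewl"])
        out[group] = {
            "rs_mean": float(rs.mean()),
            "rs_sd": float(rs.std(ddof=1)) if len(rs) > 1 else 0.0,
            "tewl_mean": float(tewl.mean()),
            "tewl_sd": float(tewl.std(ddof=1)) if len(tewl) > 1 else 0.0,
            "n": len(rs),
        }
    return out


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    equal_var: bool


def two_sample_ttest(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sided two-sample t-test (Student by default, Welch by flag)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 values per group for a t-test")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant samples: no evidence of a difference
            return TTestResult(statistic=0.0, p_value=1.0, equal_var=equal_var)
        raise ValidationError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(statistic=float(res.statistic), p_value=float(res.pvalue), equal_var=equal_var)


@dataclass(frozen=True)
class GroupTestReport:
    """ANOVA + post hoc report over labelled samples.

    ``tukey`` and ``pairwise_t`` map (group_a, group_b) → p-value; the
    Tukey p is family-wise adjusted, the pairwise t p is not.
    """

    groups: tuple[str, ...]
    anova_f: float
    anova_p: float
    tukey: dict
    pairwise_t: dict
    significant: dict
    alpha: float


def group_tests(samples: dict, alpha: float = 0.05, equal_var: bool = True) -> GroupTestReport:
    """One-way ANOVA with Tukey HSD, plus unadjusted pairwise Student t.

    ``samples`` maps group label → array of values (each with ≥ 2 values).
    """
    names = tuple(samples.keys())
    if len(names) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = []
    for name in names:
        arr = np.asarray(samples[name], float)
        if len(arr) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
        arrays.append(arr)
    if all(np.var(a, ddof=1) == 0 for a in arrays):
        raise ValidationError("zero pooled variance: all groups are constant")

    f_stat, f_p = stats.f_oneway(*arrays)
    tukey_res = stats.tukey_hsd(*arrays)

    tukey, pairwise, significant = {}, {}, {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            key = (names[i], names[j])
            tukey[key] = float(tukey_res.pvalue[i, j])
            pairwise[key] = two_sample_ttest(arrays[i], arrays[j], equal_var=equal_var).p_value
            significant[key] = tukey[key] < alpha
    return GroupTestReport(
        groups=names,
        anova_f=float(f_stat),
        anova_p=float(f_p),
        tukey=tukey,
        pairwise_t=pairwise,
        significant=significant,
        alpha=alpha,
    )
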