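"""Skin-deposition metrics: topical selectivity, total delivery, delivery
efficiency.

Topical selectivity expresses how much of the delivered drug stayed in the
skin layers rather than crossing into the receptor:

    TS = 100 · Qs / (Qs + Q24)      [%]

with Qs the skin disposition (epidermis + dermis) and Q24 the 24 h
cumulative receptor delivery, both in µg/sq·cm.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import DispositionRecord, FranzCellConfig
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "topical_selectivity",
    "total_delivery",
    "delivery_efficiency",
    "summarize_disposition",
]

EFFICIENCY_CONVENTIONS = ("reported", "strict")


def topical_selectivity(qs: float, q24: float) -> float:
    """Percent of total delivered drug retained within the skin layers."""
    if qs < 0 or q24 < 0:
        raise ValidationError("disposition amounts must be non-negative")
    if qs + q24 == 0:
        raise ValidationError("no delivery: Qs and Q24 are both zero")
    return 100.0 * qs / (qs + q24)


def total_delivery(qs: float, q24: float) -> float:
    """Total drug delivered into and across the skin (µg/sq·cm)."""
    if qs < 0 or q24 < 0:
        raise ValidationError("disposition amounts must be non-negative")
    return qs + q24


def delivery_efficiency(
    total: float, cfg: FranzCellConfig, convention: str = "reported"
) -> float:
    """Delivered fraction of the donor dose, in percent.

    Two conventions are implemented because the field's reports commonly
    divide the per-area total (µg/sq·cm) directly by the dose:

    * ``reported``: 100 × total/dose, leaving the per-area total unconverted —
      with a 100 µg dose the efficiency is numerically equal to the total
      delivery. Dimensionally loose but matches published tables.
    * ``strict``: 100 × total·A/dose — converts the per-area total to an
      absolute amount over the permeation area first.
    """
    if convention not in EFFICIENCY_CONVENTIONS:
        raise ValidationError(
            f"unknown efficiency convention {convention!r}; expected one of "
            f"{EFFICIENCY_CONVENTIONS}"
        )
    if cfg.donor_dose is None or cfg.donor_dose <= 0:
        raise ValidationError("donor dose must be positive for delivery efficiency")
    if convention == "reported":
        logger.warning(
            "delivery efficiency uses the 'reported' convention: per-area total "
            "(µg/sq·cm) divided by the dose (µg) without multiplying by the "
            "permeation area — dimensionally inconsistent unless A = 1 sq·cm"
        )
        return 100.0 * total / cfg.donor_dose
    return 100.0 * total * cfg.permeation_area / cfg.donor_dose


def summarize_disposition(
    records: list[DispositionRecord],
    cfg: FranzCellConfig,
    convention: str = "reported",
) -> pd.DataFrame:
    """Group mean ± SD of disposition metrics, computed per replicate first.

    Returns one row per group with mean/sd columns for epidermis, dermis,
    Qs, total delivery, delivery efficiency (%) and topical selectivity (%).
    """
    if not records:
        raise ValidationError("no disposition records")
    rows = []
    for rec in records:
        qs = rec.qs
        total = total_delivery(qs, rec.q24)
        rows.append(
            {
                "group": rec.group,
                "replicate": rec.replicate_id,
                "epidermis": rec.epidermis,
                "dermis": rec.dermis,
                "qs": qs,
                "total_delivery": total,
                "delivery_efficiency": delivery_efficiency(total, cfg, convention),
                "topical_selectivity": topical_selectivity(qs, rec.q24)
                if qs + rec.q24 > 0
                else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    metrics = [
        "epidermis",
        "dermis",
        "qs",
        "total_delivery",
        "delivery_efficiency",
        "topical_selectivity",
    ]
    out = []
    for group, sub in df.groupby("group", sort=True):
        row = {"group": group, "n": len(sub)}
        for m in metrics:
            row[f"{m}_mean"] = float(sub[m].mean())
            row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
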