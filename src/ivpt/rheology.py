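"""Derived quantities from oscillatory rheometry sweeps.

Three readouts characterize a semisolid gel:

* the linear-viscoelastic (LVE) limit — the largest strain at which the
  storage modulus G′ still sits on its low-strain plateau;
* the flow point — the strain at which G′ = G″, where the gel transitions
  from solid-like to fluid-like behaviour;
* thixotropic recovery — the percentage of the pre-shear G′ plateau
  regained after a high-shear structural disruption (values above 100%
  mean the rebuilt network is stiffer than the original).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import RheoSweep
from .errors import ValidationError

__all__ = ["RheoReport", "lve_limit", "flow_point", "thixotropic_recovery"]


@dataclass(frozen=True)
class RheoReport:
    lve_limit_strain: float | None = None
    flow_point_strain: float | None = None
    flow_point_modulus: float | None = None
    recovery_percent: float | None = None
    elastic_dominant: bool | None = None


def lve_limit(sweep: RheoSweep, tolerance_percent: float = 5.0) -> float:
    """Largest strain at which G′ deviates ≤ ``tolerance_percent`` from its
    low-strain plateau (mean of the first three points)."""
    if sweep.kind != "amplitude":
        raise ValidationError(f"LVE limit needs an amplitude sweep, got {sweep.kind!r}")
    if len(sweep) < 5:
        raise ValidationError("need >= 5 points for an LVE estimate")
    plateau = float(np.mean(sweep.g_prime[:3]))
    within = np.abs(sweep.g_prime - plateau) <= tolerance_percent / 100.0 * plateau
    if not within.any():
        # plateau defined from the sweep itself, so at zero tolerance only
        # points exactly on the plateau qualify; fall back to the first point
        return float(sweep.x[0])
    return float(sweep.x[np.nonzero(within)[0].max()])


def flow_point(sweep: RheoSweep) -> tuple[float, float]:
    """Strain and modulus of the first G′ = G″ crossing.

    Interpolated linearly in log–log coordinates because amplitude sweeps
    are log-spaced. Requires G′ > G″ at low strain and a sign change of
    log(G′/G″) somewhere in the sweep.
    """
    if sweep.kind != "amplitude":
        raise ValidationError(f"flow point needs an amplitude sweep, got {sweep.kind!r}")
    diff = np.log(sweep.g_prime) - np.log(sweep.g_double_prime)
    if diff[0] <= 0:
        raise ValidationError("G'' dominates already at the lowest strain")
    crossings = np.nonzero((diff[:-1] > 0) & (diff[1:] <= 0))[0]
    if len(crossings) == 0:
        raise ValidationError("no flow point in range: G' never meets G''")
    i = int(crossings[0])
    lx0, lx1 = np.log(sweep.x[i]), np.log(sweep.x[i + 1])
    frac = diff[i] / (diff[i] - diff[i + 1])
    lx = lx0 + frac * (lx1 - lx0)
    lg = np.log(sweep.g_prime[i]) + frac * (np.log(sweep.g_prime[i + 1]) - np.log(sweep.g_prime[i]))
    return float(np.exp(lx)), float(np.exp(lg))


def thixotropic_recovery(
    sweep: RheoSweep,
    pre_window: tuple[float, float] = (0.0, 100.0),
    post_window: float = 50.0,
) -> float:
    """Recovery percentage after the high-shear interval.

    100 × (mean G′ over the final ``post_window`` seconds) / (mean G′ over
    ``pre_window``). Defaults: the full 0–100 s pre-shear interval and the
    last 50 s of the recovery phase.
    """
    if sweep.kind != "thixotropy":
        raise ValidationError(f"recovery needs a thixotropy sweep, got {sweep.kind!r}")
    t = sweep.x
    pre_mask = (t >= pre_window[0]) & (t <= pre_window[1])
    post_mask = t >= t[-1] - post_window
    if not pre_mask.any():
        raise ValidationError("pre-shear window contains no samples")
    if not post_mask.any():
        raise ValidationError("post-shear window contains no samples")
    pre = float(np.mean(sweep.g_prime[pre_mask]))
    post = float(np.mean(sweep.g_prime[post_mask]))
    return 100.0 * post / pre
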