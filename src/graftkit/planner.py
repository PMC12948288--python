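"""Inverse dose planning and pulse-elevation injection schedules.

The planner turns the forward models into actionable protocol parameters:
the largest volume staying under a hypoperfusion budget (analytic inverse
of the spherical HypoR), and pulse-elevation schedules that split a total
dose into equal boluses delivered at successively shallower depths with a
pause after each step — the strategy used to improve retention in the
superficial cortex, where a single shallow bolus would mostly reflux.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

from .geometry import (
    DEFAULT_MARGIN_UM,
    hypoperfused_fraction_volume,
    nl_to_um3,
    threshold_volume,
    um3_to_nl,
    volume_from_radius,
)
from .models import RetentionModel, retention_at_depth

__all__ = [
    "InjectionStep",
    "InjectionPlan",
    "max_volume_for_hypoperfusion_budget",
    "pulse_elevation_schedule",
    "plan_report",
]


@dataclass(frozen=True)
class InjectionStep:
    """One bolus: depth (mm), volume (nL), pause after the bolus (s)."""

    depth: float
    volume: float
    pause_after: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if not self.volume > 0:
            raise ValueError("step volume must be strictly positive")
        if self.pause_after < 0:
            raise ValueError("pause must be non-negative")


@dataclass(frozen=True)
class InjectionPlan:
    """An ordered (deep -> shallow) sequence of boluses.

    ``predicted`` is filled by :func:`plan_report` with model-based
    estimates: per-step retention, a volume-weighted aggregate retention
    (a first-order planning estimate, not a validated protocol outcome)
    and the hypoperfused fraction of the total deposited volume.
    """

    steps: tuple
    rate: float  # uL/min
    final_dwell: float  # s
    total_volume: float  # nL
    predicted: Optional[Dict[str, object]] = None

    def __post_init__(self) -> None:
        depths = [s.depth for s in self.steps]
        if any(b >= a for a, b in zip(depths, depths[1:])):
            raise ValueError("step depths must be strictly decreasing (deep to shallow)")
        if abs(sum(s.volume for s in self.steps) - self.total_volume) > 1e-9:
            raise ValueError("step volumes must sum to total_volume")


def max_volume_for_hypoperfusion_budget(
    hypor_budget: float, margin_um: float = DEFAULT_MARGIN_UM
) -> float:
    """Largest volume (um^3) whose hypoperfused fraction is ``hypor_budget``.

    Inverts ``HypoR(r) = ((r - margin)/r)**3``: the budget ``h`` maps to
    radius ``margin / (1 - h**(1/3))``, i.e. the threshold volume at
    ``h = 0``.
    """
    if not 0 <= hypor_budget < 1:
        raise ValueError("hypoperfusion budget must lie in [0, 1)")
    if hypor_budget == 0:
        return float(threshold_volume(margin_um))
    r = margin_um / (1.0 - hypor_budget ** (1.0 / 3.0))
    return float(volume_from_radius(r))


def pulse_elevation_schedule(
    total_volume_nl: float,
    depth_start_mm: float,
    depth_end_mm: float,
    n_steps: int,
    rate_ul_min: float = 0.1,
    pause_s: float = 20.0,
    final_dwell_s: float = 300.0,
) -> InjectionPlan:
    """Equal boluses at linearly spaced depths from deep to shallow.

    Defaults mirror the validated superficial-cortex protocol: 0.1 uL/min,
    a 20-s pause between steps and a 5-min dwell after the last (shallow)
    step before withdrawal. ``n_steps = 1`` degenerates to a continuous
    single bolus at ``depth_start_mm``. When ``total_volume_nl`` does not
    split exactly, the remainder goes to the deepest step (highest
    predicted retention).
    """
    if not total_volume_nl > 0:
        raise ValueError("total volume must be strictly positive")
    if depth_end_mm < 0 or not depth_start_mm > 0:
        raise ValueError("depths must satisfy d_start > 0 and d_end >= 0")
    if n_steps >= 2 and not depth_start_mm > depth_end_mm:
        raise ValueError("d_start must exceed d_end")
    if n_steps < 1:
        raise ValueError("need at least one step")
    if n_steps == 1:
        depths = [depth_start_mm]
    else:
        span = depth_start_mm - depth_end_mm
        depths = [depth_start_mm - i * span / (n_steps - 1) for i in range(n_steps)]
    per = total_volume_nl / n_steps
    volumes = [per] * n_steps
    volumes[0] = total_volume_nl - per * (n_steps - 1)  # remainder to deepest step
    steps = tuple(
        InjectionStep(depth=d, volume=v, pause_after=(pause_s if i < n_steps - 1 else 0.0))
        for i, (d, v) in enumerate(zip(depths, volumes))
    )
    return InjectionPlan(
        steps=steps,
        rate=rate_ul_min,
        final_dwell=final_dwell_s,
        total_volume=total_volume_nl,
    )


def plan_report(
    plan: InjectionPlan,
    retention_model: RetentionModel,
    margin_um: float = DEFAULT_MARGIN_UM,
) -> InjectionPlan:
    """Fill a plan's predictions from the retention and hypoperfusion models.

    Per-step retention is ``R(depth)``; the aggregate is the
    volume-weighted mean ``sum((v_i / V) * R(d_i))`` — an explicit
    model-based first-order estimate of total retained fraction. The
    hypoperfused fraction is evaluated for the total volume pooled into
    one spherical deposit.
    """
    per_step = [float(retention_at_depth(s.depth, retention_model)) for s in plan.steps]
    weights = [s.volume / plan.total_volume for s in plan.steps]
    aggregate = float(sum(w * r for w, r in zip(weights, per_step)))
    hypor_total = float(
        hypoperfused_fraction_volume(nl_to_um3(plan.total_volume), margin_um)
    )
    predicted = {
        "per_step_retention": per_step,
        "aggregate_retention": aggregate,
        "aggregate_retention_note": "volume-weighted model estimate",
        "hypor_of_total": hypor_total,
    }
    return replace(plan, predicted=predicted)
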