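"""Plan/arc complexity aggregation: MU-weighted mean of per-aperture y/A.

The plan metric is ``M = (1/MU) * sum_i MU_i * y_i / A_i`` over all included
control-point apertures, where ``MU`` is the summed MU of those apertures.
Control points with zero open area carry no defined y/A; they are excluded
from both the numerator and the MU denominator (and counted), since the
ratio is undefined there.  Zero-MU control points contribute nothing to
either sum but still appear in the gantry-angle profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .mlc import DEFAULT_MIN_GAP, aperture_complexity, open_area, side_perimeter
from .rtplan import Arc, Plan

__all__ = [
    "ArcComplexity",
    "PlanComplexity",
    "arc_complexity",
    "plan_complexity",
    "complexity_profile",
    "control_point_table",
    "AllAperturesEmptyError",
]

log = logging.getLogger(__name__)


class AllAperturesEmptyError(ValueError):
    """No control point has both positive open area and positive MU."""


@dataclass
class ArcComplexity:
    beam_id: str
    M: float  # mm^-1
    included_mu: float
    excluded_cp_count: int
    profile: list[tuple[float, float | None]]  # (gantry deg, y/A or None)


@dataclass
class PlanComplexity:
    plan_id: str
    M: float  # mm^-1
    per_arc: list[ArcComplexity]
    total_mu: float

    def summary_dict(self) -> dict:
        """JSON-ready summary; metric values rounded to 3 decimals (mm^-1)."""
        return {
            "plan_id": self.plan_id,
            "complexity_mm_inv": round(self.M, 3),
            "total_mu": self.total_mu,
            "arcs": [
                {
                    "beam_id": a.beam_id,
                    "complexity_mm_inv": round(a.M, 3),
                    "included_mu": a.included_mu,
                    "excluded_control_points": a.excluded_cp_count,
                }
                for a in self.per_arc
            ],
        }


def _score_control_points(arc: Arc, min_gap: float) -> None:
    """Fill y, area, complexity on each control point record (idempotent)."""
    for cp in arc.control_points:
        if cp.area is None:
            cp.area = open_area(cp.aperture, min_gap)
            cp.y = side_perimeter(cp.aperture, min_gap)
            cp.complexity = aperture_complexity(cp.aperture, min_gap)


def arc_complexity(arc: Arc, min_gap: float = DEFAULT_MIN_GAP) -> ArcComplexity:
    """MU-weighted mean of y/A over the arc's includable control points."""
    _score_control_points(arc, min_gap)
    num = 0.0
    mu_sum = 0.0
    excluded = 0
    for cp in arc.control_points:
        if cp.complexity is None:
            excluded += 1
            if cp.mu > 0:
                log.warning(
                    "arc %s cp %d: empty aperture with %.2f MU excluded from metric",
                    arc.beam_id, cp.index, cp.mu,
                )
            continue
        num += cp.mu * cp.complexity
        mu_sum += cp.mu
    if mu_sum <= 0:
        raise AllAperturesEmptyError(
            f"arc {arc.beam_id}: no control point with open aperture and MU > 0"
        )
    return ArcComplexity(
        beam_id=arc.beam_id,
        M=num / mu_sum,
        included_mu=mu_sum,
        excluded_cp_count=excluded,
        profile=complexity_profile(arc, min_gap),
    )


def plan_complexity(plan: Plan, min_gap: float = DEFAULT_MIN_GAP) -> PlanComplexity:
    """Single MU-weighted sum over every arc's included control points.

    Equals the combination of the per-arc values weighted by included MU.
    """
    per_arc = [arc_complexity(a, min_gap) for a in plan.arcs]
    mu_sum = sum(a.included_mu for a in per_arc)
    if mu_sum <= 0:
        raise AllAperturesEmptyError(f"plan {plan.plan_id}: no includable control point")
    m = sum(a.M * a.included_mu for a in per_arc) / mu_sum
    return PlanComplexity(
        plan_id=plan.plan_id, M=m, per_arc=per_arc, total_mu=plan.total_mu
    )


def complexity_profile(
    arc: Arc, min_gap: float = DEFAULT_MIN_GAP
) -> list[tuple[float, float | None]]:
    """Per-control-point (gantry angle, y/A) series in delivery order.

    Values are un-weighted per-aperture ratios; empty apertures appear as
    ``None`` gaps so plotted series break rather than interpolate.
    """
    _score_control_points(arc, min_gap)
    return [(cp.gantry_angle, cp.complexity) for cp in arc.control_points]


def control_point_table(plan: Plan, min_gap: float = DEFAULT_MIN_GAP) -> pd.DataFrame:
    """Full-precision per-control-point table for CSV export."""
    for arc in plan.arcs:
        _score_control_points(arc, min_gap)
    rows = [
        {
            "beam_id": arc.beam_id,
            "cp_index": cp.index,
            "gantry_deg": cp.gantry_angle,
            "mu": cp.mu,
            "area_mm2": cp.area,
            "perimeter_mm": cp.y,
            "complexity_mm_inv": cp.complexity,
        }
        for arc in plan.arcs
        for cp in arc.control_points
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "beam_id", "cp_index", "gantry_deg", "mu",
            "area_mm2", "perimeter_mm", "complexity_mm_inv",
        ],
    )
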