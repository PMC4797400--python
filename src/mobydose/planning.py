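"""Therapy planning: invert the marrow dose constraint to an activity.

The administered activity is prescribed by dividing the tolerable dose of
the dose-limiting organ (red bone marrow, 12 Gy by default, a literature
estimate for mice) by that organ's total dose coefficient.  The reported
prescription is rounded to the nearest integer MBq and downstream doses
are computed from the rounded value; the unrounded activity is retained
alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PlanningConstraint", "TherapyPlan", "prescribe_activity", "doses_at_prescription"]

#: Default tolerable red-marrow absorbed dose in mice (Gy).
DEFAULT_MARROW_LIMIT_GY = 12.0


class UnconstrainedPlanError(ValueError):
    """The limiting region has a zero dose coefficient: no finite prescription."""


@dataclass(frozen=True)
class PlanningConstraint:
    limiting_region: str = "marrow"
    dose_limit_gy: float = DEFAULT_MARROW_LIMIT_GY

    def __post_init__(self) -> None:
        if self.dose_limit_gy <= 0:
            raise ValueError("dose limit must be positive")


@dataclass(frozen=True)
class TherapyPlan:
    constraint: PlanningConstraint
    activity_mbq: float          # exact: limit / coefficient
    activity_mbq_rounded: int    # reported prescription
    limiting_coefficient: float  # Gy/MBq
    doses_gy: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "limiting_region": self.constraint.limiting_region,
            "dose_limit_gy": self.constraint.dose_limit_gy,
            "limiting_total_gy_per_mbq": self.limiting_coefficient,
            "activity_mbq": self.activity_mbq,
            "activity_mbq_rounded": self.activity_mbq_rounded,
            "doses_gy_at_rounded_activity": self.doses_gy,
        }


def prescribe_activity(
    coefficients: dict[str, tuple[float, float]],
    constraint: PlanningConstraint = PlanningConstraint(),
) -> TherapyPlan:
    """Administered activity (MBq) that delivers the dose limit to the
    limiting region: dose_limit / total coefficient.

    Raises :class:`UnconstrainedPlanError` if the limiting region's total
    coefficient is zero, and ``KeyError`` if the region is absent.
    """
    if constraint.limiting_region not in coefficients:
        raise KeyError(
            f"limiting region '{constraint.limiting_region}' not in coefficient table"
        )
    total = coefficients[constraint.limiting_region][1]
    if total <= 0:
        raise UnconstrainedPlanError(
            f"{constraint.limiting_region}: zero total dose coefficient, "
            "activity is unconstrained"
        )
    exact = constraint.dose_limit_gy / total
    rounded = int(round(exact))
    plan = TherapyPlan(
        constraint=constraint,
        activity_mbq=exact,
        activity_mbq_rounded=rounded,
        limiting_coefficient=total,
        doses_gy=doses_at_prescription(coefficients, float(rounded)),
    )
    return plan


def doses_at_prescription(
    coefficients: dict[str, tuple[float, float]], prescribed_mbq: float
) -> dict[str, float]:
    """Region doses (Gy) at the prescribed activity: total coefficient x MBq."""
    if prescribed_mbq < 0:
        raise ValueError("prescribed activity must be >= 0 MBq")
    return {r: c[1] * prescribed_mbq for r, c in coefficients.items()}
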