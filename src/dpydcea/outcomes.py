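"""Rewards, per-arm totals, and incremental cost-effectiveness.

The reward model turns a cohort trace (state occupancy plus toxicity and
hospitalization event intensities) into per-cycle cost and QALY/LY
increments; :func:`compare` turns two per-arm totals into incremental
cost, ICERs, net monetary benefit and a dominance classification.

Costs counted are drug acquisition, the one-off genotyping test, and
hospitalization for toxicity; disease-management and end-of-life costs are
equal across arms by assumption and therefore set to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import ModelParameters
from .states import state_drug_costs, state_utilities

__all__ = [
    "CycleRewards",
    "StrategyResult",
    "CEResult",
    "reward_model",
    "compare",
]

#: fraction of a year the one-week hospitalization disutility applies for
HOSP_DISUTILITY_YEARS = 7.0 / 365.25


@dataclass(frozen=True)
class CycleRewards:
    """Per-cycle undiscounted reward increments (arrays over cycles)."""

    cost: np.ndarray
    qaly: np.ndarray
    ly: np.ndarray
    drug_cost: np.ndarray
    hosp_cost: np.ndarray
    test_cost: np.ndarray


def reward_model(
    occupancy: np.ndarray,
    tox_events: np.ndarray,
    hosp_events: np.ndarray,
    params: ModelParameters,
    include_test_cost: bool = False,
    overlap_disutilities: bool = True,
) -> CycleRewards:
    """Undiscounted per-cycle rewards from occupancy and event intensities.

    ``occupancy`` has one row per cycle (start-of-cycle state mix);
    ``tox_events`` / ``hosp_events`` are expected events per cohort member
    during each cycle.  QALYs accrue at 1/12 of the state utility per
    monthly cycle, minus one month of toxicity disutility per toxicity
    event and one week of hospitalization disutility per admission; with
    ``overlap_disutilities=False`` hospitalized events carry only the
    hospitalization decrement.  Cost is drug + hospitalization (+ the test
    at cycle 0 when ``include_test_cost``).
    """
    occupancy = np.atleast_2d(np.asarray(occupancy, dtype=float))
    tox_events = np.asarray(tox_events, dtype=float)
    hosp_events = np.asarray(hosp_events, dtype=float)
    if np.any(tox_events < -1e-12) or np.any(hosp_events < -1e-12):
        raise ValueError("event intensities must be non-negative")

    drug = occupancy @ state_drug_costs(params)
    hosp = hosp_events * params.cost_hosp
    test = np.zeros_like(drug)
    if include_test_cost and len(test):
        test[0] = params.cost_test
    cost = drug + hosp + test

    tox_with_disutil = tox_events if overlap_disutilities else tox_events - hosp_events
    qaly = (
        (occupancy @ state_utilities(params)) / 12.0
        - tox_with_disutil * params.disutil_tox / 12.0
        - hosp_events * params.disutil_hosp * HOSP_DISUTILITY_YEARS
    )
    alive = occupancy[:, :7].sum(axis=1)  # PF states + progressed
    ly = alive / 12.0
    return CycleRewards(cost, qaly, ly, drug, hosp, test)


@dataclass(frozen=True)
class StrategyResult:
    """Lifetime totals for one strategy arm."""

    strategy: str
    total_cost: float
    total_qaly: float
    total_ly: float
    undiscounted_cost: float
    undiscounted_qaly: float
    undiscounted_ly: float
    cost_breakdown: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cost_breakdown:
            if not math.isclose(
                sum(self.cost_breakdown.values()), self.total_cost, abs_tol=1e-6
            ):
                raise ValueError("cost breakdown does not sum to total cost")


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of a comparator arm against a reference arm."""

    inc_cost: float
    inc_qaly: float
    inc_ly: float
    icer_per_qaly: float  # NaN when inc_qaly == 0
    icer_per_ly: float
    nmb: float
    wtp: float
    classification: str

    @property
    def cost_effective(self) -> bool:
        return self.classification in ("cost_effective", "dominant")


def _safe_ratio(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def compare(
    reference: StrategyResult, comparator: StrategyResult, wtp: float
) -> CEResult:
    """Incremental cost-effectiveness of ``comparator`` vs ``reference``.

    ICERs are reported in all quadrants but are only meaningful in the
    trade-off quadrants; classification uses dominance where one arm wins
    on both axes and the sign of incremental net monetary benefit
    (``inc_qaly * wtp - inc_cost``) otherwise.
    """
    inc_cost = comparator.total_cost - reference.total_cost
    inc_qaly = comparator.total_qaly - reference.total_qaly
    inc_ly = comparator.total_ly - reference.total_ly
    nmb = inc_qaly * wtp - inc_cost
    if inc_cost < 0 and inc_qaly > 0:
        classification = "dominant"
    elif inc_cost > 0 and inc_qaly < 0:
        classification = "dominated"
    elif nmb > 0:
        classification = "cost_effective"
    else:
        classification = "not_cost_effective"
    return CEResult(
        inc_cost=inc_cost,
        inc_qaly=inc_qaly,
        inc_ly=inc_ly,
        icer_per_qaly=_safe_ratio(inc_cost, inc_qaly),
        icer_per_ly=_safe_ratio(inc_cost, inc_ly),
        nmb=nmb,
        wtp=wtp,
        classification=classification,
    )
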