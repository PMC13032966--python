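"""Cohort state-transition engine.

Monthly cycles; the cohort starts at age 62 fully progression-free, split
by genotype into the dose tier its strategy assigns.  Within a cycle,
competing events form a fixed conditional cascade:

1. background death (age-specific, from the life table),
2. treatment-related death (progression-free states only),
3. disease progression (PF) or post-progression death (Progressed),
4. grade 3/4 toxicity among PF non-progressors, which moves the survivor
   down one dose tier for subsequent cycles; a fraction of toxicity
   events (the conditional hospitalization probability) is recorded as
   hospitalization intensity.

Events are mutually exclusive within a cycle for one cohort member;
destination probabilities are products of the cascade terms.  Rewards are
booked on start-of-cycle occupancy and discounted at ``(1+r)^(-t/12)``;
no half-cycle correction is applied by default (a flag enables it for
scenario analysis).  The run stops at age 100 or when live occupancy
falls below a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import states as S
from .lifetable import LifeTable, monthly_background_mortality
from .outcomes import StrategyResult, reward_model
from .parameters import ModelParameters
from .treatment import Genotype, Strategy, initial_tier

__all__ = [
    "RunSettings",
    "CohortTrace",
    "cycle_event_probabilities",
    "build_transition_matrix",
    "initial_occupancy",
    "run_cohort",
]


@dataclass(frozen=True)
class RunSettings:
    """Structural run options (scenario flags)."""

    max_age: float = 100.0
    min_alive: float = 1e-8
    half_cycle_correction: bool = False
    #: if set, treatment-related death applies only in the first k cycles
    treatment_death_max_cycles: int | None = None
    #: hospitalized toxicity events carry the toxicity disutility too
    overlap_disutilities: bool = True

    def __post_init__(self) -> None:
        if self.max_age <= 0:
            raise ValueError("max_age must be positive")

    def n_cycles(self, start_age: float) -> int:
        n = int(np.ceil((self.max_age - start_age) * 12.0))
        if n <= 0:
            raise ValueError("horizon is empty: max_age must exceed start_age")
        return n


def _pf_cascade(m_bg, p_td, p_prog, p_tox):
    """Cascade products for a PF state; returns destination masses.

    Each argument may be scalar or an array over cycles.
    """
    to_dead_bg = m_bg
    surv = 1.0 - m_bg
    to_dead_trt = surv * p_td
    surv = surv * (1.0 - p_td)
    to_progressed = surv * p_prog
    surv = surv * (1.0 - p_prog)
    tox_flow = surv * p_tox
    stay = surv * (1.0 - p_tox)
    return to_dead_bg, to_dead_trt, to_progressed, tox_flow, stay


def cycle_event_probabilities(
    state: int,
    age: float,
    params: ModelParameters,
    lt: LifeTable,
    cycle_index: int = 0,
    settings: RunSettings | None = None,
):
    """One-cycle destination distribution and event intensities for a state.

    Returns ``(probs, intensities)`` where ``probs`` is a length-10 vector
    over destination states and ``intensities`` holds the expected
    toxicity and hospitalization events per member in the state.
    Dead states are absorbing and may not be passed here.
    """
    settings = settings or RunSettings()
    if state in S.DEAD_STATES:
        raise ValueError("cycle_event_probabilities is defined for live states only")
    m_bg = monthly_background_mortality(lt, age)
    probs = np.zeros(S.N_STATES)
    intensities = {"toxicity": 0.0, "hospitalization": 0.0}

    if state == S.PROGRESSED:
        probs[S.DEAD_BACKGROUND] = m_bg
        probs[S.DEAD_PROGRESSION] = (1.0 - m_bg) * params.p_death_progressed
        probs[S.PROGRESSED] = (1.0 - m_bg) * (1.0 - params.p_death_progressed)
        return probs, intensities

    p_td_vec, p_tox_vec, p_hosp_vec = S.pf_event_probabilities(params)
    p_td = p_td_vec[state]
    k = settings.treatment_death_max_cycles
    if k is not None and cycle_index >= k:
        p_td = 0.0
    to_bg, to_trt, to_prog, tox_flow, stay = _pf_cascade(
        m_bg, p_td, params.p_progress, p_tox_vec[state]
    )
    probs[S.DEAD_BACKGROUND] = to_bg
    probs[S.DEAD_TREATMENT] = to_trt
    probs[S.PROGRESSED] = to_prog
    probs[S.tox_destination(state)] += tox_flow
    probs[state] += stay
    intensities["toxicity"] = tox_flow
    intensities["hospitalization"] = tox_flow * p_hosp_vec[state]
    return probs, intensities


def build_transition_matrix(
    cycle_index: int,
    strategy: Strategy,
    params: ModelParameters,
    lt: LifeTable,
    settings: RunSettings | None = None,
) -> np.ndarray:
    """The 10x10 one-cycle transition matrix for a given cycle.

    The matrix is strategy-independent (strategies differ only in the
    initial occupancy); the argument is kept for interface symmetry.
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    Strategy(strategy)
    age = params.start_age + cycle_index / 12.0
    M = np.zeros((S.N_STATES, S.N_STATES))
    for state in list(range(len(S.PF_STATES))) + [S.PROGRESSED]:
        M[state], _ = cycle_event_probabilities(
            state, age, params, lt, cycle_index, settings
        )
    for state in S.DEAD_STATES:
        M[state, state] = 1.0
    return M


def initial_occupancy(strategy: Strategy, params: ModelParameters) -> np.ndarray:
    """Cycle-0 occupancy: the cohort split by genotype into its start tier."""
    occ = np.zeros(S.N_STATES)
    for genotype, share in (
        (Genotype.VARIANT, params.p_variant),
        (Genotype.WILD_TYPE, 1.0 - params.p_variant),
    ):
        occ[S.pf_index(genotype, initial_tier(strategy, genotype))] += share
    return occ


def _build_all_matrices(params, m_bg, settings):
    """Vectorized (T, 10, 10) transition matrices; T = len(m_bg)."""
    T = len(m_bg)
    p_td_vec, p_tox_vec, p_hosp_vec = S.pf_event_probabilities(params)
    M = np.zeros((T, S.N_STATES, S.N_STATES))
    tox_intensity = np.zeros((T, len(S.PF_STATES)))
    hosp_intensity = np.zeros_like(tox_intensity)
    k = settings.treatment_death_max_cycles
    td_on = np.ones(T) if k is None else (np.arange(T) < k).astype(float)
    for s in range(len(S.PF_STATES)):
        to_bg, to_trt, to_prog, tox_flow, stay = _pf_cascade(
            m_bg, p_td_vec[s] * td_on, params.p_progress, p_tox_vec[s]
        )
        M[:, s, S.DEAD_BACKGROUND] = to_bg
        M[:, s, S.DEAD_TREATMENT] = to_trt
        M[:, s, S.PROGRESSED] = to_prog
        M[:, s, S.tox_destination(s)] += tox_flow
        M[:, s, s] += stay
        tox_intensity[:, s] = tox_flow
        hosp_intensity[:, s] = tox_flow * p_hosp_vec[s]
    M[:, S.PROGRESSED, S.DEAD_BACKGROUND] = m_bg
    M[:, S.PROGRESSED, S.DEAD_PROGRESSION] = (1 - m_bg) * params.p_death_progressed
    M[:, S.PROGRESSED, S.PROGRESSED] = (1 - m_bg) * (1 - params.p_death_progressed)
    for state in S.DEAD_STATES:
        M[:, state, state] = 1.0
    return M, tox_intensity, hosp_intensity


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle trace of one strategy arm.

    ``occupancy`` has T+1 rows (start of each cycle plus the final state
    mix); reward arrays have T entries, one per cycle.
    """

    strategy: str
    occupancy: np.ndarray
    tox_events: np.ndarray
    hosp_events: np.ndarray
    cost: np.ndarray
    qaly: np.ndarray
    ly: np.ndarray
    drug_cost: np.ndarray
    hosp_cost: np.ndarray
    test_cost: np.ndarray
    discount: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.cost)

    def totals(self) -> StrategyResult:
        d = self.discount
        return StrategyResult(
            strategy=self.strategy,
            total_cost=float(self.cost @ d),
            total_qaly=float(self.qaly @ d),
            total_ly=float(self.ly @ d),
            undiscounted_cost=float(self.cost.sum()),
            undiscounted_qaly=float(self.qaly.sum()),
            undiscounted_ly=float(self.ly.sum()),
            cost_breakdown={
                "drug": float(self.drug_cost @ d),
                "hospitalization": float(self.hosp_cost @ d),
                "test": float(self.test_cost @ d),
            },
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle: occupancy by state and reward increments."""
        T = self.n_cycles
        df = pd.DataFrame(self.occupancy[:T], columns=list(S.STATE_LABELS))
        df.insert(0, "cycle", np.arange(T))
        df["tox_events"] = self.tox_events
        df["hosp_events"] = self.hosp_events
        df["cost"] = self.cost
        df["qaly"] = self.qaly
        df["ly"] = self.ly
        df["discount"] = self.discount
        df["cost_discounted"] = self.cost * self.discount
        df["qaly_discounted"] = self.qaly * self.discount
        df["ly_discounted"] = self.ly * self.discount
        return df


def run_cohort(
    strategy: Strategy,
    params: ModelParameters,
    lt: LifeTable,
    settings: RunSettings | None = None,
) -> CohortTrace:
    """Propagate the cohort and accumulate discounted rewards.

    The genotyping arm bears the test cost once, at cycle 0, undiscounted.
    """
    strategy = Strategy(strategy)
    settings = settings or RunSettings()
    T_max = settings.n_cycles(params.start_age)
    ages = params.start_age + np.arange(T_max) / 12.0
    m_bg = np.asarray(monthly_background_mortality(lt, ages))

    M, tox_int, hosp_int = _build_all_matrices(params, m_bg, settings)

    occ = np.empty((T_max + 1, S.N_STATES))
    occ[0] = initial_occupancy(strategy, params)
    T = T_max
    for t in range(T_max):
        occ[t + 1] = occ[t] @ M[t]
        if occ[t + 1, : S.PROGRESSED + 1].sum() < settings.min_alive:
            T = t + 1
            break
    occ = occ[: T + 1]

    pf_occ = occ[:T, : len(S.PF_STATES)]
    tox_events = np.einsum("ts,ts->t", pf_occ, tox_int[:T])
    hosp_events = np.einsum("ts,ts->t", pf_occ, hosp_int[:T])

    rewards = reward_model(
        occ[:T],
        tox_events,
        hosp_events,
        params,
        include_test_cost=(strategy is Strategy.GENOTYPING),
        overlap_disutilities=settings.overlap_disutilities,
    )
    cost, qaly, ly = rewards.cost, rewards.qaly, rewards.ly
    drug, hosp, test = rewards.drug_cost, rewards.hosp_cost, rewards.test_cost

    if settings.half_cycle_correction:
        # half weight on the first cycle's state rewards, half a terminal
        # cycle on the final occupancy; event rewards and the test cost
        # are left untouched.
        tail = reward_model(occ[T][None, :], [0.0], [0.0], params)
        cost = cost.copy(); qaly = qaly.copy(); ly = ly.copy(); drug = drug.copy()
        drug[0] *= 0.5
        cost[0] -= rewards.drug_cost[0] * 0.5
        qaly[0] -= (occ[0] @ S.state_utilities(params)) / 12.0 * 0.5
        ly[0] *= 0.5
        cost = np.append(cost, tail.cost[0] * 0.5)
        drug = np.append(drug, tail.drug_cost[0] * 0.5)
        hosp = np.append(hosp, 0.0)
        test = np.append(test, 0.0)
        qaly = np.append(qaly, tail.qaly[0] * 0.5)
        ly = np.append(ly, tail.ly[0] * 0.5)
        tox_events = np.append(tox_events, 0.0)
        hosp_events = np.append(hosp_events, 0.0)
        discount = (1.0 + params.discount_rate_annual) ** (
            -np.arange(T + 1) / 12.0
        )
    else:
        discount = (1.0 + params.discount_rate_annual) ** (-np.arange(T) / 12.0)

    return CohortTrace(
        strategy=strategy.value,
        occupancy=occ,
        tox_events=tox_events,
        hosp_events=hosp_events,
        cost=cost,
        qaly=qaly,
        ly=ly,
        drug_cost=drug,
        hosp_cost=hosp,
        test_cost=test,
        discount=discount,
    )
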