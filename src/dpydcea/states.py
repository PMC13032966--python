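"""The expanded health-state space.

The published four-state structure (progression-free at starting dose,
progression-free at reduced dose, progressed, dead) is expanded so that
transition probabilities are state-determined: progression-free is
stratified by genotype x dose tier (2 x 3 = 6 states) and death is tagged
by cause, giving 10 states in total.
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelParameters
from .treatment import (
    Genotype,
    drug_cost_per_cycle,
    hospitalization_probability_given_toxicity,
    next_tier_after_toxicity,
    toxicity_probability,
    treatment_death_probability,
)

__all__ = [
    "N_STATES",
    "PF_STATES",
    "PROGRESSED",
    "DEAD_BACKGROUND",
    "DEAD_TREATMENT",
    "DEAD_PROGRESSION",
    "STATE_LABELS",
    "pf_index",
    "state_utilities",
    "state_drug_costs",
]

#: progression-free states, indexed 0..5 as (genotype, tier index)
PF_STATES: tuple[tuple[Genotype, int], ...] = (
    (Genotype.VARIANT, 0),
    (Genotype.VARIANT, 1),
    (Genotype.VARIANT, 2),
    (Genotype.WILD_TYPE, 0),
    (Genotype.WILD_TYPE, 1),
    (Genotype.WILD_TYPE, 2),
)
PROGRESSED = 6
DEAD_BACKGROUND = 7
DEAD_TREATMENT = 8
DEAD_PROGRESSION = 9
N_STATES = 10

DEAD_STATES = (DEAD_BACKGROUND, DEAD_TREATMENT, DEAD_PROGRESSION)

STATE_LABELS = tuple(
    [f"pf_{g.value}_{int(ModelParameters().dose_fractions[t] * 100)}" for g, t in PF_STATES]
    + ["progressed", "dead_background", "dead_treatment", "dead_progression"]
)


def pf_index(genotype: Genotype, tier: int) -> int:
    """State index of a progression-free (genotype, tier) cell."""
    return PF_STATES.index((Genotype(genotype), tier))


def tox_destination(state: int) -> int:
    """Destination PF state after a toxicity event (dose steps down)."""
    g, tier = PF_STATES[state]
    return pf_index(g, next_tier_after_toxicity(tier))


def state_utilities(params: ModelParameters) -> np.ndarray:
    """Annual-scale utility weight of each state (dead states are 0)."""
    u = np.zeros(N_STATES)
    u[: len(PF_STATES)] = params.u_pf
    u[PROGRESSED] = params.u_prog
    return u


def state_drug_costs(params: ModelParameters) -> np.ndarray:
    """Per-cycle drug cost of each state (zero once off treatment)."""
    c = np.zeros(N_STATES)
    for s, (_, tier) in enumerate(PF_STATES):
        c[s] = drug_cost_per_cycle(tier, params)
    return c


def pf_event_probabilities(params: ModelParameters):
    """Per-PF-state vectors (p_treatment_death, p_toxicity, p_hosp_given_tox)."""
    n = len(PF_STATES)
    p_td = np.empty(n)
    p_tox = np.empty(n)
    p_hosp = np.empty(n)
    for s, (g, tier) in enumerate(PF_STATES):
        p_td[s] = treatment_death_probability(g, tier, params)
        p_tox[s] = toxicity_probability(g, tier, params)
        p_hosp[s] = hospitalization_probability_given_toxicity(g, tier, params)
    return p_td, p_tox, p_hosp
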