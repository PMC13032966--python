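"""Strategy and dose-tier logic.

Two strategies are compared: *genotyping* (DPYD test before the first
cycle; variant carriers start at 75% dose) and *no_genotyping* (everyone
starts at full dose).  After any grade 3/4 toxicity the dose steps down
one tier for all subsequent cycles -- full -> 75% -> 50% -- with 50% as
the floor.

Probability anchors come from observed cohorts: variant carriers at
standard dose (monthly toxicity 0.08), variant carriers at reduced dose
(0.044) and wild type at standard dose (0.026), and likewise for
hospitalization given toxicity and treatment-related death.  Cells without
an observed anchor are filled by the model's proportionality assumption:
toxicity and treatment-death probabilities (and the drug cost) scale
linearly with the dose fraction from the nearest observed lower-dose
anchor, while hospitalization given toxicity -- a severity measure, not an
exposure measure -- reuses the genotype's nearest anchor unscaled.
"""

from __future__ import annotations

from enum import Enum

from .parameters import ModelParameters

__all__ = [
    "Strategy",
    "Genotype",
    "TIER_FRACTIONS",
    "initial_tier",
    "next_tier_after_toxicity",
    "toxicity_probability",
    "hospitalization_probability_given_toxicity",
    "treatment_death_probability",
    "drug_cost_per_cycle",
    "monthly_drug_cost_from_regimen",
]


class Strategy(str, Enum):
    GENOTYPING = "genotyping"
    NO_GENOTYPING = "no_genotyping"


class Genotype(str, Enum):
    VARIANT = "variant"  # intermediate and poor metabolizers combined
    WILD_TYPE = "wild_type"


#: dose tiers by index: 0 = standard, 1 = reduced, 2 = floor
TIER_FRACTIONS = (1.0, 0.75, 0.5)
_STANDARD, _REDUCED, _FLOOR = 0, 1, 2


def initial_tier(strategy: Strategy, genotype: Genotype) -> int:
    """Starting dose-tier index: genotyped variant carriers start reduced."""
    strategy = Strategy(strategy)
    genotype = Genotype(genotype)
    if strategy is Strategy.GENOTYPING and genotype is Genotype.VARIANT:
        return _REDUCED
    return _STANDARD


def next_tier_after_toxicity(tier: int) -> int:
    """Step-down policy after a toxicity event; the 50% floor is absorbing."""
    if tier not in (0, 1, 2):
        raise ValueError(f"invalid dose tier index {tier}")
    return min(tier + 1, _FLOOR)


def _tier_fraction(params: ModelParameters, tier: int) -> float:
    return params.dose_fractions[tier]


def toxicity_probability(genotype: Genotype, tier: int, params: ModelParameters) -> float:
    """Monthly probability of grade 3/4 toxicity for a genotype x tier cell.

    Observed anchors: (variant, standard) = ``p_tox_variant_std``,
    (variant, reduced) = ``p_tox_variant_red``, (wild type, standard) =
    ``p_tox_wt_std``.  Unobserved cells scale the nearest higher-dose
    anchor proportionally by dose fraction.
    """
    genotype = Genotype(genotype)
    f = _tier_fraction(params, tier)
    if genotype is Genotype.VARIANT:
        if tier == _STANDARD:
            return params.p_tox_variant_std
        if tier == _REDUCED:
            return params.p_tox_variant_red
        # 50% tier scales from the observed 75% anchor
        return params.p_tox_variant_red * (f / _tier_fraction(params, _REDUCED))
    return params.p_tox_wt_std * f


def hospitalization_probability_given_toxicity(
    genotype: Genotype, tier: int, params: ModelParameters
) -> float:
    """P(hospitalization | grade 3/4 toxicity) for a genotype x tier cell.

    No dose scaling: unobserved cells reuse the genotype's nearest anchor.
    """
    genotype = Genotype(genotype)
    if genotype is Genotype.VARIANT:
        if tier == _STANDARD:
            return params.p_hosp_variant_std
        return params.p_hosp_variant_red
    return params.p_hosp_wt_std


def treatment_death_probability(
    genotype: Genotype, tier: int, params: ModelParameters
) -> float:
    """Monthly probability of treatment-related death, proportional in dose."""
    genotype = Genotype(genotype)
    f = _tier_fraction(params, tier)
    if genotype is Genotype.VARIANT:
        if tier == _STANDARD:
            return params.p_trtdeath_variant_std
        if tier == _REDUCED:
            return params.p_trtdeath_variant_red
        return params.p_trtdeath_variant_red * (f / _tier_fraction(params, _REDUCED))
    return params.p_trtdeath_wt_std * f


def drug_cost_per_cycle(tier: int, params: ModelParameters) -> float:
    """Monthly capecitabine cost at a dose tier; zero once progressed
    (treatment stops at progression, handled by the state space)."""
    return params.cost_drug_monthly_full * _tier_fraction(params, tier)


def monthly_drug_cost_from_regimen(
    unit_price_per_500mg: float, bsa: float, params: ModelParameters
) -> float:
    """Monthly full-dose drug cost rebuilt from the dosing regimen.

    1,250 mg/m2 twice daily for 14 of 21 days gives a per-regimen-cycle
    dose of 1250 * bsa * 2 * 14 mg; the per-cycle cost is prorated to the
    model's cycle length (default 30 days).  Cross-checks the tabulated
    monthly cost, which reflects average-sales-price rounding.
    """
    if unit_price_per_500mg < 0 or bsa <= 0:
        raise ValueError("unit price must be >= 0 and BSA > 0")
    dose_mg = 1250.0 * bsa * 2 * 14
    cycle_cost = dose_mg / 500.0 * unit_price_per_500mg
    return cycle_cost * params.cycle_length_days / 21.0
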