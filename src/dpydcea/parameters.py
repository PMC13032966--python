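"""Model parameters: base-case values, uncertainty distributions, config I/O.

Every input of the decision model lives in one frozen record,
:class:`ModelParameters`.  Base-case values are the published estimates for a
cohort of 62-year-old women with metastatic breast cancer treated with
capecitabine monotherapy, with toxicity, hospitalization and
treatment-related-death probabilities stratified by DPYD genotype and dose
tier.  Each uncertain parameter additionally carries a
:class:`DistributionSpec` (Beta for probabilities and utilities, Gamma for
costs, Triangular for rare-death probabilities) used by the probabilistic
sensitivity analysis, and a (low, high) range used by the deterministic
one-way analyses.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "ParameterSpec",
    "ModelParameters",
    "default_parameters",
    "load_parameters",
    "parameters_to_config",
    "sample_value",
    "sample_parameters",
    "table1_specs",
    "dsa_specs",
]


class ParameterError(ValueError):
    """Raised for unknown parameter names or out-of-range values."""


# --------------------------------------------------------------------------
# distributions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """One uncertainty distribution for probabilistic sampling.

    kind
        ``beta``          -- a, b are the alpha/beta shape parameters
        ``gamma_mean_sd`` -- a is the mean, b the standard deviation;
                             converted to shape/scale by moment matching
        ``triangular``    -- a is the minimum, b the maximum, c the mode
        ``fixed``         -- degenerate; every draw returns a
    """

    kind: str
    a: float
    b: float = 0.0
    c: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "beta":
            if self.a <= 0 or self.b <= 0:
                raise ParameterError(f"beta requires positive shapes, got {self}")
        elif self.kind == "gamma_mean_sd":
            if self.a <= 0 or self.b <= 0:
                raise ParameterError(f"gamma requires positive mean and sd, got {self}")
        elif self.kind == "triangular":
            if self.c is None or not (self.a <= self.c <= self.b):
                raise ParameterError(f"triangular requires min <= mode <= max, got {self}")
        elif self.kind != "fixed":
            raise ParameterError(f"unknown distribution kind {self.kind!r}")

    def mean(self) -> float:
        """Analytic mean of the distribution."""
        if self.kind == "beta":
            return self.a / (self.a + self.b)
        if self.kind == "gamma_mean_sd":
            return self.a
        if self.kind == "triangular":
            assert self.c is not None
            return (self.a + self.b + self.c) / 3.0
        return self.a

    def sample(self, rng: np.random.Generator, size=None):
        """Draw from the distribution using ``rng``."""
        if self.kind == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.kind == "gamma_mean_sd":
            shape = (self.a / self.b) ** 2
            scale = self.b**2 / self.a
            return rng.gamma(shape, scale, size=size)
        if self.kind == "triangular":
            return rng.triangular(self.a, self.c, self.b, size=size)
        if size is None:
            return self.a
        return np.full(size, self.a)


def sample_value(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from ``spec``; scalar convenience wrapper."""
    return float(spec.sample(rng))


@dataclass(frozen=True)
class ParameterSpec:
    """A named model parameter with its DSA range and PSA distribution."""

    name: str
    base_value: float
    low: float
    high: float
    distribution: DistributionSpec | None = None
    units: str = ""
    varies_in_dsa: bool = True

    def __post_init__(self) -> None:
        if not (self.low <= self.base_value <= self.high):
            raise ParameterError(
                f"{self.name}: base {self.base_value} outside [{self.low}, {self.high}]"
            )


# --------------------------------------------------------------------------
# the parameter record
# --------------------------------------------------------------------------

_PROBABILITY_FIELDS = (
    "p_variant",
    "p_tox_variant_std",
    "p_tox_variant_red",
    "p_tox_wt_std",
    "p_hosp_variant_std",
    "p_hosp_variant_red",
    "p_hosp_wt_std",
    "p_trtdeath_variant_std",
    "p_trtdeath_variant_red",
    "p_trtdeath_wt_std",
    "p_progress",
    "p_death_progressed",
)
_UTILITY_FIELDS = ("u_pf", "u_prog")
_NONNEGATIVE_FIELDS = (
    "cost_drug_monthly_full",
    "cost_unit_per_500mg",
    "cost_test",
    "cost_hosp",
    "disutil_hosp",
    "disutil_tox",
)
_POSITIVE_FIELDS = ("bsa", "wtp", "hosp_los_days", "cycle_length_days")


@dataclass(frozen=True)
class ModelParameters:
    """All model inputs (base case) plus structural settings.

    Probabilities are per monthly cycle unless noted; hospitalization
    probabilities are conditional on a grade 3/4 toxicity event in that
    cycle; costs are 2024 US dollars; utilities are on the 0-1 scale.
    ``cost_hosp`` is the cost of one hospital stay (five days); the
    hospitalization disutility is applied for one week per stay.
    """

    start_age: float = 62.0
    discount_rate_annual: float = 0.03
    bsa: float = 1.8
    wtp: float = 100_000.0

    p_variant: float = 0.063

    p_tox_variant_std: float = 0.08
    p_tox_variant_red: float = 0.044
    p_tox_wt_std: float = 0.026

    p_hosp_variant_std: float = 0.4
    p_hosp_variant_red: float = 0.54
    p_hosp_wt_std: float = 0.6

    p_trtdeath_variant_std: float = 0.002
    p_trtdeath_variant_red: float = 0.0002
    p_trtdeath_wt_std: float = 0.0001

    p_progress: float = 0.11
    p_death_progressed: float = 0.051

    cost_drug_monthly_full: float = 115.56
    cost_unit_per_500mg: float = 0.64
    cost_test: float = 174.81
    cost_hosp: float = 12_907.0

    u_pf: float = 0.715
    u_prog: float = 0.443
    disutil_hosp: float = 0.28
    disutil_tox: float = 0.125

    hosp_los_days: float = 5.0
    cycle_length_days: float = 30.0
    dose_fractions: tuple[float, float, float] = (1.0, 0.75, 0.5)

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} = {v} is not a probability in [0, 1]")
        for name in _UTILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} = {v} is not a utility in [0, 1]")
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} = {v} must be >= 0")
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if v <= 0:
                raise ParameterError(f"{name} = {v} must be > 0")
        if not 0.0 <= self.discount_rate_annual <= 1.0:
            raise ParameterError(f"discount_rate_annual = {self.discount_rate_annual}")
        if self.start_age < 0:
            raise ParameterError(f"start_age = {self.start_age}")
        df = tuple(float(x) for x in self.dose_fractions)
        object.__setattr__(self, "dose_fractions", df)
        if not (df[0] > df[1] > df[2] > 0):
            raise ParameterError(
                f"dose_fractions must be strictly decreasing and positive, got {df}"
            )

    # -- convenience -------------------------------------------------------
    def replace(self, **overrides) -> "ModelParameters":
        """Copy with fields replaced; revalidates."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dose_fractions"] = list(d["dose_fractions"])
        return d

    @property
    def discount_factor_monthly(self) -> float:
        """Per-cycle discount factor, (1 + annual rate) ** (-1/12)."""
        return (1.0 + self.discount_rate_annual) ** (-1.0 / 12.0)


def default_parameters() -> ModelParameters:
    """The base-case parameter set (all published point estimates)."""
    return ModelParameters()


def load_parameters(config_text: str) -> ModelParameters:
    """Build a parameter set from a YAML mapping of field overrides.

    Unknown keys and out-of-range values raise :class:`ParameterError`.
    An empty document returns the defaults.
    """
    data = yaml.safe_load(config_text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ParameterError("config must be a mapping of parameter names to values")
    overrides = {}
    for key, value in data.items():
        if isinstance(value, (list, tuple)):
            overrides[key] = tuple(value)
        else:
            overrides[key] = value
    return default_parameters().replace(**overrides)


def parameters_to_config(params: ModelParameters) -> str:
    """Serialize a parameter set to YAML; inverse of :func:`load_parameters`."""
    return yaml.safe_dump(params.to_dict(), sort_keys=True)


def parameters_to_json(params: ModelParameters) -> str:
    """Full parameter dump for provenance records."""
    return json.dumps(params.to_dict(), indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# the published uncertainty table
# --------------------------------------------------------------------------

def _pm25(base: float) -> tuple[float, float]:
    return base * 0.75, base * 1.25


def table1_specs() -> list[ParameterSpec]:
    """Published distributions and ranges for every uncertain parameter.

    Betas are (alpha, beta); Gammas are (mean, sd), moment-matched to
    shape/scale at sampling time; Triangulars are (min, max, mode).
    Ranges without a published interval default to +/- 25% of the base
    case; the variant prevalence uses the literature range 3-8%.
    """
    b = default_parameters()

    def spec(name, dist, low=None, high=None, units=""):
        base = getattr(b, name)
        if low is None:
            low, high = _pm25(base)
        return ParameterSpec(name, base, low, high, dist, units)

    return [
        spec("p_variant", DistributionSpec("beta", 6.3, 93), 0.03, 0.08, "probability"),
        spec("p_tox_variant_std", DistributionSpec("beta", 8.6, 94.5), units="1/month"),
        spec("p_tox_variant_red", DistributionSpec("beta", 3, 65.5), units="1/month"),
        spec("p_tox_wt_std", DistributionSpec("beta", 23, 879), units="1/month"),
        spec("p_hosp_variant_std", DistributionSpec("beta", 12, 18.9), units="probability"),
        spec("p_hosp_variant_red", DistributionSpec("beta", 41.6, 35.4), units="probability"),
        spec("p_hosp_wt_std", DistributionSpec("beta", 28.4, 18.9), units="probability"),
        spec(
            "p_trtdeath_variant_std",
            DistributionSpec("triangular", 0.001, 0.003, 0.002),
            0.001,
            0.003,
            "1/month",
        ),
        spec(
            "p_trtdeath_variant_red",
            DistributionSpec("triangular", 0.0001, 0.0003, 0.0002),
            0.0001,
            0.0003,
            "1/month",
        ),
        spec(
            "p_trtdeath_wt_std",
            DistributionSpec("triangular", 0.0, 0.0002, 0.0001),
            0.0,
            0.0002,
            "1/month",
        ),
        spec("p_progress", DistributionSpec("beta", 11, 89), units="1/month"),
        spec("p_death_progressed", DistributionSpec("beta", 5.1, 95), units="1/month"),
        spec("cost_drug_monthly_full", DistributionSpec("gamma_mean_sd", 116, 29), units="USD"),
        spec("cost_test", DistributionSpec("gamma_mean_sd", 174, 44), units="USD"),
        spec("cost_hosp", DistributionSpec("gamma_mean_sd", 12_907, 6450), units="USD"),
        spec("u_pf", DistributionSpec("beta", 7.2, 2.9), units="utility"),
        spec("u_prog", DistributionSpec("beta", 4.4, 5.6), units="utility"),
        spec("disutil_hosp", DistributionSpec("beta", 28, 72), units="utility decrement"),
        spec("disutil_tox", DistributionSpec("beta", 13.9, 97), units="utility decrement"),
    ]


def dsa_specs() -> list[ParameterSpec]:
    """Specs entering the deterministic (one-way/tornado) analyses."""
    return [s for s in table1_specs() if s.varies_in_dsa]


def sample_parameters(
    base: ModelParameters,
    specs: Sequence[ParameterSpec],
    rng: np.random.Generator,
) -> ModelParameters:
    """One joint PSA draw: each spec'd field replaced by an independent draw.

    Fields without a spec (or with a ``fixed`` distribution) keep their
    base value.  Probability and utility draws are valid by construction
    (Beta in (0,1), Triangular within its bounds); the record revalidates
    on construction regardless.
    """
    valid = {f.name for f in dataclasses.fields(base)}
    overrides = {}
    for spec in specs:
        if spec.name not in valid:
            raise ParameterError(f"spec names unknown field {spec.name!r}")
        if spec.distribution is None:
            continue
        overrides[spec.name] = sample_value(spec.distribution, rng)
    return base.replace(**overrides)
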