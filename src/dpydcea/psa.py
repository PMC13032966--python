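"""Probabilistic sensitivity analysis.

Each iteration draws one joint parameter set from the published
distributions and evaluates *both* strategy arms on it (common draw), so
the incremental distribution reflects parameter uncertainty rather than
sampling noise between arms.  Summaries: fraction of draws cost-effective
at a willingness-to-pay threshold (positive incremental net monetary
benefit), fraction cost-saving (lower cost, higher QALYs), and the
cost-effectiveness acceptability curve over a threshold grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import RunSettings, run_cohort
from .lifetable import LifeTable
from .outcomes import CEResult, StrategyResult, compare
from .parameters import (
    ModelParameters,
    ParameterSpec,
    sample_parameters,
    table1_specs,
)
from .treatment import Strategy

__all__ = ["PSADraw", "PSAResult", "run_psa", "ceac"]


@dataclass(frozen=True)
class PSADraw:
    """One PSA iteration: the sampled parameters and paired arm results."""

    index: int
    params: ModelParameters
    no_genotyping: StrategyResult
    genotyping: StrategyResult
    ce: CEResult


@dataclass(frozen=True)
class PSAResult:
    """All PSA iterations with summary accessors."""

    draws: list[PSADraw]
    seed: int
    wtp: float

    @property
    def n(self) -> int:
        return len(self.draws)

    @property
    def inc_cost(self) -> np.ndarray:
        return np.array([d.ce.inc_cost for d in self.draws])

    @property
    def inc_qaly(self) -> np.ndarray:
        return np.array([d.ce.inc_qaly for d in self.draws])

    def fraction_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of draws with positive incremental NMB at ``wtp``."""
        wtp = self.wtp if wtp is None else wtp
        nmb = self.inc_qaly * wtp - self.inc_cost
        return float(np.mean(nmb > 0))

    @property
    def fraction_cost_saving(self) -> float:
        """Fraction of draws where genotyping is dominant (cheaper, better)."""
        return float(np.mean((self.inc_cost < 0) & (self.inc_qaly > 0)))

    def scatter_frame(self) -> pd.DataFrame:
        """Plot-ready incremental scatter, one row per iteration."""
        return pd.DataFrame(
            {
                "iteration": [d.index for d in self.draws],
                "inc_cost": self.inc_cost,
                "inc_qaly": self.inc_qaly,
                "icer_per_qaly": [d.ce.icer_per_qaly for d in self.draws],
                "classification": [d.ce.classification for d in self.draws],
            }
        )

    def sampled_frame(self, fields: Sequence[str]) -> pd.DataFrame:
        """Sampled parameter values per iteration for the given fields."""
        return pd.DataFrame(
            {f: [getattr(d.params, f) for d in self.draws] for f in fields}
        )

    def summary(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "wtp": self.wtp,
            "fraction_cost_effective": self.fraction_cost_effective(),
            "fraction_cost_saving": self.fraction_cost_saving,
            "mean_inc_cost": float(self.inc_cost.mean()),
            "mean_inc_qaly": float(self.inc_qaly.mean()),
        }


def run_psa(
    n: int,
    seed: int,
    base: ModelParameters,
    specs: Sequence[ParameterSpec] | None = None,
    lt: LifeTable | None = None,
    settings: RunSettings | None = None,
) -> PSAResult:
    """Run ``n`` common-draw Monte-Carlo iterations.

    Reproducible for a fixed ``seed``: each iteration samples from a
    substream spawned deterministically from the run-level seed, so the
    result is invariant to evaluation order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if lt is None:
        from .lifetable import gompertz_lifetable

        lt = gompertz_lifetable()
    specs = table1_specs() if specs is None else list(specs)
    root = np.random.SeedSequence(seed)
    draws = []
    for i, child in enumerate(root.spawn(n)):
        rng = np.random.default_rng(child)
        params = sample_parameters(base, specs, rng)
        ref = run_cohort(Strategy.NO_GENOTYPING, params, lt, settings).totals()
        cmp_ = run_cohort(Strategy.GENOTYPING, params, lt, settings).totals()
        draws.append(
            PSADraw(
                index=i,
                params=params,
                no_genotyping=ref,
                genotyping=cmp_,
                ce=compare(ref, cmp_, base.wtp),
            )
        )
    return PSAResult(draws=draws, seed=seed, wtp=base.wtp)


def ceac(result: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a WTP grid.

    At zero willingness to pay the acceptable fraction reduces to the
    fraction of cost-saving-or-free draws; the curve need not be monotone.
    """
    grid = list(wtp_grid)
    if not grid:
        raise ValueError("wtp_grid must be non-empty")
    return pd.DataFrame(
        {
            "wtp": grid,
            "fraction_cost_effective": [
                result.fraction_cost_effective(w) for w in grid
            ],
        }
    )
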