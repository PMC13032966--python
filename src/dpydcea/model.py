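"""High-level modelling interface.

:class:`DecisionModel` bundles a parameter set, a background-mortality
table and structural run settings; :meth:`DecisionModel.fit` evaluates
both strategy arms and returns a :class:`CEAResults` object carrying the
per-arm totals, the incremental comparison, and a printable summary
table.  Sensitivity, probabilistic and validation analyses are methods of
the model so that every analysis shares one configuration.

Example
-------
>>> from dpydcea import DecisionModel
>>> res = DecisionModel().fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import CohortTrace, RunSettings, run_cohort
from .lifetable import LifeTable, gompertz_lifetable
from .microsim import MicrosimResult, compare_with_cohort, simulate_patients
from .outcomes import CEResult, StrategyResult, compare
from .parameters import (
    ModelParameters,
    ParameterSpec,
    default_parameters,
    dsa_specs,
    load_parameters,
    table1_specs,
)
from .psa import PSAResult, run_psa
from .sensitivity import TornadoEntry, one_way, sweep_frame, tornado
from .treatment import Strategy

__all__ = ["DecisionModel", "CEAResults"]


class DecisionModel:
    """Cost-effectiveness model of DPYD genotyping before capecitabine.

    Parameters
    ----------
    params
        Model inputs; defaults to the published base case.
    life_table
        Background mortality; defaults to the bundled Gompertz
        approximation of US female mortality.
    settings
        Structural run options (horizon, half-cycle correction, scenario
        flags).
    """

    def __init__(
        self,
        params: ModelParameters | None = None,
        life_table: LifeTable | None = None,
        settings: RunSettings | None = None,
    ):
        self.params = params or default_parameters()
        self.life_table = life_table or gompertz_lifetable()
        self.settings = settings or RunSettings()

    @classmethod
    def from_config(cls, config_text: str, **kwargs) -> "DecisionModel":
        """Build a model from a YAML document of parameter overrides."""
        return cls(params=load_parameters(config_text), **kwargs)

    # -- core evaluation ---------------------------------------------------
    def run_arm(self, strategy: Strategy) -> CohortTrace:
        """Cohort trace of a single strategy arm."""
        return run_cohort(strategy, self.params, self.life_table, self.settings)

    def fit(self) -> "CEAResults":
        """Evaluate both arms and return the incremental results."""
        ref = self.run_arm(Strategy.NO_GENOTYPING)
        cmp_ = self.run_arm(Strategy.GENOTYPING)
        return CEAResults(
            model=self,
            traces={s.strategy: s for s in (ref, cmp_)},
            no_genotyping=ref.totals(),
            genotyping=cmp_.totals(),
        )

    # -- analyses ----------------------------------------------------------
    def one_way(
        self, param_name: str, low: float, high: float, n_points: int = 11
    ) -> pd.DataFrame:
        pts = one_way(
            param_name, low, high, self.params, self.life_table, n_points, self.settings
        )
        return sweep_frame(pts, param_name)

    def prevalence_sweep(
        self, low: float = 0.03, high: float = 0.08, n_points: int = 11
    ) -> pd.DataFrame:
        """One-way sweep of the DPYD variant prevalence (default 3-8%)."""
        return self.one_way("p_variant", low, high, n_points)

    def tornado(self, specs: Sequence[ParameterSpec] | None = None) -> list[TornadoEntry]:
        return tornado(
            specs if specs is not None else dsa_specs(),
            self.params,
            self.life_table,
            self.settings,
        )

    def psa(
        self, n: int = 10_000, seed: int = 0, specs: Sequence[ParameterSpec] | None = None
    ) -> PSAResult:
        return run_psa(
            n, seed, self.params, specs or table1_specs(), self.life_table, self.settings
        )

    def simulate(
        self, n_patients: int, strategy: Strategy, seed: int = 0
    ) -> MicrosimResult:
        """Individual-level microsimulation of one arm (validation oracle)."""
        rng = np.random.default_rng(seed)
        return simulate_patients(
            n_patients, strategy, self.params, self.life_table, rng, self.settings
        )

    def validate(self, n_patients: int = 200_000, seed: int = 0) -> pd.DataFrame:
        """Cohort-vs-microsimulation agreement table (z-scores) per arm."""
        frames = []
        for i, strategy in enumerate(Strategy):
            micro = self.simulate(n_patients, strategy, seed=seed + i)
            df = compare_with_cohort(micro, self.run_arm(strategy).totals())
            df.insert(0, "strategy", strategy.value)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CEAResults:
    """Fitted results: per-arm totals and the incremental comparison."""

    model: DecisionModel
    traces: dict
    no_genotyping: StrategyResult
    genotyping: StrategyResult

    @property
    def ce(self) -> CEResult:
        return compare(self.no_genotyping, self.genotyping, self.model.params.wtp)

    # convenience accessors
    @property
    def icer_per_qaly(self) -> float:
        return self.ce.icer_per_qaly

    @property
    def icer_per_ly(self) -> float:
        return self.ce.icer_per_ly

    @property
    def nmb(self) -> float:
        return self.ce.nmb

    def arm_frame(self) -> pd.DataFrame:
        """Per-arm totals, one row per strategy."""
        rows = []
        for r in (self.no_genotyping, self.genotyping):
            rows.append(
                {
                    "strategy": r.strategy,
                    "cost": r.total_cost,
                    "qaly": r.total_qaly,
                    "ly": r.total_ly,
                    "cost_undiscounted": r.undiscounted_cost,
                    "qaly_undiscounted": r.undiscounted_qaly,
                    "ly_undiscounted": r.undiscounted_ly,
                    **{f"cost_{k}": v for k, v in r.cost_breakdown.items()},
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        ce = self.ce
        return {
            "no_genotyping": {
                "cost": self.no_genotyping.total_cost,
                "qaly": self.no_genotyping.total_qaly,
                "ly": self.no_genotyping.total_ly,
            },
            "genotyping": {
                "cost": self.genotyping.total_cost,
                "qaly": self.genotyping.total_qaly,
                "ly": self.genotyping.total_ly,
            },
            "incremental": {
                "cost": ce.inc_cost,
                "qaly": ce.inc_qaly,
                "ly": ce.inc_ly,
                "icer_per_qaly": ce.icer_per_qaly,
                "icer_per_ly": ce.icer_per_ly,
                "nmb": ce.nmb,
                "wtp": ce.wtp,
                "classification": ce.classification,
            },
        }

    def summary(self) -> str:
        """Human-readable results table."""
        ce = self.ce
        df = self.arm_frame()[["strategy", "cost", "qaly", "ly"]].copy()
        lines = [
            "Cost-effectiveness of DPYD genotyping vs no genotyping",
            "-" * 56,
            df.to_string(index=False, float_format=lambda x: f"{x:,.3f}"),
            "-" * 56,
            f"incremental cost   : ${ce.inc_cost:,.2f}",
            f"incremental QALYs  : {ce.inc_qaly:.5f}",
            f"incremental LYs    : {ce.inc_ly:.5f}",
            f"ICER               : ${ce.icer_per_qaly:,.0f}/QALY, "
            f"${ce.icer_per_ly:,.0f}/LY",
            f"NMB @ ${ce.wtp:,.0f}/QALY: ${ce.nmb:,.2f} ({ce.classification})",
        ]
        return "\n".join(lines)
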