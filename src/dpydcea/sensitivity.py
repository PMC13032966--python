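"""Deterministic sensitivity analysis: one-way sweeps and tornado ordering.

Each sweep point re-runs both strategy arms with a single parameter moved
and everything else at base case; the tornado ranks parameters by the
absolute ICER excursion between their low and high endpoints (base value
plus/minus 25% unless a published range exists, as encoded in the
parameter specs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import RunSettings, run_cohort
from .lifetable import LifeTable
from .outcomes import CEResult, compare
from .parameters import ModelParameters, ParameterSpec, ParameterError
from .treatment import Strategy

__all__ = ["TornadoEntry", "one_way", "tornado", "sweep_frame", "tornado_frame"]


def _evaluate(params: ModelParameters, lt: LifeTable, settings) -> CEResult:
    ref = run_cohort(Strategy.NO_GENOTYPING, params, lt, settings).totals()
    cmp_ = run_cohort(Strategy.GENOTYPING, params, lt, settings).totals()
    return compare(ref, cmp_, params.wtp)


def one_way(
    param_name: str,
    low: float,
    high: float,
    base: ModelParameters,
    lt: LifeTable,
    n_points: int = 11,
    settings: RunSettings | None = None,
) -> list[tuple[float, CEResult]]:
    """Evaluate the incremental result on an equally spaced parameter grid.

    ``low == high`` degenerates to a single evaluation at that value.
    """
    if low > high:
        raise ParameterError(f"low {low} must be <= high {high}")
    if n_points < 1:
        raise ParameterError("n_points must be >= 1")
    values = [low] if low == high else list(np.linspace(low, high, n_points))
    out = []
    for v in values:
        params = base.replace(**{param_name: v})
        out.append((float(v), _evaluate(params, lt, settings)))
    return out


@dataclass(frozen=True)
class TornadoEntry:
    """One tornado bar: ICERs at a parameter's low and high endpoints."""

    name: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def tornado(
    specs: Sequence[ParameterSpec],
    base: ModelParameters,
    lt: LifeTable,
    settings: RunSettings | None = None,
) -> list[TornadoEntry]:
    """One entry per DSA parameter, sorted by ICER span descending.

    Ties (including zero-influence parameters) break alphabetically so the
    ordering is invariant to the input order of ``specs``.
    """
    active = [s for s in specs if s.varies_in_dsa]
    if not active:
        raise ParameterError("tornado requires at least one spec with varies_in_dsa")
    entries = []
    for spec in sorted(active, key=lambda s: s.name):
        icers = {}
        for bound in (spec.low, spec.high):
            params = base.replace(**{spec.name: bound})
            icers[bound] = _evaluate(params, lt, settings).icer_per_qaly
        entries.append(
            TornadoEntry(
                name=spec.name,
                low=spec.low,
                high=spec.high,
                icer_low=icers[spec.low],
                icer_high=icers[spec.high],
            )
        )
    return sorted(entries, key=lambda e: (-e.span, e.name))


def sweep_frame(points: list[tuple[float, CEResult]], param_name: str) -> pd.DataFrame:
    """Long-format plot-ready table of a one-way sweep."""
    return pd.DataFrame(
        {
            "parameter": param_name,
            "value": [v for v, _ in points],
            "inc_cost": [r.inc_cost for _, r in points],
            "inc_qaly": [r.inc_qaly for _, r in points],
            "inc_ly": [r.inc_ly for _, r in points],
            "icer_per_qaly": [r.icer_per_qaly for _, r in points],
            "nmb": [r.nmb for _, r in points],
            "classification": [r.classification for _, r in points],
        }
    )


def tornado_frame(entries: Sequence[TornadoEntry], top: int | None = 6) -> pd.DataFrame:
    """Tornado table (top-``top`` bars by span; ``None`` keeps all)."""
    rows = entries if top is None else entries[:top]
    return pd.DataFrame(
        {
            "parameter": [e.name for e in rows],
            "low": [e.low for e in rows],
            "high": [e.high for e in rows],
            "icer_low": [e.icer_low for e in rows],
            "icer_high": [e.icer_high for e in rows],
            "span": [e.span for e in rows],
        }
    )
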