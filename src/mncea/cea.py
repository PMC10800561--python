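"""Incremental cost-effectiveness accounting: ICER, NMB and the WTP rule."""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CohortTrace

#: dominance flags
DOMINANT = "dominant"  # intervention cheaper and more effective
DOMINATED = "dominated"  # intervention costlier and less effective
INDIFFERENT = "indifferent"  # no cost or effect difference
RATIO = "ratio"  # a meaningful ICER exists

_EPS = 1e-12


def net_monetary_benefit(cost, qaly, wtp: float):
    """NMB = WTP x QALY - cost."""
    return wtp * np.asarray(qaly, dtype=float) - np.asarray(cost, dtype=float)


def wtp_from_gdp(gdp_per_capita: float, multiple: float = 3.0) -> float:
    """Willingness-to-pay threshold as a multiple of per-capita GDP."""
    if gdp_per_capita <= 0:
        raise ValueError("GDP per capita must be positive")
    return multiple * gdp_per_capita


def icer(delta_cost: float, delta_qaly: float) -> tuple[float, str]:
    """Incremental cost-effectiveness ratio with a dominance flag.

    Returns ``(ratio, flag)``; the ratio is NaN whenever the sign pattern
    makes it meaningless (dominance or indifference).
    """
    dc, dq = float(delta_cost), float(delta_qaly)
    if abs(dc) < _EPS and abs(dq) < _EPS:
        return math.nan, INDIFFERENT
    if dq > 0 and dc <= 0:
        return math.nan, DOMINANT
    if dq <= 0 and dc > 0:
        return math.nan, DOMINATED
    if abs(dq) < _EPS:
        return math.inf if dc > 0 else -math.inf, RATIO
    return dc / dq, RATIO


@dataclass
class CEAResult:
    """Two-strategy comparison at a willingness-to-pay threshold.

    The intervention (strategy a) is compared against the comparator
    (strategy b): positive deltas mean the intervention costs more / yields
    more QALYs.
    """

    intervention: str
    comparator: str
    yearly: pd.DataFrame  # columns strategy, year, cum_cost, cum_qaly
    delta_cost: float
    delta_qaly: float
    icer: float
    dominance: str
    wtp: float
    nmb_intervention: float
    nmb_comparator: float

    @property
    def cost_effective(self) -> bool:
        """Intervention preferred at the WTP threshold (higher NMB)."""
        return self.nmb_intervention > self.nmb_comparator

    def to_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "comparator": self.comparator,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
            "wtp": self.wtp,
            "nmb_intervention": self.nmb_intervention,
            "nmb_comparator": self.nmb_comparator,
            "cost_effective": self.cost_effective,
            "yearly": self.yearly.to_dict(orient="records"),
        }


def compare_totals(
    cost_a: float,
    qaly_a: float,
    cost_b: float,
    qaly_b: float,
    wtp: float,
) -> dict:
    """Incremental comparison from cumulative totals (a vs b)."""
    dc = float(cost_a) - float(cost_b)
    dq = float(qaly_a) - float(qaly_b)
    ratio, flag = icer(dc, dq)
    return {
        "delta_cost": dc,
        "delta_qaly": dq,
        "icer": ratio,
        "dominance": flag,
        "nmb_a": float(net_monetary_benefit(cost_a, qaly_a, wtp)),
        "nmb_b": float(net_monetary_benefit(cost_b, qaly_b, wtp)),
    }


def compare_strategies(trace_a: CohortTrace, trace_b: CohortTrace, wtp: float) -> CEAResult:
    """Compare two cohort traces sharing conventions and horizon."""
    if trace_a.n_cycles != trace_b.n_cycles:
        raise ValueError("traces have mismatched horizons")
    if trace_a.convention != trace_b.convention:
        raise ValueError("traces have mismatched cycle conventions")
    cost_a, qaly_a = (float(np.squeeze(x)) for x in trace_a.cumulative())
    cost_b, qaly_b = (float(np.squeeze(x)) for x in trace_b.cumulative())
    core = compare_totals(cost_a, qaly_a, cost_b, qaly_b, wtp)
    yearly = pd.concat(
        [trace_a.yearly_summary(), trace_b.yearly_summary()], ignore_index=True
    )
    return CEAResult(
        intervention=trace_a.strategy,
        comparator=trace_b.strategy,
        yearly=yearly,
        delta_cost=core["delta_cost"],
        delta_qaly=core["delta_qaly"],
        icer=core["icer"],
        dominance=core["dominance"],
        wtp=float(wtp),
        nmb_intervention=core["nmb_a"],
        nmb_comparator=core["nmb_b"],
    )
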