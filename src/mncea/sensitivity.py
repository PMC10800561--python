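"""One-way (tornado) and probabilistic (Monte Carlo) sensitivity analyses.

The probabilistic analysis draws every non-fixed parameter jointly and
independently from its fitted Beta/Gamma distribution, recalibrates the
remission dynamics per draw, reruns both treatment arms, and summarises the
incremental cost and QALY cloud as cost-effectiveness acceptability curves
(CEAC) and cost-effectiveness-plane scatter data.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import compare_totals, net_monetary_benefit
from .markov import (
    CalibrationError,
    build_strategy,
    calibrate_remission_probs,
    run_cohort,
)
from .parameters import Family, ParameterTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

def _deterministic_icer(table: ParameterTable, values, horizon_years: int) -> float:
    """Signed incremental cost per incremental QALY at one parameter setting."""
    conv = table.convention(horizon_years)
    traces = {
        name: run_cohort(build_strategy(name, values, table, conv), conv)
        for name in ("RTX", "TAC")
    }
    (ca, qa), (cb, qb) = traces["RTX"].cumulative(), traces["TAC"].cumulative()
    dq = float(qa) - float(qb)
    dc = float(ca) - float(cb)
    if dq == 0.0:
        return float(np.inf) if dc > 0 else float(-np.inf) if dc < 0 else 0.0
    return dc / dq


def one_way_dsa(
    table: ParameterTable,
    varied: list[str] | None = None,
    horizon_years: int | None = None,
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low/high bound, others at mean.

    Parameters without a usable range are skipped with a warning.  The result
    is sorted by span (|icer_high - icer_low|), descending, and includes the
    base-case ICER for reference.
    """
    horizon = int(horizon_years or table.settings.get("horizon_years", 5))
    base_values = table.values()
    base_icer = _deterministic_icer(table, base_values, horizon)
    rows = []
    for name in varied if varied is not None else table.names():
        spec = table[name]
        if not spec.has_range:
            warnings.warn(f"parameter {name} has no range; skipped in DSA")
            continue
        icers = {}
        for bound, value in (("low", spec.low), ("high", spec.high)):
            values = dict(base_values)
            values[name] = value
            try:
                icers[bound] = _deterministic_icer(table, values, horizon)
            except CalibrationError:
                icers[bound] = np.nan
        rows.append(
            {
                "parameter": name,
                "low": spec.low,
                "high": spec.high,
                "icer_at_low": icers["low"],
                "icer_at_high": icers["high"],
                "span": abs(icers["high"] - icers["low"]),
                "base_icer": base_icer,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("span", ascending=False, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    """Monte Carlo draws and derived acceptability curves.

    ``samples`` has one row per draw per horizon with per-arm discounted
    cumulative cost/QALY and the incrementals; ``ceac`` holds the probability
    that the intervention is cost-effective at the WTP per horizon.
    """

    samples: pd.DataFrame
    ceac: pd.DataFrame
    wtp: float
    seed: int
    iterations: int
    n_rejected: int
    parameter_draws: pd.DataFrame | None = None

    def horizon_slice(self, horizon: int) -> pd.DataFrame:
        return self.samples[self.samples["horizon"] == horizon].reset_index(drop=True)


def _sample_values(table: ParameterTable, rng: np.random.Generator, size: int) -> dict:
    """One joint, independent draw per parameter; fixed ones stay at the mean."""
    values: dict[str, np.ndarray] = {}
    for name in table.names():
        spec = table[name]
        if spec.family is Family.FIXED:
            values[name] = np.full(size, spec.mean, dtype=float)
        else:
            values[name] = spec.fitted().sample(rng, size)
    return values


def _feasible(values: dict, size: int, table: ParameterTable) -> np.ndarray:
    """Joint draws whose remission calibration is attainable.

    A draw is rejected when the sampled 12-month CR/PR targets cannot be
    reached by any stochastic transition row (their sum is too large, or the
    sampled relapse hazard caps the attainable remission occupancy).
    """
    from .markov import calibrate_cycle_probability, shared_cycle_probabilities

    m = int(table.settings.get("cycles_per_year", 12))
    shared = shared_cycle_probabilities(values, m)
    ok = np.ones(size, dtype=bool)
    for arm in ("rtx", "tac"):
        t_cr = values[f"calib.{arm}_cr_12m"]
        t_pr = values[f"calib.{arm}_pr_12m"]
        p_rel = calibrate_cycle_probability(values[f"calib.{arm}_relapse_12m"], m)
        _, _, converged = calibrate_remission_probs(
            t_cr, t_pr, p_rel, shared, n_cycles=m, on_fail="mask"
        )
        ok &= converged
    return ok


def run_psa(
    table: ParameterTable,
    iterations: int,
    seed: int,
    horizons: tuple[int, ...] | None = None,
    wtp: float | None = None,
    keep_parameter_draws: bool = False,
    max_resample_rounds: int = 100,
) -> PSAResult:
    """Monte Carlo PSA over the fitted parameter distributions.

    Bit-exact reproducible for a fixed seed and iteration count.  Joint draws
    whose sampled 12-month remission targets cannot form a stochastic
    transition row are rejected and resampled (the count is reported).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    wtp = float(wtp if wtp is not None else table.settings.get("wtp_per_qaly", 257094.0))
    horizons = tuple(
        horizons
        if horizons is not None
        else range(1, int(table.settings.get("horizon_years", 5)) + 1)
    )
    max_h = max(horizons)
    rng = np.random.default_rng(seed)
    values = _sample_values(table, rng, iterations)
    ok = _feasible(values, iterations, table)
    n_rejected = int((~ok).sum())
    rounds = 0
    while not ok.all():
        rounds += 1
        if rounds > max_resample_rounds:
            raise CalibrationError("too many infeasible PSA draws")
        idx = np.flatnonzero(~ok)
        redraw = _sample_values(table, rng, idx.size)
        for name, arr in values.items():
            arr[idx] = redraw[name]
        ok2 = _feasible(values, iterations, table)
        n_rejected += int((~ok2[idx]).sum())
        ok = ok2
    if n_rejected:
        log.info("PSA: resampled %d infeasible joint draws", n_rejected)

    conv = table.convention(max_h)
    traces = {
        name: run_cohort(build_strategy(name, values, table, conv), conv)
        for name in ("RTX", "TAC")
    }
    m = conv.cycles_per_year
    frames = []
    for h in horizons:
        cost_r, qaly_r = traces["RTX"].cumulative(h * m)
        cost_t, qaly_t = traces["TAC"].cumulative(h * m)
        frames.append(
            pd.DataFrame(
                {
                    "draw": np.arange(iterations),
                    "horizon": h,
                    "cost_rtx": cost_r,
                    "qaly_rtx": qaly_r,
                    "cost_tac": cost_t,
                    "qaly_tac": qaly_t,
                    "delta_cost": cost_r - cost_t,
                    "delta_qaly": qaly_r - qaly_t,
                }
            )
        )
    samples = pd.concat(frames, ignore_index=True)
    ceac = ceac_by_horizon(samples, wtp)
    draws = None
    if keep_parameter_draws:
        draws = pd.DataFrame(values)
    return PSAResult(samples, ceac, wtp, seed, iterations, n_rejected, draws)


def prob_cost_effective(samples: pd.DataFrame, wtp: float) -> float:
    """Fraction of draws in which the intervention has the higher NMB."""
    dnmb = wtp * samples["delta_qaly"].to_numpy() - samples["delta_cost"].to_numpy()
    return float((dnmb > 0).mean())


def ceac_by_horizon(samples: pd.DataFrame, wtp: float) -> pd.DataFrame:
    rows = [
        {
            "horizon": int(h),
            "wtp": wtp,
            "probability": prob_cost_effective(g, wtp),
        }
        for h, g in samples.groupby("horizon")
    ]
    return pd.DataFrame(rows).sort_values("horizon", ignore_index=True)


def ceac_curve(
    samples: pd.DataFrame, wtp_grid: np.ndarray, horizon: int
) -> pd.DataFrame:
    """Acceptability curve over a WTP grid at a fixed horizon."""
    sl = samples[samples["horizon"] == horizon]
    dq = sl["delta_qaly"].to_numpy()
    dc = sl["delta_cost"].to_numpy()
    rows = [
        {"horizon": horizon, "wtp": float(w), "probability": float((w * dq - dc > 0).mean())}
        for w in np.asarray(wtp_grid, dtype=float)
    ]
    return pd.DataFrame(rows)


def ce_plane_export(
    samples: pd.DataFrame, horizon: int, wtp: float
) -> tuple[pd.DataFrame, dict]:
    """Scatter data for the cost-effectiveness plane plus quadrant counts.

    The threshold line through the origin has slope ``wtp`` (cost per QALY).
    """
    sl = samples[samples["horizon"] == horizon]
    if sl.empty:
        raise ValueError(f"no PSA draws at horizon {horizon}")
    scatter = sl[["draw", "delta_qaly", "delta_cost"]].reset_index(drop=True)
    dq = scatter["delta_qaly"].to_numpy()
    dc = scatter["delta_cost"].to_numpy()
    meta = {
        "horizon": horizon,
        "threshold_slope": float(wtp),
        "n_draws": int(len(scatter)),
        "quadrants": {
            "ne": int(((dq > 0) & (dc > 0)).sum()),
            "se": int(((dq > 0) & (dc <= 0)).sum()),
            "nw": int(((dq <= 0) & (dc > 0)).sum()),
            "sw": int(((dq <= 0) & (dc <= 0)).sum()),
        },
        "prob_cost_effective": prob_cost_effective(sl, wtp),
    }
    return scatter, meta
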