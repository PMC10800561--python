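"""Cohort engine: transition matrices, constant-hazard calibration, trace accrual.

The engine is vectorised over an optional leading "draw" axis so the same code
path serves the deterministic base case (one draw) and probabilistic
sensitivity analysis (many joint parameter draws at once).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    N_STATES,
    STATE_LABELS,
    CycleConvention,
    HealthState,
    ParameterError,
    ParameterTable,
    annual_prob_to_cycle_prob,
    multi_year_prob_to_annual,
)

S = HealthState


class ModelStructureError(ValueError):
    """A transition-matrix row is not a probability distribution."""


class CalibrationError(RuntimeError):
    """The remission calibration did not converge to the 12-month targets."""


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_cycle_probability(target_cum_prob, n_cycles: int):
    """Per-cycle probability whose ``n_cycles``-fold compounding hits a target.

    Constant-hazard inversion: ``p = 1 - (1 - target)^(1/n)``.
    """
    t = np.asarray(target_cum_prob, dtype=float)
    if np.any(t < 0.0) or np.any(t >= 1.0):
        raise ParameterError("cumulative target probability must lie in [0, 1)")
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    out = -np.expm1(np.log1p(-t) / n_cycles)
    return out if out.ndim else float(out)


def shared_cycle_probabilities(values: Mapping[str, float], cycles_per_year: int = 12) -> dict:
    """Per-cycle probabilities for the downstream (ESRD) transitions.

    Annual rates are converted with the constant-hazard formula; the 10-year
    post-transplant mortality is first reduced to an annual probability.
    """
    a2c = lambda p: annual_prob_to_cycle_prob(p, cycles_per_year)
    kt_annual = multi_year_prob_to_annual(values["transition.kt_mortality_10yr"], 10.0)
    return {
        "hd_entry": a2c(values["transition.hd_incidence"]),
        "pd_entry": a2c(values["transition.pd_incidence"]),
        "hd_to_pd": a2c(values["transition.hd_to_pd"]),
        "pd_to_hd": a2c(values["transition.pd_to_hd"]),
        "hd_to_kt": a2c(values["transition.kt_incidence"]),
        "pd_to_kt": a2c(values["transition.kt_incidence"]),
        "hd_death": a2c(values["transition.hd_mortality"]),
        "pd_death": a2c(values["transition.pd_mortality"]),
        "kt_death": a2c(kt_annual),
    }


def build_transition_matrix(q_cr, q_pr, p_relapse, shared: Mapping[str, float]) -> np.ndarray:
    """Per-cycle row-stochastic matrix, shape ``(..., 8, 8)``.

    Active disease and relapse share the calibrated remission transitions and
    the dialysis-entry exits; remission states share the relapse hazard;
    dialysis and transplant rows carry the converted annual rates; death is
    absorbing.  Residual mass stays in the source state.  Rows whose exits
    exceed 1 raise :class:`ModelStructureError` (no silent rescaling).
    """
    arrays = [np.asarray(x, dtype=float) for x in (q_cr, q_pr, p_relapse)] + [
        np.asarray(shared[k], dtype=float)
        for k in ("hd_entry", "pd_entry", "hd_to_pd", "pd_to_hd",
                  "hd_to_kt", "pd_to_kt", "hd_death", "pd_death", "kt_death")
    ]
    batch = np.broadcast_shapes(*(a.shape for a in arrays))
    (q_cr, q_pr, p_rel, hd_entry, pd_entry, hd_to_pd, pd_to_hd,
     hd_to_kt, pd_to_kt, hd_death, pd_death, kt_death) = (
        np.broadcast_to(a, batch) for a in arrays
    )
    m = np.zeros(batch + (N_STATES, N_STATES), dtype=float)

    def set_row(state: S, exits: dict[S, np.ndarray]) -> None:
        total = np.zeros(batch, dtype=float)
        for dest, p in exits.items():
            if np.any(p < 0.0):
                raise ModelStructureError(f"negative probability in row {state.name}")
            m[..., state, dest] = p
            total = total + p
        if np.any(total > 1.0 + 1e-12):
            raise ModelStructureError(
                f"exit probabilities exceed 1 in row {state.name}"
            )
        m[..., state, state] = 1.0 - total

    active_exits = {
        S.COMPLETE_REMISSION: q_cr,
        S.PARTIAL_REMISSION: q_pr,
        S.HEMODIALYSIS: hd_entry,
        S.PERITONEAL_DIALYSIS: pd_entry,
    }
    set_row(S.ACTIVE, active_exits)
    set_row(S.RELAPSE, active_exits)
    set_row(S.COMPLETE_REMISSION, {S.RELAPSE: p_rel})
    set_row(S.PARTIAL_REMISSION, {S.RELAPSE: p_rel})
    set_row(
        S.HEMODIALYSIS,
        {S.PERITONEAL_DIALYSIS: hd_to_pd, S.KIDNEY_TRANSPLANT: hd_to_kt, S.DEATH: hd_death},
    )
    set_row(
        S.PERITONEAL_DIALYSIS,
        {S.HEMODIALYSIS: pd_to_hd, S.KIDNEY_TRANSPLANT: pd_to_kt, S.DEATH: pd_death},
    )
    set_row(S.KIDNEY_TRANSPLANT, {S.DEATH: kt_death})
    m[..., S.DEATH, S.DEATH] = 1.0
    return m


def _occupancy_after(matrix: np.ndarray, n_cycles: int) -> np.ndarray:
    occ = np.zeros(matrix.shape[:-1], dtype=float)
    occ[..., S.ACTIVE] = 1.0
    for _ in range(n_cycles):
        occ = np.einsum("...i,...ij->...j", occ, matrix)
    return occ


def calibrate_remission_probs(
    target_cr,
    target_pr,
    p_relapse,
    shared: Mapping[str, float],
    n_cycles: int = 12,
    tol: float = 1e-10,
    max_iter: int = 80,
    on_fail: str = "raise",
):
    """Per-cycle active->CR and active->PR probabilities hitting 12-month targets.

    The two competing cause-specific probabilities are solved jointly
    (Newton with finite-difference Jacobian, vectorised over draws) so that
    cohort occupancy of CR and PR after ``n_cycles`` cycles of the full
    eight-state matrix matches the published 12-month proportions.

    With ``on_fail="raise"`` any unreachable target raises
    :class:`CalibrationError`; with ``on_fail="mask"`` the return gains a
    boolean per-draw convergence mask instead (used by the PSA rejection
    loop, since a large sampled relapse hazard can cap the attainable
    12-month remission occupancy).
    """
    if on_fail not in ("raise", "mask"):
        raise ParameterError(f"unknown on_fail mode {on_fail!r}")
    t_cr = np.atleast_1d(np.asarray(target_cr, dtype=float)).copy()
    t_pr = np.atleast_1d(np.asarray(target_pr, dtype=float)).copy()
    p_rel = np.atleast_1d(np.asarray(p_relapse, dtype=float))
    t_cr, t_pr, p_rel = np.broadcast_arrays(t_cr, t_pr, p_rel)
    scalar = np.asarray(target_cr).ndim == 0 and np.asarray(target_pr).ndim == 0
    if np.any((t_cr < 0) | (t_pr < 0) | (t_cr >= 1) | (t_pr >= 1)):
        raise ParameterError("12-month targets must lie in [0, 1)")
    feasible = t_cr + t_pr < 1.0
    if not feasible.all():
        if on_fail == "raise":
            raise CalibrationError("12-month CR + PR targets must sum below 1")
        # benign placeholders keep the vectorised solve numerically sane
        t_cr = np.where(feasible, t_cr, 0.1)
        t_pr = np.where(feasible, t_pr, 0.1)

    exit_extra = np.asarray(shared["hd_entry"], dtype=float) + np.asarray(
        shared["pd_entry"], dtype=float
    )
    # margin exceeds the finite-difference epsilon so perturbed iterates
    # still form a stochastic row
    cap = 1.0 - exit_extra - 1e-6

    def residual(q: np.ndarray) -> np.ndarray:
        mat = build_transition_matrix(q[..., 0], q[..., 1], p_rel, shared)
        occ = _occupancy_after(mat, n_cycles)
        return np.stack(
            [occ[..., S.COMPLETE_REMISSION] - t_cr, occ[..., S.PARTIAL_REMISSION] - t_pr],
            axis=-1,
        )

    # Single-target constant-hazard inversion as the starting point.
    q = np.stack(
        [calibrate_cycle_probability(t_cr, n_cycles), calibrate_cycle_probability(t_pr, n_cycles)],
        axis=-1,
    ).astype(float)
    q = np.clip(q, 1e-12, None)
    eps = 1e-8
    for _ in range(max_iter):
        f = residual(q)
        if np.max(np.abs(f)) < tol:
            break
        # Finite-difference Jacobian, then closed-form 2x2 solve per draw.
        j = np.empty(f.shape + (2,), dtype=float)
        for k in range(2):
            dq = np.zeros_like(q)
            dq[..., k] = eps
            j[..., k] = (residual(q + dq) - f) / eps
        det = j[..., 0, 0] * j[..., 1, 1] - j[..., 0, 1] * j[..., 1, 0]
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        step = np.empty_like(q)
        step[..., 0] = (f[..., 0] * j[..., 1, 1] - f[..., 1] * j[..., 0, 1]) / det
        step[..., 1] = (f[..., 1] * j[..., 0, 0] - f[..., 0] * j[..., 1, 0]) / det
        q = q - step
        total = q[..., 0] + q[..., 1]
        over = total > cap
        if np.any(over):  # keep the active row stochastic during iteration
            scale = np.where(over, cap / np.maximum(total, 1e-300), 1.0)
            q = q * scale[..., None]
        q = np.clip(q, 1e-15, None)
    f = residual(q)
    converged = feasible & (np.abs(f) < 1e-6).all(axis=-1)
    if on_fail == "raise" and not converged.all():
        raise CalibrationError(
            f"remission calibration residual {np.nanmax(np.abs(f)):.2e} exceeds 1e-6"
        )
    if scalar:
        if on_fail == "mask":
            return float(q[0, 0]), float(q[0, 1]), bool(converged[0])
        return float(q[0, 0]), float(q[0, 1])
    if on_fail == "mask":
        return q[..., 0], q[..., 1], converged
    return q[..., 0], q[..., 1]


# ---------------------------------------------------------------------------
# Strategy cost schedules
# ---------------------------------------------------------------------------

#: lump weight sentinel: charge per member of the cohort still alive
ALIVE = "alive"


@dataclass
class StrategyDef:
    """A fully resolved treatment strategy for the cohort engine.

    ``state_cost_terms`` are per-cycle cost-rate vectors, each active during a
    half-open cycle window (``None`` = the whole horizon).  ``lumps`` are
    one-off charges at a given cycle, optionally weighted by occupancy of one
    state (or by the surviving fraction, :data:`ALIVE`).
    """

    name: str
    transition_matrix: np.ndarray  # (..., 8, 8)
    utilities: np.ndarray  # (..., 8)
    state_cost_terms: list[tuple[tuple[int, int] | None, np.ndarray]] = field(
        default_factory=list
    )
    lumps: list[tuple[int, object, np.ndarray]] = field(default_factory=list)


def expected_ae_cost(profile: Sequence[tuple[float, float]]):
    """Expected one-off adverse-event cost of a treatment course.

    ``profile`` holds (incidence per course, cost per event) pairs; the
    expectation is their sum-product, charged once per course.
    """
    total = 0.0
    for incidence, cost in profile:
        inc = np.asarray(incidence, dtype=float)
        c = np.asarray(cost, dtype=float)
        if np.any(inc < 0.0) or np.any(inc > 1.0):
            raise ParameterError("adverse-event incidence must lie in [0, 1]")
        if np.any(c < 0.0):
            raise ParameterError("adverse-event cost must be nonnegative")
        total = total + inc * c
    return total


RTX_AE_PROFILE = [
    ("ae_inc.rtx_rash", "ae_cost.rash"),
    ("ae_inc.rtx_fever", "ae_cost.fever"),
    ("ae_inc.rtx_gi_infection", "ae_cost.gi_infection"),
    ("ae_inc.rtx_pneumonia", "ae_cost.pneumonia"),
]

TAC_AE_PROFILE = [
    ("ae_inc.tac_severe_pneumonia", "ae_cost.pneumonia"),
    ("ae_inc.tac_lung_abscess", "ae_cost.lung_abscess"),
    ("ae_inc.tac_interstitial_pneumonia", "ae_cost.interstitial_pneumonia"),
    ("ae_inc.tac_hyperglycemia", "ae_cost.hyperglycemia"),
]


def _utilities_vector(values: Mapping[str, float]) -> np.ndarray:
    names = [
        "utility.active",
        "utility.cr",
        "utility.pr",
        "utility.relapse",
        "utility.hd",
        "utility.pd",
        "utility.kt",
        "utility.death",
    ]
    cols = [np.asarray(values[n], dtype=float) for n in names]
    batch = np.broadcast_shapes(*(c.shape for c in cols))
    return np.stack([np.broadcast_to(c, batch) for c in cols], axis=-1)


def _esrd_state_costs(values: Mapping[str, float], cycles_per_year: int) -> np.ndarray:
    """Per-cycle cost rates of the dialysis/transplant states (both arms)."""
    hd = np.asarray(values["cost.hd_annual"], dtype=float) / cycles_per_year
    pd_ = np.asarray(values["cost.pd_annual"], dtype=float) / cycles_per_year
    kt = np.asarray(values["cost.kt_annual"], dtype=float) / cycles_per_year
    batch = np.broadcast_shapes(hd.shape, pd_.shape, kt.shape)
    out = np.zeros(batch + (N_STATES,), dtype=float)
    out[..., S.HEMODIALYSIS] = hd
    out[..., S.PERITONEAL_DIALYSIS] = pd_
    out[..., S.KIDNEY_TRANSPLANT] = kt
    return out


def _monitoring_visit_cost(values: Mapping[str, float]) -> np.ndarray:
    return (
        np.asarray(values["cost.urinalysis"], dtype=float)
        + np.asarray(values["cost.rapid_proteinuria"], dtype=float)
        + np.asarray(values["cost.quant_proteinuria"], dtype=float)
        + np.asarray(values["cost.liver_function"], dtype=float)
    )


def rtx_induction_cost(values: Mapping[str, float], settings: Mapping) -> np.ndarray:
    """Cost of one full RTX induction course (whole-vial dispensing).

    375 mg/m2 weekly for four doses; each dose is rounded up to whole
    100 mg vials at the unit vial price.
    """
    dose_mg = float(settings.get("bsa_m2", 1.73)) * float(
        settings.get("rtx_dose_mg_per_m2", 375.0)
    )
    vials = math.ceil(dose_mg / float(settings.get("rtx_vial_mg", 100.0)))
    doses = int(settings.get("rtx_doses_per_course", 4))
    return doses * vials * np.asarray(values["cost.rtx_vial"], dtype=float)


def _methylpred_tablets_per_day(settings: Mapping, cycle: int) -> float:
    """Daily methylprednisolone tablets in the TAC arm at a given cycle.

    Prednisolone 0.5 mg/kg/day for eight weeks, tapered by 5 mg/day every four
    weeks to a 10 mg/day maintenance dose kept through month 12.
    """
    if cycle > 12:
        return 0.0
    weight = float(settings.get("body_weight_kg", 60.0))
    start_mg = float(settings.get("prednisolone_start_mg_per_kg", 0.5)) * weight
    taper = float(settings.get("prednisolone_taper_mg", 5.0))
    maintenance = float(settings.get("prednisolone_maintenance_mg", 10.0))
    mg = start_mg if cycle <= 2 else max(start_mg - taper * (cycle - 2), maintenance)
    # 4 mg methylprednisolone is equipotent to 5 mg prednisolone.
    return mg / 5.0


def build_strategy(
    name: str,
    values: Mapping[str, float],
    table: ParameterTable,
    conv: CycleConvention,
) -> StrategyDef:
    """Resolve a named strategy ("RTX" or "TAC") into matrices and schedules."""
    if name.upper() not in ("RTX", "TAC"):
        raise ParameterError(f"unknown strategy {name!r}")
    settings = table.settings
    m = conv.cycles_per_year
    shared = shared_cycle_probabilities(values, m)
    key = name.lower()
    t_cr = values[f"calib.{key}_cr_12m"]
    t_pr = values[f"calib.{key}_pr_12m"]
    p_rel = calibrate_cycle_probability(values[f"calib.{key}_relapse_12m"], m)
    q_cr, q_pr = calibrate_remission_probs(t_cr, t_pr, p_rel, shared, n_cycles=m)
    matrix = build_transition_matrix(q_cr, q_pr, p_rel, shared)
    utilities = _utilities_vector(values)

    state_terms: list[tuple[tuple[int, int] | None, np.ndarray]] = [
        (None, _esrd_state_costs(values, m))
    ]
    lumps: list[tuple[int, object, np.ndarray]] = []
    visit = _monitoring_visit_cost(values)
    for c in settings.get("monitoring_cycles", [1, 3, 6, 9, 12]):
        lumps.append((int(c), ALIVE, visit))

    if name.upper() == "RTX":
        induction = rtx_induction_cost(values, settings)
        cycles = [int(c) for c in settings.get("rtx_induction_cycles", [1, 2])]
        for c in cycles:
            lumps.append((c, ALIVE, induction / len(cycles)))
        ae = expected_ae_cost(
            [(values[i], values[c]) for i, c in RTX_AE_PROFILE]
        )
        lumps.append((cycles[0], ALIVE, ae))
        # Second full course for the fraction still in partial remission at
        # the six-month evaluation.
        c2 = int(settings.get("rtx_second_course_cycle", 6))
        lumps.append((c2, S.PARTIAL_REMISSION, induction))
        lumps.append((c2, S.PARTIAL_REMISSION, ae))
    elif name.upper() == "TAC":
        six_months = m // 2
        drug = np.zeros(
            np.broadcast_shapes(
                *(
                    np.asarray(values[k]).shape
                    for k in ("cost.tac_6m_cr", "cost.tac_6m_pr",
                              "cost.tac_6m_nr", "cost.tac_6m_relapse")
                )
            )
            + (N_STATES,),
            dtype=float,
        )
        drug[..., S.COMPLETE_REMISSION] = np.asarray(values["cost.tac_6m_cr"]) / six_months
        drug[..., S.PARTIAL_REMISSION] = np.asarray(values["cost.tac_6m_pr"]) / six_months
        drug[..., S.ACTIVE] = np.asarray(values["cost.tac_6m_nr"]) / six_months
        drug[..., S.RELAPSE] = np.asarray(values["cost.tac_6m_relapse"]) / six_months
        duration = settings.get("tac_drug_duration_cycles")
        window = None if duration in (None, "null") else (1, int(duration))
        state_terms.append((window, drug))
        tablet = np.asarray(values["cost.methylpred_tablet"], dtype=float)
        days = conv.cycle_length_days
        for c in range(1, 13):
            tabs = _methylpred_tablets_per_day(settings, c)
            if tabs > 0:
                lumps.append((c, ALIVE, tabs * days * tablet))
        ae = expected_ae_cost(
            [(values[i], values[c]) for i, c in TAC_AE_PROFILE]
        )
        lumps.append((1, ALIVE, ae))
    else:
        raise ParameterError(f"unknown strategy {name!r}")
    return StrategyDef(name.upper(), matrix, utilities, state_terms, lumps)


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Cycle-by-cycle cohort occupancy with cost and QALY accrual.

    ``occupancy`` has shape ``(..., n_cycles + 1, 8)``; row 0 is the initial
    distribution (all mass in active disease).  Per-cycle accruals have shape
    ``(..., n_cycles)``; cycle ``t`` values the state membership at the start
    of the cycle and is discounted by ``(1+r)^(-t/cycles_per_year)``.
    """

    strategy: str
    convention: CycleConvention
    occupancy: np.ndarray
    cycle_cost: np.ndarray
    cycle_cost_disc: np.ndarray
    cycle_qaly: np.ndarray
    cycle_qaly_disc: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.cycle_cost.shape[-1]

    def cumulative(self, upto_cycle: int | None = None, discounted: bool = True):
        n = self.n_cycles if upto_cycle is None else upto_cycle
        cost = self.cycle_cost_disc if discounted else self.cycle_cost
        qaly = self.cycle_qaly_disc if discounted else self.cycle_qaly
        return cost[..., :n].sum(axis=-1), qaly[..., :n].sum(axis=-1)

    def yearly_summary(self, discounted: bool = True) -> pd.DataFrame:
        """Cumulative cost/QALY at each model-year boundary (one-draw traces)."""
        m = self.convention.cycles_per_year
        rows = []
        for year in range(1, self.n_cycles // m + 1):
            cost, qaly = self.cumulative(year * m, discounted)
            rows.append(
                {"strategy": self.strategy, "year": year,
                 "cum_cost": float(np.squeeze(cost)), "cum_qaly": float(np.squeeze(qaly))}
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Per-cycle trace export (one-draw traces only)."""
        occ = np.squeeze(self.occupancy)
        if occ.ndim != 2:
            raise ValueError("to_frame is defined for single-draw traces")
        n = self.n_cycles
        df = pd.DataFrame(occ[: n + 1], columns=STATE_LABELS)
        df.insert(0, "cycle", np.arange(n + 1))
        for label, arr in [
            ("cycle_cost", self.cycle_cost),
            ("cycle_cost_disc", self.cycle_cost_disc),
            ("cycle_qaly", self.cycle_qaly),
            ("cycle_qaly_disc", self.cycle_qaly_disc),
        ]:
            col = np.concatenate([[0.0], np.squeeze(arr)])
            df[label] = col
        df["cum_cost_disc"] = df["cycle_cost_disc"].cumsum()
        df["cum_qaly_disc"] = df["cycle_qaly_disc"].cumsum()
        return df


def run_cohort(
    strategy: StrategyDef,
    conv: CycleConvention,
    horizon_years: int | None = None,
) -> CohortTrace:
    """Propagate the cohort and accrue discounted costs and QALYs.

    State membership is valued at cycle start (no half-cycle correction by
    default); QALY accrual per cycle is occupancy x utility / cycles_per_year.
    """
    years = conv.horizon_years if horizon_years is None else int(horizon_years)
    if years > conv.max_horizon_years:
        raise ParameterError(
            f"horizon {years} exceeds configured maximum {conv.max_horizon_years}"
        )
    n = conv.cycles_per_year * years
    mat = strategy.transition_matrix
    batch = mat.shape[:-2]
    occ = np.zeros(batch + (n + 1, N_STATES), dtype=float)
    occ[..., 0, S.ACTIVE] = 1.0
    disc = conv.discount_factors(n)

    cost = np.zeros(batch + (n,), dtype=float)
    qaly = np.zeros(batch + (n,), dtype=float)
    lumps_by_cycle: dict[int, list] = {}
    for c, weight, amount in strategy.lumps:
        lumps_by_cycle.setdefault(c, []).append((weight, amount))

    for t in range(1, n + 1):
        start = occ[..., t - 1, :]
        end = np.einsum("...i,...ij->...j", start, mat)
        occ[..., t, :] = end
        valued = 0.5 * (start + end) if conv.half_cycle_correction else start
        q = (valued * strategy.utilities).sum(axis=-1) / conv.cycles_per_year
        c = np.zeros(batch, dtype=float)
        for window, rates in strategy.state_cost_terms:
            if window is None or (window[0] <= t <= window[1]):
                c = c + (valued * rates).sum(axis=-1)
        for weight, amount in lumps_by_cycle.get(t, []):
            if isinstance(weight, str) and weight == ALIVE:
                w = 1.0 - valued[..., S.DEATH]
            elif weight is None:
                w = 1.0
            else:
                w = valued[..., int(weight)]
            c = c + np.asarray(amount, dtype=float) * w
        cost[..., t - 1] = c
        qaly[..., t - 1] = q

    return CohortTrace(
        strategy=strategy.name,
        convention=conv,
        occupancy=occ,
        cycle_cost=cost,
        cycle_cost_disc=cost * disc,
        cycle_qaly=qaly,
        cycle_qaly_disc=qaly * disc,
    )


def evaluate_strategies(
    values: Mapping[str, float],
    table: ParameterTable,
    horizon_years: int | None = None,
) -> dict[str, CohortTrace]:
    """Run both treatment arms on one set of parameter values."""
    conv = table.convention(horizon_years)
    return {
        name: run_cohort(build_strategy(name, values, table, conv), conv)
        for name in ("RTX", "TAC")
    }
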