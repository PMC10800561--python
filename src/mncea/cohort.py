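"""Synthetic HIS-style patient-record generator and parameter recovery.

Emits patient-level records with the statistical structure the analysis
assumes — multinomial 12-month outcome classes, independent Bernoulli
adverse events, plausible baseline covariates and per-visit proteinuria
trajectories — so the clinical-statistics stage and the full pipeline are
testable without any real data.  All trajectories are synthetic stand-ins;
they are never used as evidence about real patients.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .parameters import ParameterError, ParameterTable, wilson_interval

VISIT_MONTHS = (0, 1, 3, 6, 9, 12)
OUTCOME_CLASSES = ("CR", "PR", "NR", "Relapse")

# Class-conditional 12-month proteinuria endpoints (g/24 h, log-scale
# targets) for the synthetic trajectories; classification thresholds are not
# re-derived from these values.
_ENDPOINT_G24H = {"CR": 0.15, "PR": 1.5, "NR": 5.0, "Relapse": 4.5}
_RELAPSE_NADIR_G24H = 0.2


@dataclass
class ArmConfig:
    """Generator settings for one treatment arm."""

    name: str
    n: int
    class_probs: dict[str, float]
    ae_incidence: dict[str, float] = field(default_factory=dict)
    fixture_counts: dict[str, int] | None = None
    ae_fixture_counts: dict[str, int] | None = None
    relapse_within_cr: bool = False
    age_mean: float = 40.0
    age_sd: float = 15.0
    female_prop: float = 0.3
    onset_mean_months: float = 24.0
    onset_sd_months: float = 24.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ParameterError("arm size must be nonnegative")
        missing = set(OUTCOME_CLASSES) - set(self.class_probs)
        if missing:
            raise ParameterError(f"{self.name}: missing class probabilities {missing}")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(
                f"{self.name}: class probabilities sum to {total}, expected 1"
            )
        for label, p in self.ae_incidence.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{self.name}: AE incidence {label}={p} outside [0,1]")


@dataclass
class GeneratorConfig:
    """Full synthetic-cohort specification (all arms plus the seed)."""

    arms: list[ArmConfig]
    seed: int = 0

    @classmethod
    def from_table(cls, table: ParameterTable) -> "GeneratorConfig":
        cohort = table.cohort
        arms = [
            ArmConfig(
                name=name,
                n=int(raw["n"]),
                class_probs={k: float(v) for k, v in raw["class_probs"].items()},
                ae_incidence={k: float(v) for k, v in raw.get("ae_incidence", {}).items()},
                fixture_counts=raw.get("fixture_counts"),
                ae_fixture_counts=raw.get("ae_fixture_counts"),
                relapse_within_cr=bool(raw.get("relapse_within_cr", False)),
                age_mean=float(raw.get("age_mean", 40.0)),
                age_sd=float(raw.get("age_sd", 15.0)),
                female_prop=float(raw.get("female_prop", 0.3)),
                onset_mean_months=float(raw.get("onset_mean_months", 24.0)),
                onset_sd_months=float(raw.get("onset_sd_months", 24.0)),
            )
            for name, raw in cohort.get("arms", {}).items()
        ]
        return cls(arms=arms, seed=int(cohort.get("seed", 0)))

    @property
    def relapse_within_cr(self) -> dict[str, bool]:
        return {a.name: a.relapse_within_cr for a in self.arms}


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():  # resample out-of-range values; bounds are generous
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _proteinuria_trajectory(rng, outcome: str, baseline: float) -> list[float]:
    """Log-linear decline (with class-dependent endpoint) plus lognormal noise.

    Relapse trajectories fall to a nadir at month 6, then rebound.
    """
    months = np.array(VISIT_MONTHS, dtype=float)
    if outcome == "Relapse":
        nadir, end = _RELAPSE_NADIR_G24H, _ENDPOINT_G24H["Relapse"]
        log_vals = np.where(
            months <= 6,
            np.log(baseline) + (np.log(nadir) - np.log(baseline)) * months / 6.0,
            np.log(nadir) + (np.log(end) - np.log(nadir)) * (months - 6.0) / 6.0,
        )
    else:
        end = _ENDPOINT_G24H[outcome] * baseline / 5.0 if outcome == "NR" else _ENDPOINT_G24H[outcome]
        log_vals = np.log(baseline) + (np.log(end) - np.log(baseline)) * months / 12.0
    noise = rng.normal(0.0, 0.2, size=months.size)
    noise[0] = 0.0
    return list(np.exp(log_vals + noise))


def _fixture_classes(arm: ArmConfig) -> list[str]:
    if arm.fixture_counts is None:
        raise ParameterError(f"{arm.name}: fixture mode needs fixture_counts")
    counts = {k: int(arm.fixture_counts.get(k, 0)) for k in OUTCOME_CLASSES}
    if sum(counts.values()) != arm.n:
        raise ParameterError(f"{arm.name}: fixture counts do not sum to n={arm.n}")
    labels: list[str] = []
    for cls in OUTCOME_CLASSES:
        labels.extend([cls] * counts[cls])
    return labels


def _fixture_aes(arm: ArmConfig) -> list[list[str]]:
    events: list[list[str]] = [[] for _ in range(arm.n)]
    pos = 0
    for label, k in (arm.ae_fixture_counts or {}).items():
        for _ in range(int(k)):
            events[pos % arm.n].append(label)
            pos += 1
    return events


def generate_cohort(
    config: GeneratorConfig,
    seed: int | None = None,
    fixture: bool = False,
) -> pd.DataFrame:
    """Generate one synthetic cohort (all arms).

    In ``fixture`` mode the outcome classes and adverse events are emitted at
    exactly the configured counts (no sampling); covariates and proteinuria
    markers are still drawn, deterministically for a given seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    pid = 0
    for arm in config.arms:
        if fixture:
            classes = _fixture_classes(arm)
            ae_lists = _fixture_aes(arm)
        else:
            probs = np.array([arm.class_probs[c] for c in OUTCOME_CLASSES])
            classes = [OUTCOME_CLASSES[i] for i in rng.choice(4, size=arm.n, p=probs)]
            labels = sorted(arm.ae_incidence)
            draws = {
                lab: rng.random(arm.n) < arm.ae_incidence[lab] for lab in labels
            }
            ae_lists = [
                [lab for lab in labels if draws[lab][i]] for i in range(arm.n)
            ]
        age = _truncated_normal(rng, arm.age_mean, arm.age_sd, 14.0, 90.0, arm.n)
        female = rng.random(arm.n) < arm.female_prop
        onset = _truncated_normal(
            rng, arm.onset_mean_months, arm.onset_sd_months, 0.5, 400.0, arm.n
        )
        baseline = np.exp(rng.normal(np.log(5.5), 0.35, size=arm.n))
        rows = []
        for i in range(arm.n):
            traj = _proteinuria_trajectory(rng, classes[i], float(baseline[i]))
            rows.append(
                {
                    "patient_id": f"P{pid:05d}",
                    "arm": arm.name,
                    "age": round(float(age[i]), 1),
                    "sex": "F" if female[i] else "M",
                    "onset_months": round(float(onset[i]), 1),
                    "outcome_class": classes[i],
                    "ae_list": ";".join(ae_lists[i]),
                    **{
                        f"proteinuria_m{mo}": round(traj[j], 3)
                        for j, mo in enumerate(VISIT_MONTHS)
                    },
                }
            )
            pid += 1
        frames.append(pd.DataFrame(rows))
    return pd.concat(frames, ignore_index=True)


def estimate_generator_params(records: pd.DataFrame) -> pd.DataFrame:
    """Maximum-likelihood multinomial/Bernoulli estimates with Wilson 95% CIs.

    One row per arm per quantity (outcome-class probability or adverse-event
    incidence); single-patient arms yield maximal-width intervals.
    """
    if records.empty:
        raise ParameterError("cannot estimate from an empty cohort")
    rows = []
    for arm, group in records.groupby("arm"):
        n = len(group)
        for cls in OUTCOME_CLASSES:
            k = int((group["outcome_class"] == cls).sum())
            low, high = wilson_interval(k, n)
            rows.append(
                {
                    "arm": str(arm),
                    "quantity": f"class.{cls}",
                    "count": k,
                    "n": n,
                    "estimate": k / n,
                    "ci_low": low,
                    "ci_high": high,
                }
            )
        labels = sorted(
            {
                lab
                for evs in group["ae_list"]
                for lab in str(evs).split(";")
                if lab
            }
        )
        for lab in labels:
            k = int(
                group["ae_list"]
                .map(lambda v: lab in str(v).split(";"))
                .sum()
            )
            low, high = wilson_interval(k, n)
            rows.append(
                {
                    "arm": str(arm),
                    "quantity": f"ae.{lab}",
                    "count": k,
                    "n": n,
                    "estimate": k / n,
                    "ci_low": low,
                    "ci_high": high,
                }
            )
    return pd.DataFrame(rows)
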