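"""Efficacy and safety statistics on patient-level records.

Records arrive pre-classified into 12-month outcome classes (CR, PR, NR,
Relapse); this module tallies them, derives rates, and runs 2x2 Pearson
chi-square tests with or without the Yates continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import ParameterError, wilson_interval

OUTCOME_CLASSES = ("CR", "PR", "NR", "Relapse")

#: correction mode per published efficacy row, reproducing the original
#: analysis (the published p-values mix corrected and uncorrected tests).
PUBLISHED_TEST_MODES = {
    "CR": "auto",
    "PR": "off",
    "NR": "off",
    "Relapse": "on",
    "Overall": "on",
}


@dataclass(frozen=True)
class TwoByTwoTable:
    """Group x event counts: rows are groups, columns event / non-event."""

    a: int  # group 1, event
    b: int  # group 1, no event
    c: int  # group 2, event
    d: int  # group 2, no event

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ParameterError("2x2 counts must be nonnegative integers")

    @classmethod
    def from_events(cls, k1: int, n1: int, k2: int, n2: int) -> "TwoByTwoTable":
        return cls(k1, n1 - k1, k2, n2 - k2)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def expected(self) -> np.ndarray:
        r1, r2, c1, c2 = self.margins()
        return np.array([[r1 * c1, r1 * c2], [r2 * c1, r2 * c2]], dtype=float) / self.n


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    corrected: bool
    mode: str


def chi_square_2x2(table: TwoByTwoTable, continuity: str = "auto") -> Chi2Result:
    """Pearson chi-square test on a 2x2 table (1 degree of freedom).

    ``continuity`` is ``"on"`` (Yates), ``"off"`` (plain Pearson) or
    ``"auto"`` (Yates when any expected cell count is below 5).
    """
    if continuity not in ("auto", "on", "off"):
        raise ParameterError(f"unknown continuity mode {continuity!r}")
    r1, r2, c1, c2 = table.margins()
    if min(r1, r2, c1, c2) == 0:
        raise ParameterError("chi-square test undefined: zero margin")
    apply = continuity == "on" or (
        continuity == "auto" and table.expected().min() < 5.0
    )
    det = abs(table.a * table.d - table.b * table.c)
    if apply:
        det = max(det - table.n / 2.0, 0.0)
    stat = table.n * det * det / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(stat, df=1))
    return Chi2Result(float(stat), p, apply, continuity)


@dataclass
class EfficacyTally:
    """Per-arm 12-month outcome tallies and derived percentage rates.

    ``counts`` holds the exclusive 12-month classes.  The published marginal
    layout is recovered with :meth:`printed_marginals`; when
    ``relapse_within_cr`` the published complete-remission count includes the
    patients who subsequently relapsed.
    """

    arm: str
    n: int
    counts: dict[str, int]
    relapse_within_cr: bool = False

    @property
    def rates(self) -> dict[str, float]:
        if self.n == 0:
            return {k: float("nan") for k in self.counts}
        return {k: 100.0 * v / self.n for k, v in self.counts.items()}

    def printed_marginals(self) -> dict[str, int]:
        out = dict(self.counts)
        if self.relapse_within_cr:
            out["CR"] = out["CR"] + out["Relapse"]
        out["Overall"] = out["CR"] + out["PR"]
        return out

    def printed_rates(self) -> dict[str, float]:
        marg = self.printed_marginals()
        if self.n == 0:
            return {k: float("nan") for k in marg}
        return {k: 100.0 * v / self.n for k, v in marg.items()}


def classify_outcomes(
    records: pd.DataFrame,
    relapse_within_cr: Mapping[str, bool] | None = None,
) -> dict[str, EfficacyTally]:
    """Tally 12-month outcome classes per treatment arm.

    ``records`` needs ``arm`` and ``outcome_class`` columns; unknown class
    labels raise.  ``relapse_within_cr`` configures, per arm, whether the
    published CR marginal includes relapsed patients.
    """
    bad = set(records["outcome_class"]) - set(OUTCOME_CLASSES)
    if bad:
        raise ParameterError(f"unknown outcome class labels: {sorted(bad)}")
    conv = dict(relapse_within_cr or {})
    tallies = {}
    for arm, group in records.groupby("arm"):
        counts = {cls: int((group["outcome_class"] == cls).sum()) for cls in OUTCOME_CLASSES}
        tallies[str(arm)] = EfficacyTally(
            arm=str(arm),
            n=len(group),
            counts=counts,
            relapse_within_cr=bool(conv.get(str(arm), False)),
        )
    return tallies


def efficacy_comparison(
    tally_a: EfficacyTally,
    tally_b: EfficacyTally,
    test_modes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Published-style efficacy table with per-row chi-square p-values."""
    modes = dict(PUBLISHED_TEST_MODES)
    modes.update(test_modes or {})
    marg_a, marg_b = tally_a.printed_marginals(), tally_b.printed_marginals()
    rate_a, rate_b = tally_a.printed_rates(), tally_b.printed_rates()
    rows = []
    for indicator in ("CR", "PR", "NR", "Relapse", "Overall"):
        table = TwoByTwoTable.from_events(
            marg_a[indicator], tally_a.n, marg_b[indicator], tally_b.n
        )
        res = chi_square_2x2(table, modes.get(indicator, "auto"))
        rows.append(
            {
                "indicator": indicator,
                f"count_{tally_a.arm}": marg_a[indicator],
                f"rate_{tally_a.arm}_pct": round(rate_a[indicator], 2),
                f"count_{tally_b.arm}": marg_b[indicator],
                f"rate_{tally_b.arm}_pct": round(rate_b[indicator], 2),
                "chi2": res.statistic,
                "p_value": res.p_value,
                "continuity_corrected": res.corrected,
                "continuity_mode": res.mode,
            }
        )
    return pd.DataFrame(rows)


def _split_ae(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    text = str(value).strip()
    return [t.strip() for t in text.split(";") if t.strip()] if text else []


def safety_summary(records: pd.DataFrame, counting: str = "episodes") -> pd.DataFrame:
    """Per-arm adverse-event tallies with percentage incidence.

    ``counting`` is ``"episodes"`` (default: every listed event counts) or
    ``"patients"`` (a patient contributes at most once to the overall row).
    """
    if counting not in ("episodes", "patients"):
        raise ParameterError(f"unknown counting convention {counting!r}")
    rows = []
    for arm, group in records.groupby("arm"):
        n = len(group)
        events = group["ae_list"].map(_split_ae)
        tally: dict[str, int] = {}
        for evs in events:
            for e in evs:
                tally[e] = tally.get(e, 0) + 1
        for label in sorted(tally):
            rows.append(
                {
                    "arm": str(arm),
                    "adverse_event": label,
                    "episodes": tally[label],
                    "incidence_pct": round(100.0 * tally[label] / n, 2) if n else float("nan"),
                }
            )
        overall = (
            sum(tally.values())
            if counting == "episodes"
            else int((events.map(len) > 0).sum())
        )
        rows.append(
            {
                "arm": str(arm),
                "adverse_event": "Overall",
                "episodes": overall,
                "incidence_pct": round(100.0 * overall / n, 2) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
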