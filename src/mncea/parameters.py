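"""Typed model-input registry, time-scale conversions and distribution fits.

Every model input (transition rates, utilities, adverse-event incidences and
costs, unit costs, policy constants) lives in a :class:`ParameterTable` built
from a hierarchical YAML document.  Uncertain inputs carry a (low, high) range
read as a 95% interval, from which Beta (probabilities, utilities, incidences)
or Gamma (costs) sampling distributions are fitted by the method of moments.
"""
from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats


class ParameterError(ValueError):
    """Malformed or inconsistent model input."""


class FitError(ValueError):
    """A moment fit is degenerate (implied variance too large)."""


class HealthState(enum.IntEnum):
    """The eight mutually exclusive health states of the cohort model.

    ``DEATH`` is absorbing; everyone enters in ``ACTIVE`` (active disease).
    """

    ACTIVE = 0
    COMPLETE_REMISSION = 1
    PARTIAL_REMISSION = 2
    RELAPSE = 3
    HEMODIALYSIS = 4
    PERITONEAL_DIALYSIS = 5
    KIDNEY_TRANSPLANT = 6
    DEATH = 7


N_STATES = len(HealthState)

STATE_LABELS = [
    "active_disease",
    "complete_remission",
    "partial_remission",
    "relapse",
    "hemodialysis",
    "peritoneal_dialysis",
    "kidney_transplant",
    "death",
]


class Family(str, enum.Enum):
    BETA = "beta"
    GAMMA = "gamma"
    FIXED = "fixed"


class Category(str, enum.Enum):
    PROBABILITY = "probability"
    RATE = "rate"
    UTILITY = "utility"
    COST = "cost"
    INCIDENCE = "incidence"


class TimeBasis(str, enum.Enum):
    PER_YEAR = "per_year"
    PER_CYCLE = "per_cycle"
    PER_EVENT = "per_event"
    PER_6_MONTHS = "per_6_months"
    PER_10_YEARS = "per_10_years"
    DIMENSIONLESS = "dimensionless"


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input: point estimate, range, and sampling family."""

    name: str
    mean: float
    low: float
    high: float
    family: Family
    category: Category
    time_basis: TimeBasis = TimeBasis.DIMENSIONLESS
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ParameterError(
                f"{self.name}: mean {self.mean} outside range "
                f"[{self.low}, {self.high}]"
            )
        if self.category in (Category.PROBABILITY, Category.INCIDENCE):
            if not (0.0 <= self.low and self.high <= 1.0 and self.mean <= 1.0):
                raise ParameterError(
                    f"{self.name}: {self.category.value} values must lie in [0, 1]"
                )
        if self.category is Category.UTILITY and not (
            0.0 <= self.low and self.high <= 1.0
        ):
            raise ParameterError(f"{self.name}: utilities must lie in [0, 1]")
        if self.family is Family.BETA and self.category not in (
            Category.PROBABILITY,
            Category.UTILITY,
            Category.INCIDENCE,
        ):
            raise ParameterError(
                f"{self.name}: beta family restricted to probabilities, "
                "utilities and incidences"
            )
        if self.family is Family.GAMMA:
            if self.category is not Category.COST:
                raise ParameterError(f"{self.name}: gamma family restricted to costs")
            if self.low < 0:
                raise ParameterError(f"{self.name}: gamma range must be nonnegative")

    @property
    def has_range(self) -> bool:
        return self.high > self.low

    def fitted(self) -> "FittedDistribution":
        """Sampling distribution implied by the spec (degenerate if fixed)."""
        if self.family is Family.BETA:
            return fit_beta_from_mean_range(self.mean, self.low, self.high)
        if self.family is Family.GAMMA:
            return fit_gamma_from_mean_range(self.mean, self.low, self.high)
        return FittedDistribution(Family.FIXED, self.mean, 0.0, self.mean, 0.0)


@dataclass(frozen=True)
class FittedDistribution:
    """A Beta/Gamma (or degenerate) distribution matched to a mean and sd.

    ``a``/``b`` hold alpha/beta for Beta and shape/scale for Gamma.
    """

    family: Family
    a: float
    b: float
    target_mean: float
    target_sd: float

    @property
    def mean(self) -> float:
        if self.family is Family.BETA:
            return self.a / (self.a + self.b)
        if self.family is Family.GAMMA:
            return self.a * self.b
        return self.a

    @property
    def sd(self) -> float:
        if self.family is Family.BETA:
            n = self.a + self.b
            return math.sqrt(self.a * self.b / (n * n * (n + 1.0)))
        if self.family is Family.GAMMA:
            return math.sqrt(self.a) * self.b
        return 0.0

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        if self.family is Family.BETA:
            return rng.beta(self.a, self.b, size=size)
        if self.family is Family.GAMMA:
            return rng.gamma(self.a, self.b, size=size)
        return np.full(size if size is not None else (), self.a, dtype=float)


@dataclass(frozen=True)
class CycleConvention:
    """Time discretisation: 30-day cycles, 12 per (360-day) model year."""

    cycle_length_days: int = 30
    cycles_per_year: int = 12
    horizon_years: int = 5
    annual_discount_rate: float = 0.05
    max_horizon_years: int = 5
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.horizon_years <= self.max_horizon_years):
            raise ParameterError(
                f"horizon_years must be in [1, {self.max_horizon_years}]"
            )

    @property
    def n_cycles(self) -> int:
        return self.cycles_per_year * self.horizon_years

    def discount_factors(self, n_cycles: int | None = None) -> np.ndarray:
        """Per-cycle discount factors (1+r)^(-t/cycles_per_year), t = 1..n."""
        n = self.n_cycles if n_cycles is None else n_cycles
        t = np.arange(1, n + 1, dtype=float)
        return (1.0 + self.annual_discount_rate) ** (-t / self.cycles_per_year)


# ---------------------------------------------------------------------------
# Time-scale conversions (constant hazard within the period)
# ---------------------------------------------------------------------------

def annual_prob_to_cycle_prob(p_annual, cycles_per_year: int = 12):
    """Convert an annual probability to a per-cycle probability.

    Assumes a constant hazard: ``p_c = 1 - (1 - p_a)^(1/m)``.
    """
    p = np.asarray(p_annual, dtype=float)
    if np.any(p < 0.0) or np.any(p >= 1.0):
        raise ParameterError("annual probability must lie in [0, 1)")
    out = -np.expm1(np.log1p(-p) / cycles_per_year)
    return out if out.ndim else float(out)


def cycle_prob_to_annual_prob(p_cycle, cycles_per_year: int = 12):
    """Inverse of :func:`annual_prob_to_cycle_prob`."""
    p = np.asarray(p_cycle, dtype=float)
    if np.any(p < 0.0) or np.any(p >= 1.0):
        raise ParameterError("cycle probability must lie in [0, 1)")
    out = -np.expm1(np.log1p(-p) * cycles_per_year)
    return out if out.ndim else float(out)


def multi_year_prob_to_annual(p, years: float):
    """Convert a probability over ``years`` years to an annual probability."""
    q = np.asarray(p, dtype=float)
    if np.any(q < 0.0) or np.any(q >= 1.0):
        raise ParameterError("probability must lie in [0, 1)")
    out = -np.expm1(np.log1p(-q) / years)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Method-of-moments fits; the (low, high) range is read as a 95% interval
# ---------------------------------------------------------------------------

_RANGE_Z = 2.0 * 1.96  # width of a 95% normal interval in sd units


def fit_beta_from_mean_range(mean: float, low: float, high: float) -> FittedDistribution:
    """Fit a Beta distribution to a mean and a 95% range by moments."""
    if not (0.0 <= low <= mean <= high <= 1.0) or not low < high:
        raise ParameterError(f"invalid beta target mean={mean} range=({low}, {high})")
    if not 0.0 < mean < 1.0:
        raise ParameterError("beta mean must lie strictly inside (0, 1)")
    sd = (high - low) / _RANGE_Z
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise FitError(
            f"implied variance {var:.3g} >= m(1-m) = {mean * (1 - mean):.3g}; "
            "beta fit degenerate"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return FittedDistribution(Family.BETA, mean * nu, (1.0 - mean) * nu, mean, sd)


def fit_gamma_from_mean_range(mean: float, low: float, high: float) -> FittedDistribution:
    """Fit a Gamma distribution to a mean and a 95% range by moments."""
    if mean <= 0.0:
        raise ParameterError("gamma mean must be positive")
    if not (0.0 <= low <= mean <= high) or not low < high:
        raise ParameterError(f"invalid gamma target mean={mean} range=({low}, {high})")
    sd = (high - low) / _RANGE_Z
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return FittedDistribution(Family.GAMMA, shape, scale, mean, sd)


def wilson_interval(count: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (always inside [0, 1])."""
    if n <= 0 or count < 0 or count > n:
        raise ParameterError(f"invalid binomial counts {count}/{n}")
    res = stats.binomtest(count, n).proportion_ci(
        confidence_level=confidence, method="wilson"
    )
    return float(res.low), float(res.high)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

# section -> (name prefix, default category, default family with range,
#             default time basis)
_SECTIONS = {
    "transition_rates": ("transition", Category.RATE, Family.FIXED, TimeBasis.PER_YEAR),
    "utilities": ("utility", Category.UTILITY, Family.BETA, TimeBasis.DIMENSIONLESS),
    "ae_incidence": ("ae_inc", Category.INCIDENCE, Family.BETA, TimeBasis.PER_EVENT),
    "ae_costs": ("ae_cost", Category.COST, Family.GAMMA, TimeBasis.PER_EVENT),
    "direct_costs": ("cost", Category.COST, Family.GAMMA, TimeBasis.PER_EVENT),
    "policy": ("policy", Category.COST, Family.FIXED, TimeBasis.DIMENSIONLESS),
}

_DEFAULT_RANGE_FRACTION = 0.20


class ParameterTable:
    """Registry of every model input keyed by dotted name.

    Also carries the raw ``settings``, ``calibration`` and ``cohort`` sections
    of the configuration document.
    """

    def __init__(
        self,
        specs: Mapping[str, ParameterSpec],
        settings: dict | None = None,
        calibration: dict | None = None,
        cohort: dict | None = None,
    ) -> None:
        self._specs = dict(specs)
        self.settings = dict(settings or {})
        self.calibration = dict(calibration or {})
        self.cohort = dict(cohort or {})

    # -- mapping protocol ---------------------------------------------------
    def __getitem__(self, name: str) -> ParameterSpec:
        return self._specs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def names(self) -> list[str]:
        return list(self._specs)

    def value(self, name: str) -> float:
        return self._specs[name].mean

    def values(self) -> dict[str, float]:
        """Point estimates for every parameter (the deterministic base case)."""
        return {k: v.mean for k, v in self._specs.items()}

    def sampled_names(self) -> list[str]:
        """Parameters with a non-degenerate sampling distribution."""
        return [k for k, v in self._specs.items() if v.family is not Family.FIXED]

    def replace_mean(self, name: str, mean: float) -> "ParameterTable":
        """Copy of the table with one point estimate replaced (for DSA)."""
        spec = self._specs[name]
        new = ParameterSpec(
            spec.name,
            float(mean),
            min(spec.low, float(mean)),
            max(spec.high, float(mean)),
            spec.family,
            spec.category,
            spec.time_basis,
            spec.source_tag,
        )
        specs = dict(self._specs)
        specs[name] = new
        return ParameterTable(specs, self.settings, self.calibration, self.cohort)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_yaml(cls, text: str) -> "ParameterTable":
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:  # pragma: no cover - passthrough detail
            raise ParameterError(f"could not parse configuration: {exc}") from exc
        if not isinstance(doc, dict):
            raise ParameterError("configuration document must be a mapping")
        specs: dict[str, ParameterSpec] = {}
        for section, (prefix, cat, fam, basis) in _SECTIONS.items():
            entries = doc.get(section, {})
            if not isinstance(entries, dict):
                raise ParameterError(f"section {section!r} must be a mapping")
            for key, raw in entries.items():
                spec = _parse_entry(f"{prefix}.{key}", raw, cat, fam, basis)
                specs[spec.name] = spec
        calibration = doc.get("calibration", {})
        for spec in _calibration_specs(calibration):
            specs[spec.name] = spec
        return cls(specs, doc.get("settings", {}), calibration, doc.get("cohort", {}))

    @classmethod
    def default(cls) -> "ParameterTable":
        """The shipped default configuration."""
        text = (
            resources.files("mncea.data")
            .joinpath("default_config.yaml")
            .read_text(encoding="utf-8")
        )
        return cls.from_yaml(text)

    # -- export -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": s.name,
                "mean": s.mean,
                "low": s.low,
                "high": s.high,
                "family": s.family.value,
                "category": s.category.value,
                "time_basis": s.time_basis.value,
                "source_tag": s.source_tag,
            }
            for s in self._specs.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_frame().to_csv(buf, index=False)
        return buf.getvalue()

    def convention(self, horizon_years: int | None = None) -> CycleConvention:
        s = self.settings
        return CycleConvention(
            cycle_length_days=int(s.get("cycle_length_days", 30)),
            cycles_per_year=int(s.get("cycles_per_year", 12)),
            horizon_years=int(horizon_years or s.get("horizon_years", 5)),
            annual_discount_rate=self.value("policy.discount_rate"),
            max_horizon_years=int(s.get("max_horizon_years", 5)),
            half_cycle_correction=bool(s.get("half_cycle_correction", False)),
        )


def _parse_entry(
    name: str,
    raw,
    default_category: Category,
    default_family: Family,
    default_basis: TimeBasis,
) -> ParameterSpec:
    if isinstance(raw, (int, float)):
        raw = {"mean": float(raw)}
    if not isinstance(raw, dict) or "mean" not in raw:
        raise ParameterError(f"entry {name!r}: expected a mapping with a 'mean'")
    try:
        mean = float(raw["mean"])
        category = Category(raw.get("category", default_category))
        basis = TimeBasis(raw.get("time_basis", default_basis))
        has_range = "low" in raw or "high" in raw
        if has_range:
            low = float(raw["low"])
            high = float(raw["high"])
            family = Family(raw.get("family", default_family))
        else:
            # No published range: +/-20% band for one-way DSA, fixed in PSA.
            span = abs(mean) * _DEFAULT_RANGE_FRACTION
            low, high = mean - span, mean + span
            if category in (Category.PROBABILITY, Category.INCIDENCE, Category.UTILITY):
                low, high = max(low, 0.0), min(high, 1.0)
            family = Family(raw.get("family", Family.FIXED))
        if low == high:
            family = Family.FIXED
    except (TypeError, ValueError) as exc:
        raise ParameterError(f"entry {name!r}: {exc}") from exc
    return ParameterSpec(name, mean, low, high, family, category, basis, raw.get("source", ""))


def printed_counts(arm_cal: Mapping) -> dict[str, int]:
    """Published 12-month marginal counts for one arm.

    When ``relapse_within_cr`` the published complete-remission count includes
    the patients who subsequently relapsed.
    """
    cr = int(arm_cal["cr"])
    if arm_cal.get("relapse_within_cr", False):
        cr += int(arm_cal["relapse"])
    return {
        "cr": cr,
        "pr": int(arm_cal["pr"]),
        "nr": int(arm_cal["nr"]),
        "relapse": int(arm_cal["relapse"]),
        "n": int(arm_cal["n"]),
    }


def _calibration_specs(calibration: Mapping) -> list[ParameterSpec]:
    """Beta-distributed 12-month outcome proportions from binomial counts."""
    specs: list[ParameterSpec] = []
    for arm, arm_cal in calibration.items():
        counts = printed_counts(arm_cal)
        n = counts["n"]
        for cls in ("cr", "pr", "relapse"):
            k = counts[cls]
            p = k / n
            low, high = wilson_interval(k, n)
            specs.append(
                ParameterSpec(
                    name=f"calib.{arm.lower()}_{cls}_12m",
                    mean=p,
                    low=low,
                    high=high,
                    family=Family.BETA if 0 < k < n else Family.FIXED,
                    category=Category.PROBABILITY,
                    time_basis=TimeBasis.PER_YEAR,
                    source_tag=f"clinical counts {k}/{n}",
                )
            )
    return specs
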