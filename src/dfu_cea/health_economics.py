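"""Discounted QALY/cost accumulation, ICER, thresholds and price inversion.

Utilities follow a multiplier convention: a reference utility for a
diabetic patient with no ulcer (0.840/year) is scaled down by a per-state
multiplier.  Active-ulcer states are a within-state mixture of infected and
non-infected ulcers (default 10% infected) rather than separate Markov
states.  The non-infected post-amputation ulcer multiplier is not tabulated
in the source utility set and is composed multiplicatively
(post-amputation no-ulcer multiplier × ulcer multiplier); the infected
post-amputation values (0.715 small, 0.620 leg) are used directly.

Costs comprise weekly per-state payer costs, one-time amputation event
costs charged (and discounted) at tunnel entry, and the drug course cost —
unit cost per injection × units per week × course weeks — charged
undiscounted at model start for the treated arm.

Discounting is per-cycle compound at the annual rate:
factor (1+r)^(-(w-1)/52), so week 1 is undiscounted.  An annual-step
variant (factor constant within each model year) is available since the
convention is not dictated by the model structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .markov_engine import CohortTrace, StateSpace

__all__ = [
    "UtilityTable",
    "CostDeck",
    "DiscountSpec",
    "Icer",
    "Verdict",
    "CEAResult",
    "UndefinedICERError",
    "state_utility_per_year",
    "discount_factor",
    "accumulate_outcomes",
    "drug_course_cost",
    "compute_icer",
    "thresholds_from_salary",
    "classify_verdict",
    "threshold_unit_price",
]

CYCLES_PER_YEAR = 52


class UndefinedICERError(ValueError):
    """Raised when ΔQALY is zero and the ratio is undefined."""


@dataclass(frozen=True)
class UtilityTable:
    """Reference utility and per-state multipliers (time trade-off based)."""

    base_no_ulcer: float = 0.840
    mult_ulcer: float = 0.890
    mult_infected_ulcer: float = 0.820
    mult_post_small_no_ulcer: float = 0.830
    mult_post_leg_no_ulcer: float = 0.730
    mult_acute_post_amp: float = 0.500
    mult_infected_ulcer_post_small: float = 0.715
    mult_infected_ulcer_post_leg: float = 0.620
    infected_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mult_infected_ulcer > self.mult_ulcer:
            raise ValueError("infected ulcer multiplier exceeds the non-infected one")


@dataclass(frozen=True)
class DiscountSpec:
    annual_rate: float = 0.05
    cycles_per_year: int = CYCLES_PER_YEAR
    annual_steps: bool = False  # constant factor within each model year

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ValueError("annual_rate must be >= 0")
        if self.cycles_per_year < 1:
            raise ValueError("cycles_per_year must be >= 1")


@dataclass(frozen=True)
class CostDeck:
    """Per-state weekly payer costs (EUR) plus event and drug-course costs.

    `weekly_state_costs` is keyed by cost group: tunnel states share one
    entry per amputation type (see ``StateSpace.cost_group``).
    """

    weekly_state_costs: dict[str, float] = field(default_factory=dict)
    amputation_event_cost_small: float = 0.0
    amputation_event_cost_leg: float = 0.0
    drug_unit_cost: float = 0.0
    drug_units_per_week: float = 0.0
    drug_course_weeks: int = 0
    prorate_drug_cost: bool = False

    def __post_init__(self) -> None:
        for key, v in self.weekly_state_costs.items():
            if v < 0:
                raise ValueError(f"weekly cost for {key!r} must be >= 0, got {v}")
        for name in (
            "amputation_event_cost_small",
            "amputation_event_cost_leg",
            "drug_unit_cost",
            "drug_units_per_week",
            "drug_course_weeks",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def weekly_cost(self, space: StateSpace, label: str) -> float:
        return float(self.weekly_state_costs.get(space.cost_group(label), 0.0))


def state_utility_per_year(label: str, u: UtilityTable, space: StateSpace) -> float:
    """Annual utility of one expanded state under the multiplier convention."""
    base = u.base_no_ulcer
    f = u.infected_fraction
    if label == "no_ulcer":
        return base
    if label == "ulcer":
        return base * ((1 - f) * u.mult_ulcer + f * u.mult_infected_ulcer)
    if label.startswith("amp_tunnel_"):
        return base * u.mult_acute_post_amp
    if label == "post_amp_small_no_ulcer":
        return base * u.mult_post_small_no_ulcer
    if label == "post_amp_leg_no_ulcer":
        return base * u.mult_post_leg_no_ulcer
    if label == "post_amp_small_ulcer":
        clean = u.mult_post_small_no_ulcer * u.mult_ulcer
        return base * ((1 - f) * clean + f * u.mult_infected_ulcer_post_small)
    if label == "post_amp_leg_ulcer":
        clean = u.mult_post_leg_no_ulcer * u.mult_ulcer
        return base * ((1 - f) * clean + f * u.mult_infected_ulcer_post_leg)
    if label in space.labels:  # defensive: space grew without utility logic
        raise KeyError(f"no utility defined for state {label!r}")
    raise KeyError(f"unknown state label: {label!r}")


def discount_factor(week: int, d: DiscountSpec) -> float:
    """Discount multiplier for cycle `week` (week 1 → 1.0)."""
    if week < 1:
        raise ValueError(f"week must be >= 1, got {week}")
    if d.annual_rate == 0:
        return 1.0
    if d.annual_steps:
        years_elapsed = (week - 1) // d.cycles_per_year
        return float((1.0 + d.annual_rate) ** (-years_elapsed))
    return float((1.0 + d.annual_rate) ** (-(week - 1) / d.cycles_per_year))


def _discount_vector(horizon_weeks: int, d: DiscountSpec) -> np.ndarray:
    weeks = np.arange(1, horizon_weeks + 1)
    if d.annual_rate == 0:
        return np.ones(horizon_weeks)
    if d.annual_steps:
        return (1.0 + d.annual_rate) ** (-((weeks - 1) // d.cycles_per_year))
    return (1.0 + d.annual_rate) ** (-(weeks - 1) / d.cycles_per_year)


def drug_course_cost(c: CostDeck) -> float:
    """Full drug course cost: unit cost × units/week × course weeks."""
    return c.drug_unit_cost * c.drug_units_per_week * c.drug_course_weeks


def accumulate_outcomes(
    trace: CohortTrace,
    u: UtilityTable,
    c: CostDeck,
    d: DiscountSpec,
    treated: bool = False,
) -> tuple[float, float]:
    """Discounted (QALY, cost) totals for one arm's cohort trace.

    Cycle w contributes its end-of-cycle occupancy (trace row w) valued at
    utility/52 and weekly cost, discounted at week w.  New tunnel entrants
    (occupancy of the first tunnel cycle) incur the one-time amputation
    event cost at their entry week.  `treated` adds the drug course cost:
    by default the full course at model start, undiscounted; with
    ``prorate_drug_cost`` the weekly drug spend is weighted by the fraction
    of the cohort still in the ulcer state and discounted.
    """
    space = trace.space
    W = trace.horizon_weeks
    occ = trace.occupancy[1:]  # rows 1..W, end-of-cycle membership
    disc = _discount_vector(W, d)

    u_vec = np.array(
        [state_utility_per_year(lbl, u, space) for lbl in space.labels]
    )
    c_vec = np.array([c.weekly_cost(space, lbl) for lbl in space.labels])

    qaly = float(disc @ (occ @ (u_vec / CYCLES_PER_YEAR)))
    cost = float(disc @ (occ @ c_vec))

    entrants_small = occ[:, space.index("amp_tunnel_small_1")]
    entrants_leg = occ[:, space.index("amp_tunnel_leg_1")]
    cost += float(disc @ entrants_small) * c.amputation_event_cost_small
    cost += float(disc @ entrants_leg) * c.amputation_event_cost_leg

    if treated:
        if c.prorate_drug_cost:
            weekly_drug = c.drug_unit_cost * c.drug_units_per_week
            course = min(c.drug_course_weeks, W)
            in_ulcer = trace.occupancy[:course, space.index("ulcer")]  # start of cycle
            cost += weekly_drug * float(disc[:course] @ in_ulcer)
        else:
            cost += drug_course_cost(c)

    if not np.isfinite(qaly) or not np.isfinite(cost) or qaly < 0 or cost < 0:
        raise ValueError("non-finite or negative accumulated outcomes")
    return qaly, cost


class Verdict(str, Enum):
    REIMBURSABLE = "reimbursable"
    CONDITIONALLY_REIMBURSABLE = "conditionally_reimbursable"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    DOMINANT = "dominant"
    DOMINATED = "dominated"


@dataclass(frozen=True)
class Icer:
    """ICER value, or a dominance outcome where the ratio is not meaningful."""

    value: float | None
    kind: str  # "ratio", "dominant", "dominated"

    @property
    def is_ratio(self) -> bool:
        return self.kind == "ratio"


def compute_icer(delta_cost: float, delta_qaly: float) -> Icer:
    """Incremental cost-effectiveness ratio or dominance classification.

    Raises `UndefinedICERError` when ΔQALY is exactly zero.
    """
    if not (np.isfinite(delta_cost) and np.isfinite(delta_qaly)):
        raise ValueError("deltas must be finite")
    if delta_qaly == 0:
        raise UndefinedICERError("ΔQALY is zero: ICER undefined")
    if delta_qaly > 0 and delta_cost < 0:
        return Icer(value=None, kind="dominant")
    if delta_qaly < 0 and delta_cost > 0:
        return Icer(value=None, kind="dominated")
    return Icer(value=delta_cost / delta_qaly, kind="ratio")


def thresholds_from_salary(avg_monthly_salary: float) -> tuple[float, float]:
    """Willingness-to-pay thresholds: (24×, 35×) the average monthly salary."""
    if avg_monthly_salary <= 0:
        raise ValueError("salary must be positive")
    return 24.0 * avg_monthly_salary, 35.0 * avg_monthly_salary


def classify_verdict(icer: Icer, lambda1: float, lambda2: float) -> Verdict:
    """Reimbursement verdict against the lower/upper thresholds (inclusive)."""
    if not lambda1 < lambda2:
        raise ValueError("lambda1 must be below lambda2")
    if icer.kind == "dominant":
        return Verdict.DOMINANT
    if icer.kind == "dominated":
        return Verdict.DOMINATED
    assert icer.value is not None
    if icer.value <= lambda1:
        return Verdict.REIMBURSABLE
    if icer.value <= lambda2:
        return Verdict.CONDITIONALLY_REIMBURSABLE
    return Verdict.NOT_COST_EFFECTIVE


@dataclass(frozen=True)
class CEAResult:
    """Per-arm discounted outcomes with increments, ICER and verdict."""

    horizon_weeks: int
    qaly_treated: float
    cost_treated: float
    qaly_control: float
    cost_control: float
    lambda1: float
    lambda2: float

    @property
    def delta_qaly(self) -> float:
        return self.qaly_treated - self.qaly_control

    @property
    def delta_cost(self) -> float:
        return self.cost_treated - self.cost_control

    @property
    def icer(self) -> Icer:
        return compute_icer(self.delta_cost, self.delta_qaly)

    @property
    def verdict(self) -> Verdict:
        return classify_verdict(self.icer, self.lambda1, self.lambda2)


def threshold_unit_price(
    delta_qaly: float,
    delta_cost_nondrug: float,
    units_per_week: float,
    course_weeks: float,
    lam: float,
) -> float | None:
    """Drug unit price at which the ICER equals the threshold `lam`.

    ΔCost is affine in the unit price with slope units_per_week ×
    course_weeks (the treated arm alone bears the drug cost, charged
    undiscounted at start), so p* = (λ·ΔQALY − ΔCost_nondrug) / slope.
    Returns None when no positive price achieves the threshold.
    """
    if delta_qaly <= 0:
        raise ValueError("threshold price requires a positive QALY gain")
    slope = units_per_week * course_weeks
    if slope <= 0:
        raise ValueError("drug exposure (units/week × weeks) must be positive")
    price = (lam * delta_qaly - delta_cost_nondrug) / slope
    return price if price > 0 else None
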