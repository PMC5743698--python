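"""Configuration deck: schema, validation, resolution and hashing.

A deck is a YAML document holding every model input: either 52-week trial
targets per arm (to be calibrated) or precomputed weekly probabilities,
plus the utility table, cost deck, discount settings, model structure,
sensitivity settings and threshold salary.  Validation is schema-based
(unknown keys rejected, every violation reported with its key path, all
failures collected rather than only the first).

`resolve` turns a validated deck into a flat nested-dict parameter space
(`ResolvedDeck`) in which weekly probabilities are concrete numbers; the
one-way sensitivity analysis perturbs scalars of that space by dotted path.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import calibration
from .calibration import TrialTargets, WeeklyProbabilities
from .health_economics import CostDeck, DiscountSpec, UtilityTable
from .markov_engine import TransitionModel

__all__ = [
    "ConfigDeck",
    "DeckValidationError",
    "ResolvedDeck",
    "load_and_validate",
    "validate_deck_dict",
    "resolve",
    "deck_hash",
    "trial_targets_from_deck",
    "COST_GROUPS",
]

COST_GROUPS = (
    "no_ulcer",
    "ulcer",
    "amp_tunnel_small",
    "amp_tunnel_leg",
    "post_amp_small_no_ulcer",
    "post_amp_small_ulcer",
    "post_amp_leg_no_ulcer",
    "post_amp_leg_ulcer",
)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ArmTargetsConfig(_Strict):
    closure_52w: float = Field(ge=0, le=1)
    amputation_52w: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _exit_below_one(self) -> "ArmTargetsConfig":
        if self.closure_52w + self.amputation_52w >= 1:
            raise ValueError("closure_52w + amputation_52w must be < 1")
        return self


class RecurrenceConfig(_Strict):
    events: int = Field(ge=0)
    denominator: int = Field(gt=0)

    @model_validator(mode="after")
    def _events_bounded(self) -> "RecurrenceConfig":
        if self.events > self.denominator:
            raise ValueError("events must not exceed denominator")
        return self


class TrialTargetsConfig(_Strict):
    heberprot_gwc: ArmTargetsConfig
    gwc: ArmTargetsConfig
    recurrence: RecurrenceConfig


class ArmProbsConfig(_Strict):
    p_heal: float = Field(ge=0, le=1)
    p_amp: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _row_valid(self) -> "ArmProbsConfig":
        if self.p_heal + self.p_amp > 1:
            raise ValueError("p_heal + p_amp must not exceed 1")
        return self


class WeeklyProbsConfig(_Strict):
    heberprot_gwc: ArmProbsConfig
    gwc: ArmProbsConfig
    p_rec: float = Field(ge=0, le=1)


class StructureConfig(_Strict):
    phase1_weeks: int = Field(default=52, ge=0)
    t_tunnel: int = Field(default=4, ge=1)
    leg_fraction: float = Field(default=0.1208, ge=0, le=1)
    allow_reamputation: bool = True


class UtilityConfig(_Strict):
    base_no_ulcer: float = Field(default=0.840, ge=0, le=1)
    mult_ulcer: float = Field(default=0.890, ge=0, le=1)
    mult_infected_ulcer: float = Field(default=0.820, ge=0, le=1)
    mult_post_small_no_ulcer: float = Field(default=0.830, ge=0, le=1)
    mult_post_leg_no_ulcer: float = Field(default=0.730, ge=0, le=1)
    mult_acute_post_amp: float = Field(default=0.500, ge=0, le=1)
    mult_infected_ulcer_post_small: float = Field(default=0.715, ge=0, le=1)
    mult_infected_ulcer_post_leg: float = Field(default=0.620, ge=0, le=1)
    infected_fraction: float = Field(default=0.10, ge=0, le=1)


class CostConfig(_Strict):
    weekly_state_costs: dict[str, float]
    amputation_event_cost_small: float = Field(ge=0)
    amputation_event_cost_leg: float = Field(ge=0)
    drug_unit_cost: float = Field(ge=0)
    drug_units_per_week: float = Field(default=3, ge=0)
    drug_course_weeks: int = Field(default=8, ge=0)
    prorate_drug_cost: bool = False

    @model_validator(mode="after")
    def _known_groups(self) -> "CostConfig":
        unknown = set(self.weekly_state_costs) - set(COST_GROUPS)
        if unknown:
            raise ValueError(f"unknown cost group keys: {sorted(unknown)}")
        negative = {k: v for k, v in self.weekly_state_costs.items() if v < 0}
        if negative:
            raise ValueError(f"negative weekly costs: {negative}")
        return self


class DiscountConfig(_Strict):
    annual_rate: float = Field(default=0.05, ge=0)
    cycles_per_year: int = Field(default=52, ge=1)
    annual_steps: bool = False


class OwsaConfig(_Strict):
    perturbation: float = Field(default=0.10, ge=0)


class ConfigDeck(_Strict):
    """Fully validated model input deck."""

    label: str = "unnamed"
    seed: int = 0
    version: int = 1
    horizons_years: list[int] = Field(default_factory=lambda: [5, 10])
    avg_monthly_salary: float = Field(default=858.0, gt=0)
    trial_targets: TrialTargetsConfig | None = None
    weekly_probabilities: WeeklyProbsConfig | None = None
    structure: StructureConfig = Field(default_factory=StructureConfig)
    utilities: UtilityConfig = Field(default_factory=UtilityConfig)
    costs: CostConfig
    discount: DiscountConfig = Field(default_factory=DiscountConfig)
    owsa: OwsaConfig = Field(default_factory=OwsaConfig)

    @model_validator(mode="after")
    def _one_probability_source(self) -> "ConfigDeck":
        if (self.trial_targets is None) == (self.weekly_probabilities is None):
            raise ValueError(
                "exactly one of trial_targets or weekly_probabilities is required"
            )
        if any(h < 1 for h in self.horizons_years):
            raise ValueError("horizons_years must be positive")
        return self


class DeckValidationError(ValueError):
    """All validation failures of a deck, each named by its key path."""

    def __init__(self, failures: list[str]):
        self.failures = failures
        super().__init__("invalid deck:\n" + "\n".join(f"  - {f}" for f in failures))


def validate_deck_dict(raw: dict[str, Any]) -> ConfigDeck:
    try:
        return ConfigDeck.model_validate(raw)
    except ValidationError as err:
        failures = [
            ".".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in err.errors()
        ]
        raise DeckValidationError(failures) from None


def load_and_validate(path: str | Path) -> ConfigDeck:
    """Parse a YAML deck file and validate it fully."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DeckValidationError(["top level: deck must be a YAML mapping"])
    return validate_deck_dict(raw)


def deck_hash(deck: ConfigDeck) -> str:
    """Short stable hash of the deck contents, embedded in every output."""
    payload = json.dumps(deck.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Resolution: deck -> concrete scalar parameter space

_PROB_LIKE_PREFIXES = ("probs.", "utilities.", "structure.leg_fraction")


@dataclass(frozen=True)
class ResolvedDeck:
    """Concrete model inputs as a nested dict, addressable by dotted path.

    Weekly probabilities are resolved (calibrated from trial targets if the
    deck supplied targets).  This is the space the one-way sensitivity
    analysis perturbs; `scalar_paths` enumerates every perturbable scalar.
    """

    params: dict[str, Any]
    label: str
    seed: int
    hash: str
    horizons_years: tuple[int, ...]

    def get(self, path: str) -> Any:
        node: Any = self.params
        for part in path.split("."):
            node = node[part]
        return node

    def with_value(self, path: str, value: Any) -> "ResolvedDeck":
        params = json.loads(json.dumps(self.params))  # deep copy, plain types
        node = params
        parts = path.split(".")
        for part in parts[:-1]:
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown parameter path: {path!r}")
        node[parts[-1]] = value
        return ResolvedDeck(
            params=params,
            label=self.label,
            seed=self.seed,
            hash=self.hash,
            horizons_years=self.horizons_years,
        )

    def scalar_paths(self) -> list[str]:
        """Every scalar the sensitivity analysis varies, sorted by path.

        Covers weekly probabilities, leg fraction, all utilities and the
        infected fraction, all costs and the discount rate; structural
        integers (horizon, tunnel length, drug schedule counts) and the
        threshold salary are excluded.
        """
        paths = [
            "probs.heberprot_gwc.p_heal",
            "probs.heberprot_gwc.p_amp",
            "probs.gwc.p_heal",
            "probs.gwc.p_amp",
            "probs.p_rec",
            "structure.leg_fraction",
            "discount.annual_rate",
            "costs.amputation_event_cost_small",
            "costs.amputation_event_cost_leg",
            "costs.drug_unit_cost",
        ]
        paths += [f"utilities.{k}" for k in self.params["utilities"]]
        paths += [
            f"costs.weekly_state_costs.{k}"
            for k in self.params["costs"]["weekly_state_costs"]
        ]
        return sorted(paths)

    @staticmethod
    def clamp_bounds(path: str) -> tuple[float, float]:
        """Admissible interval for a perturbed value of this parameter."""
        if path.startswith(_PROB_LIKE_PREFIXES):
            return (0.0, 1.0)
        return (0.0, float("inf"))

    # -- domain object builders -------------------------------------------

    def utility_table(self) -> UtilityTable:
        return UtilityTable(**self.params["utilities"])

    def cost_deck(self) -> CostDeck:
        return CostDeck(**self.params["costs"])

    def discount_spec(self) -> DiscountSpec:
        return DiscountSpec(**self.params["discount"])

    def probabilities(self, arm: Literal["heberprot_gwc", "gwc"]) -> WeeklyProbabilities:
        p = self.params["probs"][arm]
        return WeeklyProbabilities(
            p_heal=p["p_heal"], p_amp=p["p_amp"], p_rec=self.params["probs"]["p_rec"]
        )

    def transition_model(self, arm: Literal["heberprot_gwc", "gwc"]) -> TransitionModel:
        """Arm model: arm-specific probabilities in phase 1, comparator
        probabilities thereafter and after amputation (both arms)."""
        s = self.params["structure"]
        own = self.probabilities(arm)
        gwc = self.probabilities("gwc")
        return TransitionModel(
            arm=arm,
            phase1_weeks=s["phase1_weeks"],
            p_heal_phase1=own.p_heal,
            p_amp_phase1=own.p_amp,
            p_heal_phase2=gwc.p_heal,
            p_amp_phase2=gwc.p_amp,
            p_rec=own.p_rec,
            p_heal_post_amp=gwc.p_heal,
            p_amp_post_amp=gwc.p_amp,
            leg_fraction=s["leg_fraction"],
            t_tunnel=s["t_tunnel"],
            allow_reamputation=s["allow_reamputation"],
        )

    @property
    def avg_monthly_salary(self) -> float:
        return self.params["salary"]

    @property
    def owsa_perturbation(self) -> float:
        return self.params["owsa_perturbation"]


def resolve(deck: ConfigDeck) -> ResolvedDeck:
    """Concrete parameter space from a validated deck, calibrating weekly
    probabilities from trial targets when targets were supplied."""
    if deck.weekly_probabilities is not None:
        wp = deck.weekly_probabilities
        probs = {
            "heberprot_gwc": {"p_heal": wp.heberprot_gwc.p_heal, "p_amp": wp.heberprot_gwc.p_amp},
            "gwc": {"p_heal": wp.gwc.p_heal, "p_amp": wp.gwc.p_amp},
            "p_rec": wp.p_rec,
        }
    else:
        tt = deck.trial_targets
        assert tt is not None
        n_cycles = 52
        p_rec = calibration.recurrence_probability(
            tt.recurrence.events, tt.recurrence.denominator, n_cycles
        )
        probs = {"p_rec": p_rec}
        for arm_name, arm_cfg in (("heberprot_gwc", tt.heberprot_gwc), ("gwc", tt.gwc)):
            p_heal, p_amp = calibration.calibrate_competing(
                arm_cfg.closure_52w, arm_cfg.amputation_52w, n_cycles
            )
            probs[arm_name] = {"p_heal": p_heal, "p_amp": p_amp}

    params = {
        "probs": probs,
        "structure": deck.structure.model_dump(),
        "utilities": deck.utilities.model_dump(),
        "costs": deck.costs.model_dump(),
        "discount": deck.discount.model_dump(),
        "salary": deck.avg_monthly_salary,
        "owsa_perturbation": deck.owsa.perturbation,
    }
    return ResolvedDeck(
        params=params,
        label=deck.label,
        seed=deck.seed,
        hash=deck_hash(deck),
        horizons_years=tuple(deck.horizons_years),
    )


def trial_targets_from_deck(deck: ConfigDeck) -> dict[str, TrialTargets]:
    """Domain `TrialTargets` per arm (empty when the deck carries
    precomputed probabilities)."""
    if deck.trial_targets is None:
        return {}
    tt = deck.trial_targets
    out = {}
    for arm_name, arm_cfg in (("heberprot_gwc", tt.heberprot_gwc), ("gwc", tt.gwc)):
        out[arm_name] = TrialTargets(
            arm=arm_name,
            closure_52w=arm_cfg.closure_52w,
            amputation_52w=arm_cfg.amputation_52w,
            recurrence_events=tt.recurrence.events,
            recurrence_denominator=tt.recurrence.denominator,
        )
    return out
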