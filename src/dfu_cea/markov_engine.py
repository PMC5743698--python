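"""Weekly-cycle cohort state-transition engine for diabetic foot ulcer.

The cohort moves between five reported health states — no ulcer, ulcer,
amputation, no ulcer after amputation, ulcer after amputation — with the
whole cohort starting in *ulcer*.  Internally the amputation state is
expanded into a tunnel of fixed length (the acute post-amputation period)
split by amputation type (small vs leg), and the two after-amputation
states are likewise split by type, so that utilities and costs can differ
between small and leg amputations while reporting stays in the five-state
vocabulary.

Death is not modelled: occupancy is conserved exactly (each trace row sums
to one), which every operation here checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "HealthState",
    "StateSpace",
    "TransitionModel",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "aggregate_trace",
]

_CONSERVATION_TOL = 1e-12


class HealthState(str, Enum):
    """The five mutually exclusive reported health states."""

    NO_ULCER = "no_ulcer"
    ULCER = "ulcer"
    AMPUTATION = "amputation"
    NO_ULCER_AFTER_AMPUTATION = "no_ulcer_after_amputation"
    ULCER_AFTER_AMPUTATION = "ulcer_after_amputation"


@dataclass(frozen=True)
class StateSpace:
    """Expanded state space for a given tunnel length.

    Labels, in order: ``no_ulcer``, ``ulcer``, ``amp_tunnel_small_k`` and
    ``amp_tunnel_leg_k`` for k = 1..t_tunnel, then the four post-amputation
    states.  Tunnel states advance deterministically one step per cycle and
    exit into the matching ``post_amp_*_no_ulcer`` state.
    """

    t_tunnel: int

    def __post_init__(self) -> None:
        if self.t_tunnel < 1:
            raise ValueError(f"t_tunnel must be >= 1, got {self.t_tunnel}")

    @property
    def labels(self) -> tuple[str, ...]:
        tunnel = [f"amp_tunnel_small_{k}" for k in range(1, self.t_tunnel + 1)]
        tunnel += [f"amp_tunnel_leg_{k}" for k in range(1, self.t_tunnel + 1)]
        return tuple(
            ["no_ulcer", "ulcer"]
            + tunnel
            + [
                "post_amp_small_no_ulcer",
                "post_amp_small_ulcer",
                "post_amp_leg_no_ulcer",
                "post_amp_leg_ulcer",
            ]
        )

    @property
    def n_states(self) -> int:
        return 6 + 2 * self.t_tunnel

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown state label: {label!r}") from None

    def health_state(self, label: str) -> HealthState:
        """Map an expanded label to its reported five-state label."""
        if label in ("no_ulcer", "ulcer"):
            return HealthState(label)
        if label.startswith("amp_tunnel_"):
            return HealthState.AMPUTATION
        if label.endswith("_no_ulcer"):
            return HealthState.NO_ULCER_AFTER_AMPUTATION
        if label.startswith("post_amp_") and label.endswith("_ulcer"):
            return HealthState.ULCER_AFTER_AMPUTATION
        raise KeyError(f"unknown state label: {label!r}")

    def cost_group(self, label: str) -> str:
        """Collapse the tunnel index so cost decks can be keyed compactly."""
        if label.startswith("amp_tunnel_small"):
            return "amp_tunnel_small"
        if label.startswith("amp_tunnel_leg"):
            return "amp_tunnel_leg"
        return label


@dataclass(frozen=True)
class TransitionModel:
    """Per-arm weekly transition probabilities with a two-phase time axis.

    Arm-specific heal/amputate probabilities apply for weeks 1..phase1_weeks
    (the trial observation period); thereafter both arms fall back to the
    comparator (GWC) probabilities.  Recurrence and the post-amputation
    probabilities are shared between arms throughout.

    Parameters
    ----------
    arm:
        ``"heberprot_gwc"`` or ``"gwc"``; informational only — the phase-1
        probabilities passed in already embody the arm.
    p_heal_phase1, p_amp_phase1:
        Weekly probabilities of ulcer closure / amputation from *ulcer*
        during phase 1.
    p_heal_phase2, p_amp_phase2:
        The same after phase 1 (comparator values for both arms).
    p_rec:
        Weekly recurrence probability from any healed state.
    p_heal_post_amp, p_amp_post_amp:
        Weekly closure / re-amputation probabilities from
        *ulcer after amputation*.
    leg_fraction:
        Proportion of amputation events that are leg (major) amputations;
        the remainder are small.
    t_tunnel:
        Acute post-amputation tunnel length in weekly cycles.
    allow_reamputation:
        If False the re-amputation route is closed (``p_amp_post_amp``
        treated as 0).
    """

    arm: str = "gwc"
    phase1_weeks: int = 52
    p_heal_phase1: float = 0.0
    p_amp_phase1: float = 0.0
    p_heal_phase2: float = 0.0
    p_amp_phase2: float = 0.0
    p_rec: float = 0.0
    p_heal_post_amp: float = 0.0
    p_amp_post_amp: float = 0.0
    leg_fraction: float = 0.1208
    t_tunnel: int = 4
    allow_reamputation: bool = True

    def __post_init__(self) -> None:
        probs = {
            "p_heal_phase1": self.p_heal_phase1,
            "p_amp_phase1": self.p_amp_phase1,
            "p_heal_phase2": self.p_heal_phase2,
            "p_amp_phase2": self.p_amp_phase2,
            "p_rec": self.p_rec,
            "p_heal_post_amp": self.p_heal_post_amp,
            "p_amp_post_amp": self.p_amp_post_amp,
            "leg_fraction": self.leg_fraction,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0) or not np.isfinite(p):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for phase in (1, 2):
            h = getattr(self, f"p_heal_phase{phase}")
            a = getattr(self, f"p_amp_phase{phase}")
            if h + a > 1.0 + 1e-15:
                raise ValueError(
                    f"p_heal + p_amp exceeds 1 in phase {phase}: {h} + {a}"
                )
        if self.p_heal_post_amp + self.p_amp_post_amp > 1.0 + 1e-15:
            raise ValueError("post-amputation p_heal + p_amp exceeds 1")
        if self.t_tunnel < 1:
            raise ValueError("t_tunnel must be >= 1")
        if self.phase1_weeks < 0:
            raise ValueError("phase1_weeks must be >= 0")

    @property
    def space(self) -> StateSpace:
        return StateSpace(self.t_tunnel)

    def probabilities_at(self, week: int) -> tuple[float, float]:
        """(p_heal, p_amp) from the ulcer state in effect at `week`."""
        if week <= self.phase1_weeks:
            return self.p_heal_phase1, self.p_amp_phase1
        return self.p_heal_phase2, self.p_amp_phase2


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy fractions per cycle: rows 0..horizon_weeks, one column per
    expanded state.  Row 0 is the start vector (whole cohort in ulcer)."""

    occupancy: np.ndarray
    space: StateSpace

    def __post_init__(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != self.space.n_states:
            raise ValueError("occupancy shape does not match state space")
        if not np.all(np.isfinite(occ)):
            raise FloatingPointError("non-finite occupancy in cohort trace")
        if np.any(occ < -_CONSERVATION_TOL) or np.any(occ > 1 + _CONSERVATION_TOL):
            raise ValueError("occupancy outside [0, 1]")
        row_err = np.abs(occ.sum(axis=1) - 1.0)
        if row_err.max() > _CONSERVATION_TOL:
            cycle = int(row_err.argmax())
            raise ValueError(
                f"occupancy not conserved at cycle {cycle}: row sum error {row_err.max():.3e}"
            )

    @property
    def horizon_weeks(self) -> int:
        return self.occupancy.shape[0] - 1

    def column(self, label: str) -> np.ndarray:
        return self.occupancy[:, self.space.index(label)]

    def to_frame(self) -> pd.DataFrame:
        """Long-form export: cycle, each expanded state, each reported state."""
        df = pd.DataFrame(self.occupancy, columns=list(self.space.labels))
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        agg = aggregate_trace(self)
        for state in HealthState:
            df[state.value] = agg[:, list(HealthState).index(state)]
        return df


def build_transition_matrix(model: TransitionModel, week: int) -> np.ndarray:
    """One-cycle row-stochastic transition matrix in effect at `week`.

    Routes: ulcer → no_ulcer (heal) or into a fresh tunnel (amputate, split
    leg/small by ``leg_fraction``), remainder stays; no_ulcer → ulcer
    (recurrence); tunnel states advance and exit to the matching post-amp
    no-ulcer state; post-amp states mirror the ulcer/no-ulcer logic with the
    shared post-amputation probabilities.
    """
    if week < 1:
        raise ValueError(f"week must be >= 1, got {week}")
    space = model.space
    n = space.n_states
    idx = space.index
    P = np.zeros((n, n))

    p_heal, p_amp = model.probabilities_at(week)
    lf = model.leg_fraction

    # healed, never amputated
    i = idx("no_ulcer")
    P[i, idx("ulcer")] = model.p_rec
    P[i, i] = 1.0 - model.p_rec

    # active ulcer: competing heal vs amputate
    i = idx("ulcer")
    P[i, idx("no_ulcer")] = p_heal
    P[i, idx("amp_tunnel_leg_1")] = p_amp * lf
    P[i, idx("amp_tunnel_small_1")] = p_amp * (1.0 - lf)
    P[i, i] = 1.0 - p_heal - p_amp

    # acute post-amputation tunnels: deterministic advance, then exit
    for kind in ("small", "leg"):
        for k in range(1, model.t_tunnel + 1):
            i = idx(f"amp_tunnel_{kind}_{k}")
            if k < model.t_tunnel:
                P[i, idx(f"amp_tunnel_{kind}_{k + 1}")] = 1.0
            else:
                P[i, idx(f"post_amp_{kind}_no_ulcer")] = 1.0

    # post-amputation, no ulcer: recurrence into post-amp ulcer
    for kind in ("small", "leg"):
        i = idx(f"post_amp_{kind}_no_ulcer")
        P[i, idx(f"post_amp_{kind}_ulcer")] = model.p_rec
        P[i, i] = 1.0 - model.p_rec

    # post-amputation ulcer: heal back, optionally re-amputate into a new tunnel
    p_reamp = model.p_amp_post_amp if model.allow_reamputation else 0.0
    for kind in ("small", "leg"):
        i = idx(f"post_amp_{kind}_ulcer")
        P[i, idx(f"post_amp_{kind}_no_ulcer")] = model.p_heal_post_amp
        P[i, idx("amp_tunnel_leg_1")] += p_reamp * lf
        P[i, idx("amp_tunnel_small_1")] += p_reamp * (1.0 - lf)
        P[i, i] = 1.0 - model.p_heal_post_amp - p_reamp

    row_sums = P.sum(axis=1)
    bad = np.abs(row_sums - 1.0) > _CONSERVATION_TOL
    if bad.any():
        label = space.labels[int(np.argmax(bad))]
        raise ValueError(f"transition row for {label!r} does not sum to 1")
    return P


def run_cohort(model: TransitionModel, horizon_weeks: int) -> CohortTrace:
    """Propagate the cohort for `horizon_weeks` weekly cycles.

    The whole cohort starts in *ulcer* at cycle 0.  Since the probabilities
    are piecewise constant in time, only the phase-1 and phase-2 matrices
    are built; row w is row (w-1) times the matrix in effect at week w.
    """
    if horizon_weeks < 1:
        raise ValueError(f"horizon_weeks must be >= 1, got {horizon_weeks}")
    space = model.space
    occ = np.zeros((horizon_weeks + 1, space.n_states))
    occ[0, space.index("ulcer")] = 1.0

    P1 = build_transition_matrix(model, 1)
    P2 = build_transition_matrix(model, max(model.phase1_weeks + 1, 1))
    for w in range(1, horizon_weeks + 1):
        P = P1 if w <= model.phase1_weeks else P2
        occ[w] = occ[w - 1] @ P
    if not np.all(np.isfinite(occ)):
        raise FloatingPointError("non-finite occupancy during cohort run")
    return CohortTrace(occupancy=occ, space=space)


def aggregate_trace(trace: CohortTrace) -> np.ndarray:
    """Sum expanded-state occupancy into the five reported health states.

    Returns a [cycle, HealthState] matrix with columns ordered as the
    ``HealthState`` enum; row sums are preserved.
    """
    states = list(HealthState)
    out = np.zeros((trace.occupancy.shape[0], len(states)))
    for j, label in enumerate(trace.space.labels):
        out[:, states.index(trace.space.health_state(label))] += trace.occupancy[:, j]
    return out
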