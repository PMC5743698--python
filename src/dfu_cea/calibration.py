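"""Calibrate weekly transition probabilities from 52-week trial outcomes.

The trial reports cumulative 52-week proportions of first ulcer closure and
first amputation.  Under constant weekly cause-specific probabilities the
two events compete for exit from the ulcer state, so the total exit
probability per cycle is recovered from the cumulative exit proportion by
the standard geometric conversion and then split between causes in
proportion to their cumulative shares.  This closed form reproduces both
cumulative incidences exactly, which `verify_calibration` checks by forward
simulation.

Recurrence follows the source study's pooling rule: recurrent cases divided
by the pooled two-arm population, treated as a 52-week cumulative
proportion (time-at-risk is deliberately ignored, matching the rule).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TrialTargets",
    "WeeklyProbabilities",
    "CalibrationReport",
    "weekly_from_cumulative",
    "calibrate_competing",
    "recurrence_probability",
    "verify_calibration",
    "simulate_two_exit_chain",
    "calibrate_targets",
]


@dataclass(frozen=True)
class TrialTargets:
    """Cumulative 52-week outcome proportions for one arm, plus the pooled
    recurrence count."""

    arm: str
    closure_52w: float
    amputation_52w: float
    recurrence_events: int = 0
    recurrence_denominator: int = 1

    def __post_init__(self) -> None:
        if self.closure_52w < 0 or self.amputation_52w < 0:
            raise ValueError("target proportions must be non-negative")
        if self.closure_52w + self.amputation_52w > 1.0:
            raise ValueError(
                f"closure + amputation exceeds 1 for arm {self.arm!r}: "
                f"{self.closure_52w} + {self.amputation_52w}"
            )
        if self.recurrence_denominator <= 0:
            raise ValueError("recurrence denominator must be positive")
        if not 0 <= self.recurrence_events <= self.recurrence_denominator:
            raise ValueError("recurrence events must be within [0, denominator]")


@dataclass(frozen=True)
class WeeklyProbabilities:
    """Constant per-cycle probabilities implied by one arm's targets."""

    p_heal: float
    p_amp: float
    p_rec: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_heal", "p_amp", "p_rec"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.p_heal + self.p_amp > 1.0 + 1e-15:
            raise ValueError("p_heal + p_amp exceeds 1")


def weekly_from_cumulative(cum_prob: float, n_cycles: int) -> float:
    """Per-cycle probability whose n-cycle cumulative incidence is `cum_prob`.

    Inverse of ``1 - (1 - p)**n_cycles``.
    """
    if not 0.0 <= cum_prob < 1.0:
        raise ValueError(f"cumulative probability must be in [0, 1), got {cum_prob}")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    return 1.0 - (1.0 - cum_prob) ** (1.0 / n_cycles)


def calibrate_competing(
    closure_52w: float, amputation_52w: float, n_cycles: int = 52
) -> tuple[float, float]:
    """Weekly (p_heal, p_amp) reproducing the cumulative targets exactly.

    With total cumulative exit E = closure + amputation, the per-cycle exit
    probability is s = 1 - (1-E)^(1/n); the cause-specific probabilities
    split s in proportion to the cumulative shares.  A patient exiting at
    cycle k then healed with probability p_heal/s regardless of k, so the
    cumulative closure over n cycles is (p_heal/s)·E·(E-normalised) =
    closure exactly, and likewise for amputation.
    """
    if closure_52w < 0 or amputation_52w < 0:
        raise ValueError("targets must be non-negative")
    total = closure_52w + amputation_52w
    if total >= 1.0:
        raise ValueError(
            "closure + amputation >= 1: certain exit cannot be represented by "
            "a constant weekly probability over a finite horizon"
        )
    if total == 0.0:
        return 0.0, 0.0
    s = weekly_from_cumulative(total, n_cycles)
    return s * closure_52w / total, s * amputation_52w / total


def recurrence_probability(events: int, denominator: int, n_cycles: int = 52) -> float:
    """Weekly recurrence probability from the pooled-count rule.

    The cumulative recurrence proportion is events/denominator (the source
    study's rule: recurrent cases over the pooled two-arm population),
    converted to a per-cycle probability over `n_cycles`.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= events <= denominator:
        raise ValueError("events must be within [0, denominator]")
    cumulative = events / denominator
    if cumulative >= 1.0:
        raise ValueError("all patients recurring implies cumulative 1, not representable")
    return weekly_from_cumulative(cumulative, n_cycles)


def simulate_two_exit_chain(
    p_heal: float, p_amp: float, n_cycles: int
) -> tuple[float, float]:
    """Cumulative (closure, amputation) after n cycles of the two-exit chain.

    Independent forward recursion used as the round-trip oracle for
    `calibrate_competing`; kept free of the engine's matrix machinery.
    """
    in_ulcer = 1.0
    healed = 0.0
    amputated = 0.0
    for _ in range(n_cycles):
        healed += in_ulcer * p_heal
        amputated += in_ulcer * p_amp
        in_ulcer *= 1.0 - p_heal - p_amp
    return healed, amputated


@dataclass(frozen=True)
class CalibrationReport:
    """Absolute round-trip errors of a calibrated probability pair."""

    arm: str
    closure_error: float
    amputation_error: float
    tolerance: float = 1e-10

    @property
    def passed(self) -> bool:
        return self.closure_error < self.tolerance and self.amputation_error < self.tolerance


def verify_calibration(
    probs: WeeklyProbabilities,
    targets: TrialTargets,
    n_cycles: int = 52,
    tolerance: float = 1e-10,
) -> CalibrationReport:
    """Forward-simulate the two-exit chain and report |simulated - target|."""
    closure, amputation = simulate_two_exit_chain(probs.p_heal, probs.p_amp, n_cycles)
    return CalibrationReport(
        arm=targets.arm,
        closure_error=abs(closure - targets.closure_52w),
        amputation_error=abs(amputation - targets.amputation_52w),
        tolerance=tolerance,
    )


def calibrate_targets(targets: TrialTargets, n_cycles: int = 52) -> WeeklyProbabilities:
    """Convenience wrapper: full `WeeklyProbabilities` from one arm's targets."""
    p_heal, p_amp = calibrate_competing(
        targets.closure_52w, targets.amputation_52w, n_cycles
    )
    p_rec = recurrence_probability(
        targets.recurrence_events, targets.recurrence_denominator, n_cycles
    )
    return WeeklyProbabilities(p_heal=p_heal, p_amp=p_amp, p_rec=p_rec)
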