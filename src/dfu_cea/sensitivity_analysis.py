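"""One-way deterministic sensitivity analysis (tornado) over deck scalars.

Each scalar input is perturbed to ×(1−δ) and ×(1+δ) of its base value
(default δ = 10%), one at a time with all other inputs at base, the full
pipeline is re-run, and the resulting ICERs are tabulated sorted by span
(|ICER_high − ICER_low|) descending, ties broken lexicographically by
parameter name.  Perturbed probabilities and utility multipliers are
clamped to [0, 1]; a perturbed deck that still fails validation is flagged
in the output rather than silently dropped.  The whole analysis is
deterministic: identical decks give byte-identical tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import pandas as pd

if TYPE_CHECKING:  # avoid import cycle with pipeline
    from .config import ResolvedDeck

log = logging.getLogger("dfu_cea")

__all__ = ["TornadoEntry", "run_owsa", "tornado_frame", "tornado_plot"]


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    base_value: float
    low_value: float
    high_value: float
    icer_low: float  # NaN when not a ratio (dominance / undefined / invalid)
    icer_high: float
    status_low: str
    status_high: str

    @property
    def span(self) -> float:
        if math.isnan(self.icer_low) or math.isnan(self.icer_high):
            return float("nan")
        return abs(self.icer_high - self.icer_low)


def _icer_at(rd: "ResolvedDeck", path: str, value: float, horizon_weeks: int):
    """(icer_value, status) of the pipeline with one parameter replaced."""
    from .health_economics import UndefinedICERError
    from .pipeline import run_cea

    try:
        cea = run_cea(rd.with_value(path, value), horizon_weeks)
        icer = cea.icer
    except UndefinedICERError:
        return float("nan"), "undefined"
    except (ValueError, KeyError) as err:
        log.warning("OWSA: perturbed deck invalid at %s=%s: %s", path, value, err)
        return float("nan"), "invalid"
    if icer.is_ratio:
        return float(icer.value), "ok"
    return float("nan"), icer.kind


def run_owsa(
    rd: "ResolvedDeck", horizon_weeks: int, perturbation: float = 0.10
) -> tuple[float, list[TornadoEntry]]:
    """Tornado table for one horizon.

    Returns (base ICER, entries sorted by span descending).  Exactly two
    pipeline re-runs per parameter; a parameter whose base value is zero is
    unchanged by a multiplicative perturbation and contributes a zero span.
    """
    from .pipeline import run_cea

    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    base_cea = run_cea(rd, horizon_weeks)
    base_icer_obj = base_cea.icer
    base_icer = base_icer_obj.value if base_icer_obj.is_ratio else float("nan")

    entries = []
    for path in rd.scalar_paths():
        base = float(rd.get(path))
        lo_bound, hi_bound = rd.clamp_bounds(path)
        low = min(max(base * (1.0 - perturbation), lo_bound), hi_bound)
        high = min(max(base * (1.0 + perturbation), lo_bound), hi_bound)
        if high < base * (1.0 + perturbation):
            log.warning("OWSA: %s high value clamped to %s", path, high)
        icer_low, status_low = _icer_at(rd, path, low, horizon_weeks)
        icer_high, status_high = _icer_at(rd, path, high, horizon_weeks)
        entries.append(
            TornadoEntry(
                parameter=path,
                base_value=base,
                low_value=low,
                high_value=high,
                icer_low=icer_low,
                icer_high=icer_high,
                status_low=status_low,
                status_high=status_high,
            )
        )
    # NaN spans (flagged entries) sort last; ties broken by name
    entries.sort(
        key=lambda e: (
            math.isnan(e.span),
            -(e.span if not math.isnan(e.span) else 0.0),
            e.parameter,
        )
    )
    return base_icer, entries


def tornado_frame(entries: list[TornadoEntry], base_icer: float) -> pd.DataFrame:
    """Tabular tornado artifact (one row per parameter, sorted by span)."""
    if not entries:
        raise ValueError("no tornado entries")
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "base_value": e.base_value,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "span": e.span,
                "status_low": e.status_low,
                "status_high": e.status_high,
                "base_icer": base_icer,
            }
            for e in entries
        ]
    )


def tornado_plot(entries: list[TornadoEntry], base_icer: float, path: str, top: int = 15):
    """Horizontal-bar tornado diagram (largest spans at the top)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = [e for e in entries if not math.isnan(e.span)][:top]
    if not shown:
        raise ValueError("no plottable tornado entries")
    shown = shown[::-1]  # largest span on top
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(shown) + 1.5))
    for i, e in enumerate(shown):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(base_icer, color="black", lw=1, ls="--", label="base ICER")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.parameter for e in shown], fontsize=8)
    ax.set_xlabel("ICER (€ per QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
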