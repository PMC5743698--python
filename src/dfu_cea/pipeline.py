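"""End-to-end analysis: calibrate, simulate both arms, value, compare.

`run_cea` executes one horizon: cohort traces for both arms, discounted
QALY/cost accumulation (drug course charged to the treated arm only), the
ICER against the salary-derived willingness-to-pay thresholds, and the
reimbursement verdict.  `run_full_analysis` repeats this per configured
horizon and adds the one-way sensitivity tables.  `solve_threshold_price`
inverts the drug unit price at a threshold; ΔCost is affine in the unit
price, and the slope is measured from two pipeline runs so the inversion
is exact under either drug-cost charging convention.

Every CSV writer embeds the deck hash so outputs are traceable to their
inputs; results are a pure function of the deck.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import ConfigDeck, ResolvedDeck, resolve
from .health_economics import (
    CEAResult,
    Icer,
    UndefinedICERError,
    accumulate_outcomes,
    thresholds_from_salary,
)
from .markov_engine import CohortTrace, run_cohort
from .sensitivity_analysis import TornadoEntry, run_owsa, tornado_frame

log = logging.getLogger("dfu_cea")

__all__ = [
    "HorizonResult",
    "AnalysisBundle",
    "run_cea",
    "run_full_analysis",
    "solve_threshold_price",
    "write_results_csv",
    "write_trace_csv",
    "write_calibration_csv",
]

WEEKS_PER_YEAR = 52


def _icer_or_undefined(cea: CEAResult) -> Icer | None:
    """The ICER, or None when ΔQALY is zero and no ratio exists."""
    try:
        return cea.icer
    except UndefinedICERError:
        return None


@dataclass(frozen=True)
class HorizonResult:
    horizon_years: int
    cea: CEAResult
    trace_treated: CohortTrace
    trace_control: CohortTrace
    tornado: list[TornadoEntry] | None = None


@dataclass(frozen=True)
class AnalysisBundle:
    deck_label: str
    deck_hash: str
    resolved: ResolvedDeck
    horizons: dict[int, HorizonResult] = field(default_factory=dict)


def run_cea(rd: ResolvedDeck, horizon_weeks: int) -> CEAResult:
    """One horizon's cost-utility comparison of treated vs control arm."""
    u = rd.utility_table()
    c = rd.cost_deck()
    d = rd.discount_spec()
    lambda1, lambda2 = thresholds_from_salary(rd.avg_monthly_salary)

    trace_t = run_cohort(rd.transition_model("heberprot_gwc"), horizon_weeks)
    trace_c = run_cohort(rd.transition_model("gwc"), horizon_weeks)
    qaly_t, cost_t = accumulate_outcomes(trace_t, u, c, d, treated=True)
    qaly_c, cost_c = accumulate_outcomes(trace_c, u, c, d, treated=False)
    return CEAResult(
        horizon_weeks=horizon_weeks,
        qaly_treated=qaly_t,
        cost_treated=cost_t,
        qaly_control=qaly_c,
        cost_control=cost_c,
        lambda1=lambda1,
        lambda2=lambda2,
    )


def run_full_analysis(deck: ConfigDeck, with_owsa: bool = True) -> AnalysisBundle:
    """Calibrate, run every configured horizon, and (optionally) the OWSA."""
    rd = resolve(deck)
    bundle = AnalysisBundle(deck_label=deck.label, deck_hash=rd.hash, resolved=rd)
    for years in rd.horizons_years:
        t0 = time.perf_counter()
        horizon_weeks = years * WEEKS_PER_YEAR
        cea = run_cea(rd, horizon_weeks)
        trace_t = run_cohort(rd.transition_model("heberprot_gwc"), horizon_weeks)
        trace_c = run_cohort(rd.transition_model("gwc"), horizon_weeks)
        tornado = None
        if with_owsa:
            _, tornado = run_owsa(rd, horizon_weeks, rd.owsa_perturbation)
        bundle.horizons[years] = HorizonResult(
            horizon_years=years,
            cea=cea,
            trace_treated=trace_t,
            trace_control=trace_c,
            tornado=tornado,
        )
        icer = _icer_or_undefined(cea)
        log.info(
            "horizon=%dy deck=%s delta_qaly=%.4f delta_cost=%.0f icer=%s "
            "verdict=%s elapsed=%.2fs",
            years,
            rd.hash,
            cea.delta_qaly,
            cea.delta_cost,
            "undefined" if icer is None else (f"{icer.value:.0f}" if icer.is_ratio else icer.kind),
            "undefined" if icer is None else cea.verdict.value,
            time.perf_counter() - t0,
        )
    return bundle


def solve_threshold_price(
    rd: ResolvedDeck, lam: float, horizon_weeks: int
) -> float | None:
    """Drug unit price at which the ICER equals `lam` on this deck.

    Measures ΔCost at unit prices 0 and 1 (two full pipeline runs) to get
    the intercept and the exact per-euro slope, then inverts the affine
    relation.  Returns None when no positive price reaches the threshold.
    """
    cea0 = run_cea(rd.with_value("costs.drug_unit_cost", 0.0), horizon_weeks)
    cea1 = run_cea(rd.with_value("costs.drug_unit_cost", 1.0), horizon_weeks)
    delta_qaly = cea0.delta_qaly
    if delta_qaly <= 0:
        raise ValueError("threshold price requires a positive QALY gain")
    slope = cea1.delta_cost - cea0.delta_cost  # EUR of ΔCost per EUR of unit price
    if slope <= 0:
        raise ValueError("drug exposure (units/week × weeks) must be positive")
    price = (lam * delta_qaly - cea0.delta_cost) / slope
    return price if price > 0 else None


# ---------------------------------------------------------------------------
# CSV writers — each embeds the deck hash as a leading comment line


def _write_with_hash(df: pd.DataFrame, path: Path, deck_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# deck_hash={deck_hash}\n")
        df.to_csv(fh, index=False)


def results_frame(bundle: AnalysisBundle) -> pd.DataFrame:
    rows = []
    for years, hr in sorted(bundle.horizons.items()):
        cea = hr.cea
        icer = _icer_or_undefined(cea)
        rows.append(
            {
                "horizon_years": years,
                "qaly_heberprot_gwc": cea.qaly_treated,
                "qaly_gwc": cea.qaly_control,
                "delta_qaly": cea.delta_qaly,
                "cost_heberprot_gwc": cea.cost_treated,
                "cost_gwc": cea.cost_control,
                "delta_cost": cea.delta_cost,
                "icer_eur_per_qaly": (
                    icer.value if icer is not None and icer.is_ratio else float("nan")
                ),
                "icer_kind": icer.kind if icer is not None else "undefined",
                "lambda1": cea.lambda1,
                "lambda2": cea.lambda2,
                "verdict": cea.verdict.value if icer is not None else "undefined",
            }
        )
    return pd.DataFrame(rows)


def write_results_csv(bundle: AnalysisBundle, path: str | Path) -> None:
    _write_with_hash(results_frame(bundle), Path(path), bundle.deck_hash)


def write_trace_csv(trace: CohortTrace, path: str | Path, deck_hash: str) -> None:
    df = trace.to_frame()
    df.insert(1, "week", df["cycle"])
    _write_with_hash(df, Path(path), deck_hash)


def write_calibration_csv(
    report_rows: list[dict], path: str | Path, deck_hash: str
) -> None:
    _write_with_hash(pd.DataFrame(report_rows), Path(path), deck_hash)


def write_tornado_csv(
    entries: list[TornadoEntry], base_icer: float, path: str | Path, deck_hash: str
) -> None:
    _write_with_hash(tornado_frame(entries, base_icer), Path(path), deck_hash)
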