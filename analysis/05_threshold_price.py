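"""Invert the drug unit price at the reimbursement thresholds.

Solves for the price per injection at which the 10-year ICER equals the
lower (24× salary) and upper (35× salary) willingness-to-pay thresholds,
and verifies each solution by re-running the pipeline at the solved price.
"""

import argparse
from pathlib import Path

import pandas as pd

from dfu_cea.config import load_and_validate, resolve
from dfu_cea.health_economics import thresholds_from_salary
from dfu_cea.pipeline import run_cea, solve_threshold_price


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", type=Path, default=Path("results/reference_deck.yaml"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--horizon-years", type=int, default=10)
    args = ap.parse_args()

    rd = resolve(load_and_validate(args.config))
    weeks = args.horizon_years * 52
    lambda1, lambda2 = thresholds_from_salary(rd.avg_monthly_salary)
    current = rd.get("costs.drug_unit_cost")

    rows = []
    for name, lam in (("lambda1", lambda1), ("lambda2", lambda2)):
        price = solve_threshold_price(rd, lam, weeks)
        if price is None:
            print(f"{name} ({lam:,.0f}): no positive unit price reaches the threshold")
            continue
        check = run_cea(rd.with_value("costs.drug_unit_cost", price), weeks).icer.value
        rows.append({"threshold": name, "wtp_eur_per_qaly": lam,
                     "unit_price_eur": price, "icer_at_price": check})
        print(f"{name} ({lam:,.0f} EUR/QALY): unit price {price:.2f} EUR "
              f"(current {current:.2f}); ICER at that price {check:,.1f}")
    df = pd.DataFrame(rows)
    path = args.out_dir / "threshold_prices.csv"
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    print(f"threshold prices -> {path}")


if __name__ == "__main__":
    main()
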