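"""One-way ±10% deterministic sensitivity analysis (tornado) per horizon.

Perturbs every scalar deck input one at a time, re-runs the full pipeline,
and writes a span-ordered tornado table and diagram for the 5- and 10-year
horizons.  Prints the top drivers of the ICER.
"""

import argparse
from pathlib import Path

from dfu_cea.config import load_and_validate, resolve
from dfu_cea.pipeline import write_tornado_csv
from dfu_cea.sensitivity_analysis import run_owsa, tornado_frame, tornado_plot


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", type=Path, default=Path("results/reference_deck.yaml"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    rd = resolve(load_and_validate(args.config))
    for years in rd.horizons_years:
        base, entries = run_owsa(rd, years * 52, rd.owsa_perturbation)
        write_tornado_csv(entries, base, args.out_dir / f"tornado_{years}y.csv", rd.hash)
        tornado_plot(entries, base, str(args.out_dir / f"tornado_{years}y.png"))
        top = tornado_frame(entries, base).head(3)
        print(f"{years}y horizon: base ICER {base:,.0f} EUR/QALY; top drivers:")
        for _, row in top.iterrows():
            print(f"  {row.parameter}: span {row.span:,.0f} "
                  f"(low {row.icer_low:,.0f}, high {row.icer_high:,.0f})")


if __name__ == "__main__":
    main()
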