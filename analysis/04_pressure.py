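#!/usr/bin/env python
"""Human-population pressure on the forecast ranges.

Reads the report bundle produced by 03_exposure.py and summarises (a) the
suitability-weighted human population density each species experiences per
period (group quartiles, the boxplot-style view), and (b) the spatial
overlap between cells where 80-100% of the local species pool loses
suitability by 2080 and cells whose HPD exceeds the high-pressure benchmark
(50.14 people/km^2), now and in 2080.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RUN = ROOT / "scratch" / "run"


def main() -> None:
    if not (RUN / "report.json").exists():
        raise SystemExit("run analysis/03_exposure.py first")
    hpd = pd.read_csv(RUN / "weighted_hpd_consensus.csv")
    occ = pd.read_csv(RUN / "species_exposure.csv")[
        ["species_id", "habitat_group"]].drop_duplicates()
    hpd = hpd.merge(occ, on="species_id")
    sel = hpd[(hpd.dispersal_km == 100.0)
              & ((hpd.co2 == "plus") | (hpd.period == "baseline"))]
    q = (sel.groupby(["habitat_group", "period"]).weighted_hpd_mean
         .describe(percentiles=[0.25, 0.5, 0.75])
         [["min", "25%", "50%", "75%", "max"]].round(1).reset_index())
    out = ROOT / "results" / "04_weighted_hpd_quartiles.csv"
    q.to_csv(out, index=False)

    report = json.loads((RUN / "report.json").read_text())
    ov = report["overlap"]["all"]
    print("weighted HPD within 100-km dispersal ranges (+CO2), by group:")
    print(q.to_string(index=False))
    print(f"\nhigh-loss cells (80-100% of local pool losing by 2080): "
          f"{ov['n_high_loss_cells']}")
    print(f"  with 2080 HPD over benchmark: "
          f"{ov['pct_high_loss_cells_over_threshold_future']:.1f}%")
    print(f"  already over benchmark now:   "
          f"{ov['pct_high_loss_cells_over_threshold_now']:.1f}%")
    pct = report["pct_species_weighted_hpd_over_benchmark_2080_plus"]
    print(f"species above benchmark HPD by 2080: all {pct['all']:.1f}%")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
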