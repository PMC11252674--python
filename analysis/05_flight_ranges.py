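#!/usr/bin/env python
"""Departure scenarios: flight ranges and the share reaching the coast.

Translates scenario SST values into condition offsets through the
model-averaged effect curve, draws 100 departure fuel loads per age class,
simulates each bird's maximum range at the wind-assisted airspeed, and
reports medians, IQRs, the proportion covering the 3205 km minimum
migration distance, and the relative decline versus the long-term-trend
reference SST.
"""

import json
from pathlib import Path

import pandas as pd

from stagefuel.pipeline import (RunConfig, condition_stage, fly_stage,
                                generate_stage, scan_stage)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    config = RunConfig(scan_variables=("avg_sst_prev_year",))
    _, weather, captures, _ = generate_stage(config)
    cond = condition_stage(captures, config)
    scan = scan_stage(cond["conditions"]["JUV"], weather, config)
    fly = fly_stage(scan["curve"], config)

    rows = []
    for sst, entry in fly["scenarios"].items():
        print(f"\nscenario SST(prev June) = {sst} C  "
              f"(condition offset {entry['offset']:.1f} %lbm"
              + (", extrapolated beyond fitted range)" if entry["extrapolated"]
                 else ")"))
        for age, r in entry["by_age"].items():
            decline = fly["declines"][sst][age]
            print(f"  {age}: median {r.median_km:,.0f} km "
                  f"IQR ({r.iqr_km[0]:,.0f}, {r.iqr_km[1]:,.0f}), "
                  f"reaching {r.proportion_reaching:.2f}, "
                  f"surplus {r.surplus_km:,.0f} km, decline {decline:.0f}%")
            rows.append(dict(sst_c=sst, age=age, median_km=r.median_km,
                             iqr_lo_km=r.iqr_km[0], iqr_hi_km=r.iqr_km[1],
                             proportion_reaching=r.proportion_reaching,
                             surplus_km=r.surplus_km,
                             relative_decline_pct=decline,
                             n_truncated=r.n_truncated,
                             condition_offset_lbm=entry["offset"]))

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "flight_scenarios.csv", index=False)
    (RESULTS / "flight_summary.json").write_text(json.dumps(
        {"reference_sst": fly["reference_sst"],
         "declines": {str(k): v for k, v in fly["declines"].items()}}, indent=2))


if __name__ == "__main__":
    main()
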