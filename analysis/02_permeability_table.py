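#!/usr/bin/env python
"""Derived permeability-table columns from the published bidirectional means.

Feeds the published per-condition Papp means (control and four refined
polysaccharide fractions, 1e-6 cm/s) through ``uptake_ratio`` and
``percent_of_control`` and compares with the published derived columns.
Writes results/permeability_table.csv.
"""

from pathlib import Path

import pandas as pd

from glucassay.io import round_half_up
from glucassay.transport import percent_of_control, uptake_ratio

OUT = Path(__file__).resolve().parent.parent / "results"

# published: condition -> (Papp AP-BL, Papp BL-AP, UR, % ctrl AP-BL, % ctrl BL-AP)
PUBLISHED = {
    "Control": (34.56, 4.68, 7.39, 100.0, 100.0),
    "RPP-1": (21.79, 5.58, 3.91, 63.05, 119.23),
    "RPP-2": (34.89, 4.57, 7.63, 100.95, 97.65),
    "RPP-3": (12.79, 7.37, 1.74, 37.01, 157.48),
    "RPP-4": (17.21, 6.54, 2.63, 69.8, 139.74),
}

def main() -> None:
    ctrl_ap, ctrl_bl = PUBLISHED["Control"][:2]
    rows = []
    for name, (ap, bl, ur_pub, pct_ap_pub, pct_bl_pub) in PUBLISHED.items():
        rows.append(
            {"sample": name,
             "papp_ap_bl_1e6": ap, "papp_bl_ap_1e6": bl,
             "uptake_ratio": round_half_up(uptake_ratio(ap, bl), 2),
             "uptake_ratio_published": ur_pub,
             "pct_ctrl_ap_bl": round_half_up(percent_of_control(ap, ctrl_ap), 2),
             "pct_ctrl_ap_bl_published": pct_ap_pub,
             "pct_ctrl_bl_ap": round_half_up(percent_of_control(bl, ctrl_bl), 2),
             "pct_ctrl_bl_ap_published": pct_bl_pub}
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "permeability_table.csv", index=False)
    print(df.to_string(index=False))
    mismatch = df[(df.uptake_ratio != df.uptake_ratio_published)
                  | (df.pct_ctrl_ap_bl != df.pct_ctrl_ap_bl_published)
                  | (df.pct_ctrl_bl_ap != df.pct_ctrl_bl_ap_published)]
    print(f"\n{len(df) * 3 - 4 - len(mismatch)} derived cells close exactly at 2 d.p.; "
          f"{len(mismatch)} row(s) carry a published cell inconsistent with its "
          "published inputs (Control UR, RPP-4 AP-BL %):")
    print(mismatch[["sample"]].to_string(index=False))

if __name__ == "__main__":
    main()
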