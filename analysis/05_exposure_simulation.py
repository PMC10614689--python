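#!/usr/bin/env python
"""Dose-normalised tumour exposure and signal decomposition.

Simulates both antibody formats' tumour kinetics at the packaged
cohort-mean parameters (two-tissue model, 70 µg dose, tumour without
pre-existing contrast enhancement), decomposes the PET signal into its
non-specific and specific components, and reports the 0-168 h AUC and
the time from which specific binding dominates.  Also writes
tissue-to-plasma ratio curves for tumour vs contralateral at the mutant
cohort means.

Writes results/exposure_curves_<fmt>.csv, results/exposure_summary.json
and results/tissue_to_plasma_ratio.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fuspet import reference
from fuspet.data_model import TimeActivityCurve
from fuspet.exposure import (
    auc,
    dose_normalized_simulation,
    specific_dominance_time,
    tissue_to_plasma_ratio,
)
from fuspet.io import save_json
from fuspet.plasma import plasma_concentration
from fuspet.synthetic import default_schedule
from fuspet.tissue import analytic_tissue_curve

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for fmt in reference.FORMATS:
        sim = dose_normalized_simulation(
            reference.plasma_means(fmt), reference.tissue_means(fmt, "pet_ce"), dose=70.0
        )
        thin = slice(None, None, 10)  # keep the written table light
        pd.DataFrame(
            {
                "time_h": sim.time[thin],
                "c_free_ug_per_mL": sim.c_free[thin],
                "c_spec_ug_per_mL": sim.c_spec[thin],
                "signal_ug_per_mL": sim.signal()[thin],
            }
        ).round(5).to_csv(OUT / f"exposure_curves_{fmt}.csv", index=False)
        summary[fmt] = {
            "auc_0_168h_ug_h_per_mL": round(auc(sim.time, sim.signal(), 0, 168), 1),
            "specific_dominance_time_h": round(specific_dominance_time(sim), 1),
        }
        print(
            f"{fmt}: AUC 0-168 h = {summary[fmt]['auc_0_168h_ug_h_per_mL']} µg·h/mL, "
            f"specific binding dominates from {summary[fmt]['specific_dominance_time_h']} h"
        )
    save_json(OUT / "exposure_summary.json", summary)

    # tumour vs contralateral tissue-to-plasma ratios (mutant means)
    sched = default_schedule()
    plasma = reference.plasma_means("C4FcMUT")
    cp = plasma_concentration(plasma, 100.0, sched.mid)
    rows = {"time_h": sched.mid}
    for region in ("t1w_mri_ce", "contralateral"):
        tp = reference.tissue_means("C4FcMUT", region)
        cf, cs = analytic_tissue_curve(plasma, 100.0, tp, sched.mid)
        tac = TimeActivityCurve(region, sched, (1 - tp.vB) * (cf + cs) + tp.vB * 0.55 * cp)
        rows[f"ratio_{region}"] = tissue_to_plasma_ratio(tac, plasma)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "tissue_to_plasma_ratio.csv", index=False)
    crossed = df.loc[df.ratio_t1w_mri_ce > df.ratio_contralateral, "time_h"]
    print(
        f"tumour ratio exceeds contralateral from {crossed.iloc[0]:.2f} h onwards "
        "(specific binding retains the mutant in the tumour)"
    )


if __name__ == "__main__":
    main()
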