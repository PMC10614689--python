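#!/usr/bin/env python
"""Fit the bicompartmental plasma model to every subject's blood curve.

Per subject: convert the image-derived blood TAC to plasma (/0.55), fit
Vc/k10/k12/k21 by weighted least squares, derive half-lives, Vp and AUC,
and freeze the parameters for the tissue fits (03).  Formats are compared
per parameter with two-sample t-tests, as is conventional for plasma PK
summaries.

Reads results/data/, writes results/plasma_fits/ and
results/plasma_cohort_table.csv.
"""

import zlib
from pathlib import Path

import pandas as pd

from fuspet.estimation import plasma_param_ttest
from fuspet.io import load_subject, save_json
from fuspet.plasma import derived_plasma_metrics, fit_plasma

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "plasma_fits"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for meta_path in sorted(DATA.glob("*_meta.yaml")):
        tac_path = meta_path.with_name(meta_path.name.replace("_meta.yaml", "_tacs.csv"))
        subject = load_subject(tac_path, meta_path)
        seed = zlib.crc32(subject.subject_id.encode()) % 2**31
        params, fit = fit_plasma(subject.blood_tac, n_starts=16, seed=seed)
        metrics = derived_plasma_metrics(params, dose=100.0)
        payload = fit.to_dict()
        payload["derived"] = {
            "initial_half_life_h": metrics.initial_half_life,
            "terminal_half_life_h": metrics.terminal_half_life,
            "Vp_mL": metrics.Vp,
        }
        save_json(OUT / f"{subject.subject_id}.json", payload)
        fmt = subject.subject_id.split("-")[0]
        rows.append(
            {
                "subject": subject.subject_id,
                "format": fmt,
                "converged": fit.converged,
                **fit.estimates,
                "Vp": metrics.Vp,
                "initial_t_half_h": metrics.initial_half_life,
                "terminal_t_half_h": metrics.terminal_half_life,
            }
        )
    df = pd.DataFrame(rows)
    summary = (
        df.groupby("format")[["Vc", "k10", "k12", "k21", "Vp", "initial_t_half_h", "terminal_t_half_h"]]
        .agg(["mean", "std"])
        .round(4)
    )
    table = summary.T.reset_index()
    table.columns = ["parameter", "stat", *summary.index]
    table.to_csv(ROOT / "results" / "plasma_cohort_table.csv", index=False)
    print(summary.T.to_string())
    for p in ("k10", "k21", "terminal_t_half_h"):
        a = df.loc[df.format == "C4", p]
        b = df.loc[df.format == "C4FcMUT", p]
        if len(a) >= 2 and len(b) >= 2:
            t, pv = plasma_param_ttest(a, b)
            print(f"t-test {p}: C4 vs mutant p = {pv:.4g}")
    n_conv = int(df.converged.sum())
    print(f"{n_conv}/{len(df)} plasma fits converged; fits under {OUT}")


if __name__ == "__main__":
    main()
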