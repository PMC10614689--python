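#!/usr/bin/env python
"""Cohort parameter tables and group statistics.

Builds the mean/SD tissue-parameter table per (format, region) from the
per-subject fits, then runs the two-factor ANOVA (format x region) with
Bonferroni-adjusted pairwise comparisons on the efflux constant k2 and
the entry constants — the comparisons that probe FcRn's role at the
blood-brain barrier.

Reads results/tissue_fits/, writes results/tissue_cohort_table.csv and
results/group_comparisons.csv.
"""

from pathlib import Path

import pandas as pd

from fuspet.estimation import group_compare, summarize_cohort
from fuspet.io import load_fit

ROOT = Path(__file__).resolve().parent.parent
FITS = ROOT / "results" / "tissue_fits"


def main() -> None:
    groups: dict[tuple[str, str], list] = {}
    rows = []
    for path in sorted(FITS.glob("*.json")):
        # filenames: <fmt>-<arm>-<idx>_<region>_<model>.json
        subject_id, rest = path.stem.split("_", 1)
        region, model = rest.rsplit("_", 1)
        fmt, arm, _ = subject_id.split("-")
        if arm != "fus":
            continue  # sham arm summarised separately below
        fit = load_fit(path)
        groups.setdefault((fmt, region), []).append(fit)
        for p, v in fit.estimates.items():
            rows.append({"format": fmt, "region": region, "parameter": p, "value": v})

    table = summarize_cohort(groups).round(4)
    table.to_csv(ROOT / "results" / "tissue_cohort_table.csv", index=False)
    print(table.to_string(index=False))

    values = pd.DataFrame(rows)
    comparisons = []
    for p in ("K_FUS", "t_FUS", "K1", "k2"):
        sub = values[values.parameter == p]
        out = group_compare(sub)
        pw = out["pairwise"].assign(parameter=p)
        comparisons.append(pw)
        for _, row in pw.iterrows():
            star = "*" if row.significant else "ns"
            print(
                f"{p:6s} {row.region:14s} {row.format_a} vs {row.format_b}: "
                f"p_adj = {row.p_adjusted:.4g} [{star}]"
            )
    pd.concat(comparisons).to_csv(ROOT / "results" / "group_comparisons.csv", index=False)
    print("\ntables -> results/tissue_cohort_table.csv, results/group_comparisons.csv")


if __name__ == "__main__":
    main()
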