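#!/usr/bin/env python
"""Between-group statistics and the trend report.

Takes results/morphometry.csv, runs one-way ANOVA with Tukey HSD
post-hoc tests per metric, and writes the group-comparison table and a
human-readable trend report under results/.  Prints the rank ordering
of the groups for the headline metrics.
"""

import argparse
from pathlib import Path

import pandas as pd

from angiotomo.morphometry import DIAMETER_BIN_LABELS, Morphometry, compare_groups, trend_report
from angiotomo.pipeline import COHORT_METRICS

ROOT = Path(__file__).resolve().parents[1]


def morphometry_from_row(row) -> Morphometry:
    return Morphometry(
        sample_id=str(row["sample_id"]), condition=str(row["condition"]),
        n_branches=int(row["n_branches"]), n_nodes=int(row["n_nodes"]),
        mean_length_um=float(row["mean_length_um"]),
        total_length_um=float(row["total_length_um"]),
        diameter_histogram=tuple(int(row[f"hist_{lbl}"]) for lbl in DIAMETER_BIN_LABELS),
        vascular_volume_fraction=float(row["vascular_volume_fraction"]),
        cavity_volume_um3=float(row["cavity_volume_um3"]),
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    results = ROOT / "results"
    table = results / "morphometry.csv"
    if not table.exists():
        raise SystemExit("no morphometry table — run 02_quantify_samples.py first")
    samples = [morphometry_from_row(r) for _, r in pd.read_csv(table).iterrows()]

    comparisons = [compare_groups(samples, m, alpha=args.alpha) for m in COHORT_METRICS]
    report = trend_report(comparisons, alpha=args.alpha)
    report.table.to_csv(results / "group_comparisons.csv", index=False)
    (results / "trend_report.md").write_text(report.text)

    for comp in comparisons:
        order = " < ".join(report.orderings[comp.metric])
        print(f"{comp.metric}: F={comp.F_statistic:.2f}, p={comp.p_value:.2g}; "
              f"ascending means: {order}")
    print(f"\nwrote {results / 'group_comparisons.csv'} and trend_report.md")


if __name__ == "__main__":
    main()
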