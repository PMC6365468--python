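#!/usr/bin/env python
"""Quantify every simulated sample.

Runs the imaging pipeline (vesselness → segmentation → cavity →
skeleton → graph → morphometry) on each volume written by
01_simulate_cohort.py and collects the per-sample morphometry table in
results/morphometry.csv.  Stage intermediates land next to each volume
under scratch/cohort/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from angiotomo import read_volume
from angiotomo.pipeline import PipelineConfig, run_sample

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cohort = ROOT / "scratch" / "cohort"
    if not cohort.exists():
        raise SystemExit("no simulated cohort found — run 01_simulate_cohort.py first")
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    cfg = PipelineConfig(seed=args.seed)
    rows = []
    for d in sorted(cohort.iterdir()):
        if not (d / "volume.tif").exists():
            continue
        meta = json.loads((d / "truth.json").read_text())
        vol = read_volume(d / "volume.tif")
        morpho, _ = run_sample(cfg, vol, sample_id=d.name,
                               condition=meta["condition"], out_dir=cohort)
        rows.append(morpho.as_dict())
        print(f"{d.name}: {morpho.n_branches} branches "
              f"(truth {meta['n_branches']}), cavity {morpho.cavity_volume_um3:.3g} μm³")
    frame = pd.DataFrame(rows)
    frame.to_csv(results / "morphometry.csv", index=False)
    print(f"\nwrote {results / 'morphometry.csv'} ({len(frame)} samples)")


if __name__ == "__main__":
    main()
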