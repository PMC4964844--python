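#!/usr/bin/env python
"""Generate the synthetic experiment: growth curves and cytometry events.

Writes the two data streams the downstream analyses consume — daily
OD650 growth curves for 4 treatments x 6 replicates over 4 days, and
per-event forward/side-scatter tables — together with their truth
sidecars, under the output directory.
"""

import argparse
from pathlib import Path

from terminvest import io as tio
from terminvest.synthetic_data import (
    ExperimentDesign,
    default_cytometry_truth,
    generate_cytometry_dataset,
    generate_growth_dataset,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    ap.add_argument("--events", type=int, default=20_000, help="cytometry events per sample")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    design = ExperimentDesign()
    curves, truth = generate_growth_dataset(design, seed=args.seed)
    growth_path = tio.write_growth_csv(curves, args.out / "growth_curves.csv")
    truth.to_csv(tio.truth_sidecar_path(growth_path), index=False)
    print(f"growth: {curves['well'].nunique()} wells x {design.reads_per_day} reads -> {growth_path}")

    cyto_truth = default_cytometry_truth(design, events=args.events)
    events = generate_cytometry_dataset(cyto_truth, seed=args.seed + 1)
    cyto_path = tio.write_cytometry_csv(events, args.out / "cytometry_events.csv")
    print(f"cytometry: {len(events)} events over {events.groupby(['day','treatment']).ngroups} samples -> {cyto_path}")


if __name__ == "__main__":
    main()
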