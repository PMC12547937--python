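#!/usr/bin/env python
"""Generate the synthetic study cohorts every downstream analysis consumes.

Writes, under --out (default results/data/):
  imaging_cohort.csv + .epochs.yaml  - 60 cells, 0.5 Hz ratio traces with a
      1.3x test stimulus carried by 50% of cells and a 1.5x positive control
  imaging_truth.csv                  - per cell x epoch ground truth
  capacitance ground truth           - 8 cells under the 6x10 ms + 4x100 ms
      train (5 fF noise), pool truth in capacitance_truth.csv
  secretion plates                   - 3 plates, true fold 2.0, cv 0.3
Capacitance/voltage traces are regenerated on demand by 03 from the recorded
seeds (they are large relative to their information content).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from ecphys.sim import (
    ImagingEpochSpec,
    ImagingSimConfig,
    PoolSimConfig,
    SecretionSimConfig,
    simulate_capacitance,
    simulate_imaging_cohort,
    simulate_secretion_plate,
)
from ecphys.traces import write_traces


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    imaging_cfg = ImagingSimConfig(
        n_cells=60,
        baseline_dur=120.0,
        noise_sd=0.03,
        responder_fraction=0.5,
        epochs=[ImagingEpochSpec(label="stimulus", duration=60.0, amplitude=1.3)],
        seed=args.seed,
    )
    traces, schedule, truth = simulate_imaging_cohort(imaging_cfg)
    write_traces(out / "imaging_cohort.csv", traces, schedule)
    truth.to_csv(out / "imaging_truth.csv", index=False)
    n_true = int(truth.loc[truth["epoch"] == "stimulus", "true_responder"].sum())
    print(f"imaging: {len(traces)} cells, {n_true} true responders")

    pool_rows = []
    for k in range(8):
        cfg = PoolSimConfig(noise_sd=5.0, seed=args.seed * 1000 + k)
        _, truth_k = simulate_capacitance(cfg)
        pool_rows.append(
            {"cell_id": f"ec{k}", "seed": cfg.seed,
             "released_after_shorts_ff": truth_k["released_after_shorts"],
             "released_after_train_ff": truth_k["released_after_train"],
             "cm0_pf": truth_k["cm0"]}
        )
    pd.DataFrame(pool_rows).to_csv(out / "capacitance_truth.csv", index=False)
    print(f"capacitance: {len(pool_rows)} cells (traces regenerated by seed in 03)")

    plates = []
    for p in range(3):
        cfg = SecretionSimConfig(
            n_basal_wells=9, n_treatment_wells=9, true_fold=2.0, cv=0.3,
            plate_id=f"plate{p + 1}", seed=args.seed * 100 + p,
        )
        tbl, _ = simulate_secretion_plate(cfg)
        plates.append(tbl)
    pd.concat(plates, ignore_index=True).to_csv(out / "secretion_plates.csv", index=False)
    print("secretion: 3 plates, 9+9 wells each, true fold 2.0")

    (out / "sim_manifest.json").write_text(
        json.dumps({"seed": args.seed, "imaging": imaging_cfg.model_dump()}, indent=2,
                   default=str) + "\n"
    )


if __name__ == "__main__":
    main()
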