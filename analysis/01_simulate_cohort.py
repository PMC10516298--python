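#!/usr/bin/env python
"""Simulate the synthetic study cohort (n = 60).

Draws a latent disease severity per participant, maps it to clinical
scores (EDSS quantized to half steps, SDMT/RAVLT/BVMT-R, T25FW, 9HPT)
and to the planted oculomotor generative parameters, and writes

* results/cohort.csv        -- the clinical table
* results/planted_truth.csv -- the per-participant generative values

Gaze traces themselves are regenerated deterministically from the same
seed by the extraction step, so they are not persisted here.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from oculomet.synth import SyntheticCohortConfig, simulate_cohort

SEED = 60
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SyntheticCohortConfig(n_participants=60, seed=SEED,
                                simulate_gaze=False)
    cohort = simulate_cohort(cfg)
    cohort.clinical.to_csv(OUT / "cohort.csv", index=False)
    truth = pd.DataFrame({pid: dataclasses.asdict(t)
                          for pid, t in cohort.truths.items()}).T
    truth = truth.drop(columns=["blink_dur_range_s"])
    truth.index.name = "participant_id"
    truth.to_csv(OUT / "planted_truth.csv")

    clin = cohort.clinical
    print(f"simulated cohort of {len(clin)} participants (seed {SEED})")
    print(f"  EDSS {clin.edss.min():.1f}-{clin.edss.max():.1f} "
          f"(median {clin.edss.median():.1f}); "
          f"{(clin.edss >= 4.5).sum()} in the high-EDSS subgroup")
    print(f"  SDMT mean {clin.sdmt.mean():.1f} (SD {clin.sdmt.std():.1f}); "
          f"T25FW median {clin.t25fw.median():.1f} s")
    print(f"wrote {OUT / 'cohort.csv'} and {OUT / 'planted_truth.csv'}")


if __name__ == "__main__":
    main()
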