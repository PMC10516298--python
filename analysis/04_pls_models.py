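#!/usr/bin/env python
"""PLS estimation of clinical scales from oculomotor parameters.

For each outcome (EDSS, SDMT, BICAMS, MSFC): subset search over the
profile columns with age always included, complete cases scoped per
subset, latent-variable count chosen by 5-fold CV, scored by R^2.
The search is capped at subsets of 8 parameters (flagged in the model
reports).  Writes

* results/model_<outcome>.json   -- features, coefficients, R^2
* results/predictions_<outcome>.csv
* results/contributions.csv      -- normalized |standardized beta|
"""

import json
import warnings
from pathlib import Path

import pandas as pd

from oculomet.clinical import compute_composites
from oculomet.pipeline import model_outcomes
from oculomet.pls import SearchSettings

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    profiles = pd.read_csv(OUT / "profiles.csv", index_col="participant_id")
    clinical = compute_composites(pd.read_csv(OUT / "cohort.csv"))
    settings = SearchSettings(mode="greedy", max_size=8, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models = model_outcomes(profiles, clinical, settings=settings)

    contrib = pd.DataFrame({o: pd.Series(m.contributions)
                            for o, m in models.items()})
    contrib.to_csv(OUT / "contributions.csv", index_label="parameter")
    print("PLS models (greedy search, <= 8 parameters + age):")
    for outcome, m in models.items():
        (OUT / f"model_{outcome}.json").write_text(
            json.dumps(m.to_report(), indent=2))
        m.predictions.to_csv(OUT / f"predictions_{outcome}.csv",
                             index_label="participant_id")
        top = max(m.contributions, key=m.contributions.get)
        print(f"  {outcome:7s} R2={m.r2:.2f} adjR2={m.adj_r2:.2f} "
              f"cvR2={m.cv_r2:.2f} n={m.n_used} "
              f"components={m.n_components} "
              f"features={len(m.features)} top={top}")
    print(f"wrote model reports, predictions and "
          f"{OUT / 'contributions.csv'}")


if __name__ == "__main__":
    main()
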