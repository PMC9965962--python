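#!/usr/bin/env python
"""Develop the PAEE prediction equation on the validation group.

Merges covariates, DLW PAEE and CPM; applies the +-3 SD outlier screen;
assigns every third participant (within sex, by ascending age) to the
cross-validation group; runs stepwise regression on the validation
group; fits sex-specific variants; and selects the preliminary
equation on goodness of fit.  Writes the analysis dataset with group
labels and a Table-2-style equation summary.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS

from paee import equations, validation
from paee.data_io import read_cohort, write_results
from paee.pipeline import build_dataset
from paee.synthetic import SCREEN_COLUMNS


def main() -> None:
    cohort = read_cohort(RESULTS / "cohort.csv")
    energy = pd.read_csv(RESULTS / "energy.csv", dtype={"participant_id": str})
    cpm = pd.read_csv(RESULTS / "cpm.csv", dtype={"participant_id": str})
    dataset = build_dataset(cohort, energy, cpm[cpm.protocol_valid])

    kept, removed = validation.filter_outliers(dataset, columns=SCREEN_COLUMNS)
    print(f"outlier screen removed {len(removed)}: "
          f"{sorted(removed.participant_id)}")
    print(f"analysis sample n={len(kept)}")

    split = validation.split_every_third(kept)
    merged = kept.merge(split, on="participant_id")
    merged.to_csv(RESULTS / "analysis_groups.csv", index=False, float_format="%.8g")
    val_group = merged[merged.group == "validation"]
    print(f"validation n={len(val_group)}, "
          f"cross-validation n={len(merged) - len(val_group)}")

    pooled = equations.stepwise_select(val_group)
    per_sex = equations.fit_sex_specific(val_group, [p for p in pooled.predictors
                                                     if p != "sex_code"])
    selection = equations.select_best(pooled, per_sex["male"], per_sex["female"])
    write_results(selection, RESULTS / "equation_selection.json")

    table = pd.DataFrame(
        [
            {
                "equation": eq.sex_scope,
                "predictors": "+".join(eq.predictors),
                "intercept": eq.coefficients["intercept"],
                **{k: v for k, v in eq.coefficients.items() if k != "intercept"},
                "R": eq.r,
                "R2_pct": eq.r2_pct,
                "RMSE": eq.rmse,
                "n": eq.n,
            }
            for eq in (pooled, per_sex["male"], per_sex["female"])
        ]
    )
    table.to_csv(RESULTS / "equation_table.csv", index=False, float_format="%.6g")
    print(table.to_string(index=False))
    print(f"selected: {selection.chosen} ({selection.rationale})")


if __name__ == "__main__":
    main()
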