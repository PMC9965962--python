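#!/usr/bin/env python
"""Validate the preliminary equation and build the final one.

Cross-validates the preliminary (pooled) equation on the held-out
group — paired t-test, correlation, pure error versus development RMSE,
Bland-Altman agreement — then refits on the combined sample, validates
the final equation with PRESS, and writes the Bland-Altman pairs of the
final fit for plotting.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import RESULTS

from paee import equations, validation
from paee.data_io import write_results


def main() -> None:
    merged = pd.read_csv(RESULTS / "analysis_groups.csv",
                         dtype={"participant_id": str})
    with open(RESULTS / "equation_selection.json", encoding="utf-8") as handle:
        selection = json.load(handle)
    prelim_raw = selection["pooled"]
    preliminary = equations.FittedEquation(
        predictors=prelim_raw["predictors"],
        coefficients=prelim_raw["coefficients"],
        r=prelim_raw["r"], r2_pct=prelim_raw["r2_pct"],
        rmse=prelim_raw["rmse"], n=prelim_raw["n"],
    )

    cv_group = merged[merged.group == "cross_validation"]
    report = validation.validate_equation(preliminary, cv_group)
    write_results(report, RESULTS / "cross_validation.json")
    print(
        f"cross-validation (n={report.n}): criterion "
        f"{report.mean_criterion:.2f} +- {report.sd_criterion:.2f} vs predicted "
        f"{report.mean_predicted:.2f} +- {report.sd_predicted:.2f} kcal/min "
        f"(paired t p={report.p_value:.2f}); R={report.correlation_r:.2f}"
    )
    print(
        f"pure error {report.pure_error:.3f} vs development RMSE "
        f"{report.rmse_validation:.3f} kcal/min"
    )

    final = equations.fit_ols(merged, preliminary.predictors)
    press = validation.press_statistics(merged, final.predictors)
    predicted = equations.predict(final, merged)
    bias, sd_diff, (lo, hi), pairs = validation.bland_altman(
        merged["paee"].to_numpy(), predicted
    )
    pairs.to_csv(RESULTS / "bland_altman_pairs.csv", index=False,
                 float_format="%.6g")
    write_results(
        {"final": final, "press": press,
         "bland_altman": {"bias": bias, "sd_diff": sd_diff,
                          "loa_lower": lo, "loa_upper": hi}},
        RESULTS / "final_equation.json",
    )
    slope = final.coefficients.get("cpm", float("nan"))
    print(
        f"final equation (n={final.n}): PAEE = {slope:.6f}*CPM "
        f"{final.coefficients['intercept']:+.4f}  "
        f"(R2 {final.r2_pct:.1f}%, PRESS R2 {press.press_r2_pct:.1f}%, "
        f"PRESS RMSE {press.press_rmse:.3f} kcal/min)"
    )
    print(
        f"Bland-Altman: bias {bias:.3f} +- {sd_diff:.3f} kcal/min, "
        f"limits of agreement [{lo:.3f}, {hi:.3f}]"
    )


if __name__ == "__main__":
    main()
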