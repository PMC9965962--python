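"""End-to-end study replication.

Stages, in the study's order: generate (or load) the cohort -> DLW
energy chain with protocol exclusions -> accelerometry with wear-time
exclusions -> merged analysis dataset -> +-3 SD outlier screen ->
every-third split -> stepwise equation development on the validation
group -> pooled-versus-sex-specific selection -> cross-validation
report -> final combined-group fit with PRESS and Bland-Altman.

Every stage is callable on its own; :func:`run_study` composes them
under one seeded configuration and writes all intermediate artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import accelerometry, equations, synthetic, validation
from .data_io import write_results
from .dlw_energy import EnergyResult, analyze_cohort
from .equations import FittedEquation
from .synthetic import SimulationConfig
from .validation import PressResult, ValidationReport

log = logging.getLogger(__name__)

__all__ = ["StudyReport", "run_study", "summarize_groups", "build_dataset"]

DATASET_COLUMNS = [
    "participant_id", "sex_code", "age", "weight", "height",
    "bmi", "ffm", "fm", "cpm", "paee",
]


@dataclass
class StudyReport:
    """Everything the replication reports, in one serializable object."""

    n_enrolled: int
    exclusions: dict[str, int]
    exclusion_detail: list[tuple[str, str]]
    n_analyzed: int
    split_sizes: dict[str, int]
    group_summary: pd.DataFrame
    pooled: FittedEquation
    male: FittedEquation | None
    female: FittedEquation | None
    selection_rationale: str
    selected_scope: str
    cross_validation: ValidationReport
    final: FittedEquation
    press: PressResult
    final_bias: float
    final_sd_diff: float
    final_loa_lower: float
    final_loa_upper: float
    config: dict = field(default_factory=dict)


def energy_table(results: list[EnergyResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def build_dataset(
    cohort: pd.DataFrame, energy: pd.DataFrame, cpm: pd.DataFrame
) -> pd.DataFrame:
    """Merge covariates, DLW results and CPM into the model dataset.

    BMI is recomputed from weight and height rather than trusted from
    any input.
    """
    merged = cohort.merge(
        energy[["participant_id", "ffm_kg", "fm_kg", "paee_kcal_min"]],
        on="participant_id",
    ).merge(cpm[["participant_id", "cpm"]], on="participant_id")
    merged["bmi"] = merged["weight"] / merged["height"] ** 2
    merged = merged.rename(
        columns={"ffm_kg": "ffm", "fm_kg": "fm", "paee_kcal_min": "paee"}
    )
    return merged[DATASET_COLUMNS]


def summarize_groups(
    dataset: pd.DataFrame, split: pd.DataFrame, energy: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean +- SD of each characteristic per group and sex.

    Mirrors the usual cohort-description table: one row per
    (group, sex), characteristics as mean and SD columns.
    """
    frame = dataset.merge(split, on="participant_id")
    if energy is not None:
        frame = frame.merge(
            energy[["participant_id", "tee_kcal_day"]], on="participant_id"
        )
        frame["tee_kcal_min"] = frame["tee_kcal_day"] / 1440.0
        frame = frame.drop(columns=["tee_kcal_day"])
    stats = []
    value_cols = [
        c for c in frame.columns
        if c not in ("participant_id", "sex_code", "group")
    ]
    for (group, sex), sub in frame.groupby(["group", "sex_code"]):
        if len(sub) == 0:
            log.warning("empty summary cell (%s, sex=%s)", group, sex)
            continue
        row: dict = {"group": group, "sex_code": sex, "n": len(sub)}
        for col in value_cols:
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1))
        stats.append(row)
    return pd.DataFrame(stats)


def run_study(
    config: SimulationConfig,
    out_dir=None,
    candidates: list[str] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> StudyReport:
    """Run the full replication on a synthetic cohort.

    Epoch streams are generated lazily and processed in memory, one
    participant at a time; only derived tables are written when
    ``out_dir`` is given.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cohort, truth = synthetic.generate_participants(config)
    n_enrolled = len(cohort)
    log.info("enrolled %d participants", n_enrolled)
    exclusion_detail: list[tuple[str, str]] = []

    # --- DLW chain (flags incomplete and below-baseline participants)
    records = synthetic.iter_isotope_records(config, truth)
    energy_results, dlw_exclusions = analyze_cohort(
        records, cohort, config.constants, config.schofield, config.hydration
    )
    exclusion_detail.extend(dlw_exclusions)
    energy = energy_table(energy_results)
    n_incomplete = sum(
        1 for _, r in dlw_exclusions if "incomplete" in r
    )
    n_enrichment = sum(
        1 for _, r in dlw_exclusions if "below baseline" in r
    )
    log.info(
        "DLW analysed %d, excluded %d", len(energy), len(dlw_exclusions)
    )

    # --- accelerometry (wear-protocol exclusions)
    cpm_rows = []
    dlw_ok = set(energy["participant_id"]) if len(energy) else set()
    for pid, stream, _ in synthetic.iter_epoch_streams(config, truth):
        result, _daily = accelerometry.process_stream(stream, participant_id=pid)
        cpm_rows.append(dataclasses.asdict(result))
    cpm = pd.DataFrame(cpm_rows)
    protocol_fail = set(cpm.loc[~cpm["protocol_valid"], "participant_id"])
    n_weartime = len(protocol_fail & dlw_ok)
    for pid in sorted(protocol_fail & dlw_ok):
        exclusion_detail.append((pid, "accelerometer wear protocol not met"))
    cpm_valid = cpm[cpm["protocol_valid"]]

    # --- merged dataset and outlier screen
    dataset = build_dataset(cohort, energy, cpm_valid)
    kept, removed = validation.filter_outliers(
        dataset, columns=synthetic.SCREEN_COLUMNS
    )
    for pid in removed["participant_id"]:
        exclusion_detail.append((pid, "outlier beyond 3 SD"))
    n_outliers = len(removed)
    n_analyzed = len(kept)
    log.info("analysis sample n=%d after %d outliers", n_analyzed, n_outliers)

    # --- split and equation development on the validation group
    split = validation.split_every_third(kept)
    merged = kept.merge(split, on="participant_id")
    val_group = merged[merged["group"] == "validation"]
    cv_group = merged[merged["group"] == "cross_validation"]

    pooled = equations.stepwise_select(
        val_group, candidates, alpha_enter, alpha_remove
    )
    male = female = None
    if pooled.predictors:
        sex_predictors = [p for p in pooled.predictors if p != "sex_code"]
        if sex_predictors:
            try:
                per_sex = equations.fit_sex_specific(val_group, sex_predictors)
                male, female = per_sex["male"], per_sex["female"]
            except ValueError:
                log.warning("sex-specific fits skipped (subset too small)")
    selection = equations.select_best(pooled, male, female)

    # --- cross-validation of the preliminary equation
    report_cv = validation.validate_equation(pooled, cv_group)

    # --- final combined fit, PRESS, Bland-Altman
    final = equations.fit_ols(
        merged, pooled.predictors or ["cpm"], sex_scope="pooled"
    )
    press = validation.press_statistics(merged, final.predictors)
    predicted_final = equations.predict(final, merged)
    bias, sd_diff, (loa_lo, loa_hi), pairs = validation.bland_altman(
        merged["paee"].to_numpy(), predicted_final
    )

    summary = summarize_groups(merged.drop(columns=["group"]), split, energy)

    exclusions = {
        "incomplete_collection": n_incomplete,
        "enrichment_below_baseline": n_enrichment,
        "wear_protocol": n_weartime,
        "outliers": n_outliers,
    }
    assert n_analyzed + sum(exclusions.values()) == n_enrolled, (
        "exclusion ledger does not conserve participants"
    )

    report = StudyReport(
        n_enrolled=n_enrolled,
        exclusions=exclusions,
        exclusion_detail=exclusion_detail,
        n_analyzed=n_analyzed,
        split_sizes={
            "validation": int(len(val_group)),
            "cross_validation": int(len(cv_group)),
        },
        group_summary=summary,
        pooled=pooled,
        male=male,
        female=female,
        selection_rationale=selection.rationale,
        selected_scope=selection.chosen,
        cross_validation=report_cv,
        final=final,
        press=press,
        final_bias=bias,
        final_sd_diff=sd_diff,
        final_loa_lower=loa_lo,
        final_loa_upper=loa_hi,
        config=_config_dict(config),
    )

    if out is not None:
        cohort.to_csv(out / "cohort.csv", index=False)
        energy.to_csv(out / "energy.csv", index=False, float_format="%.8g")
        cpm.to_csv(out / "cpm.csv", index=False, float_format="%.8g")
        dataset.to_csv(out / "dataset.csv", index=False, float_format="%.8g")
        merged.to_csv(out / "analysis_groups.csv", index=False, float_format="%.8g")
        pairs.to_csv(out / "bland_altman_pairs.csv", index=False, float_format="%.8g")
        summary.to_csv(out / "group_summary.csv", index=False, float_format="%.8g")
        write_results(report, out / "study_report.json")
    return report


def _config_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["start_date"] = config.start_date.isoformat()
    return out
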