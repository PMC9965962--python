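"""Synthetic study generator with known ground truth.

Emulates a child cohort wearing triaxial accelerometers for ten days
while undergoing a two-point doubly-labelled-water protocol:

* participants: per-sex anthropometry and activity drawn around the
  published group moments; true PAEE follows the published prediction
  equation in CPM plus Gaussian residual noise; true TEE is constructed
  by inverting the ``PAEE = (0.9 TEE - BMR)/1440`` identity with the
  Schofield BMR, so the regression ground truth is exact.
* isotope records: the DLW chain run forwards — dilution spaces from
  true TBW at a fixed ND/NO ratio, ``kO`` chosen so the Schoeller and
  Weir equations reproduce true TEE exactly, enrichments decaying
  exponentially above fixed baselines, and multiplicative measurement
  noise on the post-dose excesses at the stated IRMS precisions.
* epoch streams: 15-s triaxial counts with overnight and daytime
  non-wear bouts; wear-minute totals are lognormal, split across axes
  and rescaled so that the per-minute vector-magnitude mean over wear
  time equals the participant's true CPM.

The generator can also plant protocol failures (incomplete collection,
post-dose enrichment below baseline, insufficient wear time) and
outlying measurement rows, so the pipeline's exclusion ledger can be
exercised end to end.  Clean participants are drawn inside the +-3 SD
outlier screen (covariates truncated at ``truncation_z`` population SDs
and certified against the actual screen), so the screen removes exactly
the planted aberrant rows; the small resulting shrinkage of realized
SDs is deliberate and documented.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .accelerometry import EpochStream
from .dlw_energy import (
    DlwConstants,
    HydrationTable,
    IsotopeRecord,
    IsotopeSample,
    SchofieldTable,
    bmr_schofield,
)

__all__ = [
    "Moments",
    "SexProfile",
    "PlantedOutlier",
    "SimulationConfig",
    "GenerationError",
    "enrolled_study_config",
    "generate_participants",
    "generate_isotope_record",
    "generate_epoch_stream",
    "generate_study",
    "participant_ids",
]

MINUTES_PER_DAY = 1440
PAEE_FLOOR = 0.005  # kcal/min; truncation floor for true PAEE

# screen columns of the analysis dataset, in filter order
SCREEN_COLUMNS = [
    "age", "weight", "height", "bmi", "ffm", "fm", "cpm", "paee",
]


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Moments:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class SexProfile:
    """Generative moments for one sex."""

    age: Moments
    weight: Moments
    height: Moments
    body_fat_fraction: Moments
    cpm: Moments
    paee_resid_sd: float
    age_bounds: tuple[float, float] = (11.0, 13.75)
    body_fat_bounds: tuple[float, float] = (0.05, 0.45)


# Defaults follow the validation-group moments (larger subsample); the
# residual SDs are the published per-sex preliminary-equation RMSEs.
BOYS_DEFAULT = SexProfile(
    age=Moments(12.0, 0.8),
    weight=Moments(34.2, 7.5),
    height=Moments(1.4, 0.1),
    body_fat_fraction=Moments(0.266, 0.10),
    cpm=Moments(403.5, 181.7),
    paee_resid_sd=0.139,
)
GIRLS_DEFAULT = SexProfile(
    age=Moments(12.0, 0.8),
    weight=Moments(36.8, 9.2),
    height=Moments(1.5, 0.1),
    body_fat_fraction=Moments(0.321, 0.10),
    cpm=Moments(388.9, 163.6),
    paee_resid_sd=0.122,
)


@dataclass(frozen=True)
class PlantedOutlier:
    participant_id: str
    column: str  # one of weight, height, cpm, paee
    z: float


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generator needs; one seed governs all stages."""

    seed: int = 0
    n_boys: int = 41
    n_girls: int = 38
    boys: SexProfile = BOYS_DEFAULT
    girls: SexProfile = GIRLS_DEFAULT
    # true PAEE prediction equation (kcal/min per CPM unit; kcal/min)
    true_slope: float = 0.001
    true_intercept: float = -0.112
    truncate_paee_at_zero: bool = True
    truncation_z: float = 2.5
    # DLW forward model
    constants: DlwConstants = DlwConstants()
    schofield: SchofieldTable = SchofieldTable()
    hydration: HydrationTable = HydrationTable()
    dose_2h_per_kg_bw: float = 0.12
    dose_18o_per_kg_bw: float = 1.8
    assumed_tbw_fraction: float = 0.6
    cv_2h: float = 0.010
    cv_18o: float = 0.0008
    baseline_2h_ppm: float = 155.76
    baseline_18o_ppm: float = 2005.2
    base_kd_per_day: float = 0.10
    dilution_space_ratio: float = 1.034
    post_dose_sample_h: float = 4.0
    # accelerometry forward model
    study_days: int = 10
    epoch_s: int = 15
    start_date: dt.date = dt.date(2017, 6, 5)  # a Monday
    sleep_morning_min: int = 360  # midnight to 06:00
    sleep_evening_start_min: int = 1320  # 22:00
    day_bout_min: tuple[int, int] = (60, 120)
    day_bout_window_min: tuple[int, int] = (480, 1200)
    minute_lognormal_sigma: float = 0.7
    axis_mix: tuple[float, float, float] = (0.62, 0.55, 0.56)
    # planted protocol failures / aberrant rows
    plant_incomplete: tuple[str, ...] = ()
    plant_enrichment_fail: tuple[str, ...] = ()
    plant_weartime_fail: tuple[str, ...] = ()
    plant_outliers: tuple[PlantedOutlier, ...] = ()

    def __post_init__(self) -> None:
        if self.n_boys < 0 or self.n_girls < 0:
            raise ValueError("negative group size")
        if not 0 < self.assumed_tbw_fraction < 1:
            raise ValueError("assumed_tbw_fraction outside (0, 1)")
        if not math.isfinite(self.true_slope):
            raise ValueError("true_slope must be finite")
        if self.cv_2h < 0 or self.cv_18o < 0:
            raise ValueError("negative measurement CV")
        if self.study_days < 1:
            raise ValueError("study_days must be at least 1")

    def profile(self, sex_code: int) -> SexProfile:
        return self.boys if sex_code == 1 else self.girls


def enrolled_study_config(seed: int = 0) -> SimulationConfig:
    """The full enrolled cohort: 96 children with planted exclusions.

    49 boys and 47 girls are enrolled; one incomplete urine collection,
    four enrichment-below-baseline participants, four wear-protocol
    failures and eight outlying rows are planted so that 79 adolescents
    (41 boys, 38 girls) survive to analysis.
    """
    return SimulationConfig(
        seed=seed,
        n_boys=49,
        n_girls=47,
        plant_incomplete=("B005",),
        plant_enrichment_fail=("B011", "B017", "G008", "G014"),
        plant_weartime_fail=("B023", "B029", "G020", "G026"),
        plant_outliers=(
            PlantedOutlier("B035", "weight", 8.0),
            PlantedOutlier("B041", "height", -8.0),
            PlantedOutlier("B047", "cpm", 7.0),
            PlantedOutlier("G032", "weight", 7.0),
            PlantedOutlier("G038", "height", 8.0),
            PlantedOutlier("G044", "cpm", 8.0),
            PlantedOutlier("G005", "paee", 8.0),
            PlantedOutlier("G011", "paee", 7.0),
        ),
    )


def participant_ids(config: SimulationConfig) -> list[tuple[str, int]]:
    """Stable (participant_id, sex_code) enumeration: boys, then girls."""
    ids = [(f"B{i + 1:03d}", 1) for i in range(config.n_boys)]
    ids += [(f"G{i + 1:03d}", 0) for i in range(config.n_girls)]
    return ids


def _rng(seed: int, index: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, index, purpose)))


def _truncated_sd_factor(zmax: float) -> float:
    """SD of a standard normal truncated to [-zmax, zmax].

    ``sqrt(1 - 2*z*phi(z) / (2*Phi(z) - 1))`` — the factor by which
    symmetric truncation shrinks the realized SD below the configured
    one (means are unaffected).
    """
    phi = math.exp(-0.5 * zmax * zmax) / math.sqrt(2.0 * math.pi)
    mass = math.erf(zmax / math.sqrt(2.0))
    return math.sqrt(1.0 - 2.0 * zmax * phi / mass)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, zmax: float
) -> float:
    if sd == 0:
        return mean
    while True:
        z = rng.standard_normal()
        if abs(z) <= zmax:
            return mean + sd * z


def _bounded_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0:
        return min(max(mean, lo), hi)
    while True:
        x = mean + sd * rng.standard_normal()
        if lo <= x <= hi:
            return x


@lru_cache(maxsize=32)
def _derived_moments(
    profile: SexProfile, slope: float, intercept: float, truncation_z: float
) -> dict[str, Moments]:
    """Population moments of derived columns, by deterministic Monte Carlo.

    Used only to guard clean draws away from the outlier screen; 20,000
    draws with a fixed internal seed keep the guard reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence((424242,)))
    n = 20_000

    def draw_trunc(m: Moments, zmax: float) -> np.ndarray:
        z = rng.standard_normal(n)
        for _ in range(64):
            bad = np.abs(z) > zmax
            if not bad.any():
                break
            z[bad] = rng.standard_normal(int(bad.sum()))
        return m.mean + m.sd * z

    weight = draw_trunc(profile.weight, truncation_z)
    height = draw_trunc(profile.height, truncation_z)
    lo, hi = profile.body_fat_bounds
    bf = np.clip(draw_trunc(profile.body_fat_fraction, truncation_z), lo, hi)
    cpm_z = min(
        truncation_z,
        profile.cpm.mean / profile.cpm.sd if profile.cpm.sd else truncation_z,
    )
    cpm = draw_trunc(profile.cpm, cpm_z)
    resid = draw_trunc(Moments(0.0, profile.paee_resid_sd), truncation_z)
    paee = slope * cpm + intercept + resid
    out = {}
    for name, values in {
        "bmi": weight / height**2,
        "ffm": weight * (1.0 - bf),
        "fm": weight * bf,
        "paee": paee,
    }.items():
        out[name] = Moments(float(values.mean()), float(values.std(ddof=1)))
    return out


def _draw_participant(
    config: SimulationConfig, sex_code: int, rng: np.random.Generator
) -> dict[str, float]:
    """One clean participant from the truncated per-sex distributions.

    Covariate draws are symmetric truncated normals, so group means are
    unbiased; derived columns (BMI, FM, ...) are not guarded here — the
    screen-level certification in :func:`generate_participants` redraws
    the rare rows the +-3 SD screen would flag, which keeps the
    generative distribution essentially untouched.
    """
    profile = config.profile(sex_code)
    tz = config.truncation_z
    age = _bounded_normal(
        rng, profile.age.mean, profile.age.sd, *profile.age_bounds
    )
    weight = _truncated_normal(rng, profile.weight.mean, profile.weight.sd, tz)
    height = _truncated_normal(rng, profile.height.mean, profile.height.sd, tz)
    bf = _bounded_normal(
        rng,
        profile.body_fat_fraction.mean,
        profile.body_fat_fraction.sd,
        *profile.body_fat_bounds,
    )
    cpm_z = min(tz, profile.cpm.mean / profile.cpm.sd if profile.cpm.sd else tz)
    cpm = _truncated_normal(rng, profile.cpm.mean, profile.cpm.sd, cpm_z)
    mean_paee = config.true_slope * cpm + config.true_intercept
    if profile.paee_resid_sd == 0:
        paee = mean_paee
    else:
        for _ in range(1000):
            resid = _truncated_normal(rng, 0.0, profile.paee_resid_sd, tz)
            paee = mean_paee + resid
            if not config.truncate_paee_at_zero or paee > PAEE_FLOOR:
                break
        else:  # pragma: no cover
            raise GenerationError("cannot satisfy PAEE floor")
    return {
        "age": age,
        "weight": weight,
        "height": height,
        "body_fat_fraction": bf,
        "cpm": cpm,
        "paee": paee,
    }


def _finalize_truth(row: dict, sex_code: int, config: SimulationConfig) -> dict:
    """Fill derived ground-truth fields from the drawn/planted values."""
    row = dict(row)
    row["sex_code"] = sex_code
    row["bmi"] = row["weight"] / row["height"] ** 2
    row["ffm"] = row["weight"] * (1.0 - row["body_fat_fraction"])
    row["fm"] = row["weight"] * row["body_fat_fraction"]
    hc = config.hydration.lookup(sex_code, row["age"])
    row["tbw"] = row["ffm"] * hc
    row["bmr"] = bmr_schofield(row["weight"], sex_code, row["age"], config.schofield)
    row["tee"] = (row["paee"] * MINUTES_PER_DAY + row["bmr"]) / (
        1.0 - config.constants.tef_fraction
    )
    return row


def generate_participants(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the cohort table and its ground truth.

    Returns
    -------
    cohort, truth
        ``cohort`` carries the observable covariates (id, sex, age,
        weight, height); ``truth`` additionally holds body composition,
        TBW, CPM, PAEE, BMR, TEE and the planted-condition label.
    """
    from .validation import filter_outliers  # deferred: avoids a cycle

    ids = participant_ids(config)
    if not ids:
        empty_cohort = pd.DataFrame(
            columns=["participant_id", "sex_code", "age", "weight", "height"]
        )
        return empty_cohort, pd.DataFrame(columns=empty_cohort.columns)
    planted_outlier = {p.participant_id: p for p in config.plant_outliers}
    all_planted = (
        set(config.plant_incomplete)
        | set(config.plant_enrichment_fail)
        | set(config.plant_weartime_fail)
        | set(planted_outlier)
    )
    unknown = all_planted - {pid for pid, _ in ids}
    if unknown:
        raise GenerationError(f"planted ids not in cohort: {sorted(unknown)}")

    rngs = [_rng(config.seed, i, 0) for i in range(len(ids))]
    rows: list[dict] = []
    for i, (pid, sex_code) in enumerate(ids):
        row = _draw_participant(config, sex_code, rngs[i])
        row["participant_id"] = pid
        plant = ""
        if pid in config.plant_incomplete:
            plant = "incomplete"
        elif pid in config.plant_enrichment_fail:
            plant = "enrichment_fail"
        elif pid in config.plant_weartime_fail:
            plant = "weartime_fail"
        elif pid in planted_outlier:
            planted = planted_outlier[pid]
            plant = f"outlier:{planted.column}"
            profile = config.profile(sex_code)
            if planted.column in ("weight", "height", "cpm"):
                m: Moments = getattr(profile, planted.column)
                row[planted.column] = m.mean + planted.z * m.sd
                if planted.column == "cpm":
                    # the equation world stays consistent: PAEE follows CPM
                    row["paee"] = (
                        config.true_slope * row["cpm"] + config.true_intercept
                    )
            elif planted.column == "paee":
                pop = _derived_moments(
                    profile,
                    config.true_slope,
                    config.true_intercept,
                    config.truncation_z,
                )["paee"]
                row["paee"] = pop.mean + planted.z * pop.sd
            else:
                raise GenerationError(
                    f"unsupported outlier column {planted.column}"
                )
        row["plant"] = plant
        rows.append(_finalize_truth(row, sex_code, config))

    truth = pd.DataFrame(rows)

    # Certify against the actual outlier screen: the screen will run on
    # participants that survive the earlier exclusions, and must remove
    # exactly the planted aberrant rows.  Redraw any clean row it would
    # also catch (sampling noise in the screen's own mean/SD estimates).
    if len(truth) >= 3:
        index_of = {pid: i for i, (pid, _) in enumerate(ids)}
        for _ in range(50):
            screened = truth[
                ~truth["plant"].isin(
                    ["incomplete", "enrichment_fail", "weartime_fail"]
                )
            ]
            _, removed = filter_outliers(screened, columns=SCREEN_COLUMNS)
            flagged_clean = [
                pid
                for pid in removed["participant_id"]
                if truth.loc[truth["participant_id"] == pid, "plant"].iloc[0] == ""
            ]
            if not flagged_clean:
                break
            for pid in flagged_clean:
                i = index_of[pid]
                sex_code = ids[i][1]
                row = _draw_participant(config, sex_code, rngs[i])
                row["participant_id"] = pid
                row["plant"] = ""
                truth.iloc[i] = pd.Series(_finalize_truth(row, sex_code, config))
        else:  # pragma: no cover
            raise GenerationError("outlier-screen certification did not converge")

    cohort = truth[["participant_id", "sex_code", "age", "weight", "height"]].copy()
    return cohort, truth


def generate_isotope_record(
    truth_row, config: SimulationConfig, rng: np.random.Generator
) -> IsotopeRecord:
    """Forward-simulate one participant's isotope record.

    Inverts the analysis chain exactly: dilution spaces are placed at the
    configured ND/NO ratio around the true TBW, ``kO`` is solved so the
    Schoeller/Weir chain returns the true TEE, and the three urine
    samples are laid on the exponential washout curves.  Measurement
    noise is multiplicative on the post-dose excesses at the configured
    CVs; with the CVs at zero the analysis recovers the truth to
    round-off.
    """
    c = config.constants
    tbw_kg = float(truth_row["tbw"])
    tee = float(truth_row["tee"])
    weight = float(truth_row["weight"])
    pid = str(truth_row["participant_id"])

    tbw_mol = tbw_kg * 1000.0 / c.water_molar_mass
    ratio = config.dilution_space_ratio
    no_mol = 2.0 * tbw_mol / (ratio / c.f_d + 1.0 / c.f_o)
    nd_mol = ratio * no_mol

    rco2 = tee / (c.molar_volume_co2_l * (c.weir_a_o2 / c.food_quotient + c.weir_a_co2))
    if rco2 <= 0:
        raise GenerationError(f"{pid}: infeasible truth (non-positive rCO2)")
    kd = config.base_kd_per_day
    ko = (rco2 / (c.schoeller_factor * tbw_mol) + c.f_d * kd) / c.f_o
    if ko <= kd * c.f_d / c.f_o:  # pragma: no cover - implied by rco2 > 0
        raise GenerationError(f"{pid}: infeasible elimination rates")

    assumed_bw_kg = config.assumed_tbw_fraction * weight
    dose_2h_g = config.dose_2h_per_kg_bw * assumed_bw_kg
    dose_18o_g = config.dose_18o_per_kg_bw * assumed_bw_kg

    e0_2h = (dose_2h_g / c.molar_mass_2h2o * 0.998) / nd_mol * 1e6
    e0_18o = (dose_18o_g / c.molar_mass_h218o * 0.10) / no_mol * 1e6

    t1 = config.post_dose_sample_h
    t2 = t1 + (config.study_days - 1) * 24.0

    def excess(e0: float, k: float, t_h: float, cv: float) -> float:
        value = e0 * math.exp(-k * t_h / 24.0)
        if cv > 0:
            value *= 1.0 + cv * rng.standard_normal()
        return value

    samples = {
        "baseline": IsotopeSample(0.0, config.baseline_2h_ppm, config.baseline_18o_ppm),
        "post4h": IsotopeSample(
            t1,
            config.baseline_2h_ppm + excess(e0_2h, kd, t1, config.cv_2h),
            config.baseline_18o_ppm + excess(e0_18o, ko, t1, config.cv_18o),
        ),
        "day10": IsotopeSample(
            t2,
            config.baseline_2h_ppm + excess(e0_2h, kd, t2, config.cv_2h),
            config.baseline_18o_ppm + excess(e0_18o, ko, t2, config.cv_18o),
        ),
    }

    plant = str(truth_row.get("plant", ""))
    if plant == "enrichment_fail":
        # post-dose enrichments come back below the baseline (failed dose
        # or sample mix-up); the analysis must flag and exclude
        samples["day10"] = IsotopeSample(
            t2, config.baseline_2h_ppm - 1.0, config.baseline_18o_ppm - 1.0
        )
    if plant == "incomplete":
        samples["day10"] = None

    return IsotopeRecord(
        participant_id=pid,
        dose_2h_g=dose_2h_g,
        dose_18o_g=dose_18o_g,
        dose_enrichment_2h=0.998,
        dose_enrichment_18o=0.10,
        baseline=samples["baseline"],
        post4h=samples["post4h"],
        day10=samples["day10"],
    )


def _wear_mask(
    truth_row, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-minute wear mask: sleep overnight, one daytime non-wear bout."""
    n_min = config.study_days * MINUTES_PER_DAY
    wear = np.ones(n_min, dtype=bool)
    lo_len, hi_len = config.day_bout_min
    win_lo, win_hi = config.day_bout_window_min
    for day in range(config.study_days):
        base = day * MINUTES_PER_DAY
        wear[base : base + config.sleep_morning_min] = False
        wear[base + config.sleep_evening_start_min : base + MINUTES_PER_DAY] = False
        length = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(win_lo, win_hi - length + 1))
        wear[base + start : base + start + length] = False
    if str(truth_row.get("plant", "")) == "weartime_fail":
        wear[2 * MINUTES_PER_DAY :] = False  # device returned after two days
    return wear


def generate_epoch_stream(
    truth_row, config: SimulationConfig, rng: np.random.Generator
) -> tuple[EpochStream, np.ndarray]:
    """Forward-simulate one participant's 15-s epoch stream.

    Returns the stream and the true per-minute wear mask.  Wear-minute
    vector magnitudes are lognormal, rescaled so their mean over wear
    minutes equals the true CPM before integer rounding; non-wear
    minutes are all-zero.
    """
    wear = _wear_mask(truth_row, config, rng)
    n_min = len(wear)
    cpm = float(truth_row["cpm"])

    vm = np.zeros(n_min)
    n_wear = int(wear.sum())
    if n_wear and cpm > 0:
        sigma = config.minute_lognormal_sigma
        draws = rng.lognormal(
            mean=math.log(cpm) - 0.5 * sigma**2, sigma=sigma, size=n_wear
        )
        draws *= cpm * n_wear / draws.sum()
        vm[wear] = draws

    mix = np.asarray(config.axis_mix, dtype=float)
    mix = mix / np.linalg.norm(mix)
    minute_axis = np.rint(vm[:, None] * mix[None, :]).astype(np.int64)

    ratio = 60 // config.epoch_s
    q, r = np.divmod(minute_axis, ratio)
    epochs = np.repeat(q[:, None, :], ratio, axis=1)
    epoch_index = np.arange(ratio)[None, :, None]
    epochs += (epoch_index < r[:, None, :]).astype(np.int64)
    counts = epochs.reshape(n_min * ratio, 3)

    start = dt.datetime.combine(config.start_date, dt.time(0, 0))
    return EpochStream(start=start, epoch_s=config.epoch_s, counts=counts), wear


def iter_isotope_records(
    config: SimulationConfig, truth: pd.DataFrame
) -> dict[str, IsotopeRecord]:
    """All isotope records, keyed by participant id (deterministic)."""
    records = {}
    for i, row in enumerate(truth.to_dict(orient="records")):
        records[row["participant_id"]] = generate_isotope_record(
            row, config, _rng(config.seed, i, 1)
        )
    return records


def iter_epoch_streams(config: SimulationConfig, truth: pd.DataFrame):
    """Yield (participant_id, stream, wear_mask) one at a time.

    Streams are large (57,600 epochs per day at 15 s); generating them
    lazily keeps cohort-scale runs in constant memory.
    """
    for i, row in enumerate(truth.to_dict(orient="records")):
        stream, wear = generate_epoch_stream(row, config, _rng(config.seed, i, 2))
        yield row["participant_id"], stream, wear


def generate_study(
    config: SimulationConfig, out_dir, write_epochs: bool = True
) -> pd.DataFrame:
    """Write a complete synthetic study to disk and return its manifest.

    Writes ``cohort.csv``, ``isotopes.csv``, ``truth.csv`` (the
    ground-truth manifest) and, optionally, one epoch file per
    participant under ``epochs/``.  The manifest lists each file with
    its SHA-256, so identical seeds yield identical manifests.
    """
    from .data_io import write_cohort, write_epoch_stream, write_isotope_records

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_participants(config)
    files = []

    write_cohort(cohort, out / "cohort.csv")
    files.append(out / "cohort.csv")
    write_isotope_records(iter_isotope_records(config, truth), out / "isotopes.csv")
    files.append(out / "isotopes.csv")
    truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")
    files.append(out / "truth.csv")

    if write_epochs and len(truth):
        (out / "epochs").mkdir(exist_ok=True)
        for pid, stream, _ in iter_epoch_streams(config, truth):
            path = out / "epochs" / f"{pid}.csv"
            write_epoch_stream(stream, path, participant_id=pid)
            files.append(path)

    manifest = pd.DataFrame(
        {
            "file": [str(p.relative_to(out)) for p in files],
            "sha256": [
                hashlib.sha256(p.read_bytes()).hexdigest() for p in files
            ],
        }
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
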