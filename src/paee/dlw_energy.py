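"""Doubly labelled water (DLW) energy chain.

Implements the two-point isotope-elimination method: urine ``2H`` and
``18O`` enrichments measured 4 h and ~10 days after a weighed oral dose
give per-day elimination rates and dilution spaces, from which total body
water (TBW), fat-free mass (FFM), CO2 production (Schoeller), total energy
expenditure (modified Weir at a fixed food quotient) and finally physical
activity energy expenditure ``PAEE = (0.9*TEE - BMR)/1440`` kcal/min are
derived.  BMR is predicted from body weight with Schofield's age- and
sex-band equations.

All physical constants live in :class:`DlwConstants` so that the whole
chain can be audited or re-parameterised in one place; the synthetic
cohort generator shares the same record, which makes the forward model an
exact inverse of this analysis in the noise-free case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "DlwConstants",
    "SchofieldTable",
    "HydrationTable",
    "IsotopeSample",
    "IsotopeRecord",
    "EnergyResult",
    "FlaggedParticipant",
    "ConfigurationError",
    "elimination_rate",
    "dilution_space",
    "total_body_water",
    "body_composition",
    "co2_production",
    "tee_weir",
    "bmr_schofield",
    "paee_from_tee",
    "analyze_dlw",
    "analyze_cohort",
]

MINUTES_PER_DAY = 1440.0


class FlaggedParticipant(Exception):
    """A participant whose isotope data violate a protocol rule.

    Raised for conditions that exclude the participant from the cohort
    analysis (mirroring the study exclusions), e.g. post-dose enrichment
    at or below baseline, or an incomplete sample set.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class ConfigurationError(Exception):
    """A lookup table does not cover the requested (sex, age) cell."""


@dataclass(frozen=True)
class DlwConstants:
    """Physical constants of the DLW computation chain.

    Attributes
    ----------
    f_d, f_o
        Dilution-space correction factors for non-aqueous exchange of
        hydrogen (1.041) and oxygen (1.007).  They appear both in the
        dilution-space -> TBW conversion and in the Schoeller rate
        combination.
    schoeller_factor
        Combined factor (0.4554/day) of the Schoeller CO2-production
        equation ``rCO2 = 0.4554 * N * (f_o*kO - f_d*kD)``.
    molar_volume_co2_l
        Litres of CO2 gas per mole (22.4 L/mol at STP).
    weir_a_o2, weir_a_co2
        Caloric equivalents of the modified Weir equation
        (3.941 kcal/L O2, 1.106 kcal/L CO2).
    food_quotient
        Diet-level CO2/O2 ratio substituted for the respiratory quotient
        (default 0.86).
    tef_fraction
        Fraction of TEE attributed to the thermic effect of food; encoded
        as the ``0.9`` multiplier of TEE in the PAEE identity.
    water_molar_mass
        18.02 g/mol.
    molar_mass_2h2o, molar_mass_h218o
        Molar masses of the dose species (20.03 and 20.015 g/mol).
    nd_no_band
        Plausibility band for the dilution-space ratio ND/NO; values
        outside it raise a warning flag, never an exclusion.
    """

    f_d: float = 1.041
    f_o: float = 1.007
    schoeller_factor: float = 0.4554
    molar_volume_co2_l: float = 22.4
    weir_a_o2: float = 3.941
    weir_a_co2: float = 1.106
    food_quotient: float = 0.86
    tef_fraction: float = 0.10
    water_molar_mass: float = 18.02
    molar_mass_2h2o: float = 20.03
    molar_mass_h218o: float = 20.015
    nd_no_band: tuple[float, float] = (1.015, 1.060)

    def __post_init__(self) -> None:
        for name in (
            "f_d", "f_o", "schoeller_factor", "molar_volume_co2_l",
            "weir_a_o2", "weir_a_co2", "water_molar_mass",
            "molar_mass_2h2o", "molar_mass_h218o",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.7 < self.food_quotient < 1.0:
            raise ValueError("food_quotient outside (0.7, 1.0)")


@dataclass(frozen=True)
class SchofieldTable:
    """Weight-only Schofield BMR equations, kcal/day.

    ``bands`` rows are ``(sex_code, age_lo, age_hi, slope, intercept)``
    with ``BMR = slope * weight_kg + intercept`` and ``age_lo <= age <
    age_hi``.  Defaults are the 10-18-year weight-only coefficients
    (boys ``17.686 W + 658.2``, girls ``13.384 W + 692.6``).
    """

    bands: tuple[tuple[int, float, float, float, float], ...] = (
        (1, 10.0, 18.0, 17.686, 658.2),
        (0, 10.0, 18.0, 13.384, 692.6),
    )

    def lookup(self, sex_code: int, age: float) -> tuple[float, float]:
        for sex, lo, hi, slope, intercept in self.bands:
            if sex == sex_code and lo <= age < hi:
                return slope, intercept
        raise ConfigurationError(
            f"no Schofield band for sex_code={sex_code}, age={age}"
        )


@dataclass(frozen=True)
class HydrationTable:
    """Fraction of FFM that is water, by sex and completed year of age.

    Keys are ``(sex_code, age_years)`` with age taken as the completed
    year (``floor``).  The defaults are plausible adolescent values and
    are fully overridable; the generator and the analyser always share
    one table, so round-trip correctness does not depend on the exact
    literature values.
    """

    coefficients: tuple[tuple[int, int, float], ...] = (
        (1, 11, 0.765),
        (1, 12, 0.764),
        (1, 13, 0.762),
        (0, 11, 0.770),
        (0, 12, 0.768),
        (0, 13, 0.766),
    )

    def lookup(self, sex_code: int, age: float) -> float:
        age_year = int(math.floor(age))
        for sex, year, hc in self.coefficients:
            if sex == sex_code and year == age_year:
                if not 0.70 <= hc <= 0.80:
                    raise ConfigurationError(
                        f"hydration coefficient {hc} outside [0.70, 0.80]"
                    )
                return hc
        raise ConfigurationError(
            f"no hydration coefficient for sex_code={sex_code}, age={age}"
        )


@dataclass(frozen=True)
class IsotopeSample:
    """One urine sample: hours since dose and absolute enrichments (ppm)."""

    time_h: float
    e_2h_ppm: float
    e_18o_ppm: float


@dataclass(frozen=True)
class IsotopeRecord:
    """Doses and the three timed urine samples for one participant.

    Dose enrichments are fractional abundances of the labelled species in
    the dose water (0.998 for 99.8% 2H2O, 0.10 for 10% H2-18O).  A missing
    ``day10`` sample marks an incomplete collection and excludes the
    participant.
    """

    participant_id: str
    dose_2h_g: float
    dose_18o_g: float
    dose_enrichment_2h: float = 0.998
    dose_enrichment_18o: float = 0.10
    baseline: Optional[IsotopeSample] = None
    post4h: Optional[IsotopeSample] = None
    day10: Optional[IsotopeSample] = None


@dataclass
class EnergyResult:
    """All intermediate and final quantities of the DLW chain."""

    participant_id: str
    kd_per_day: float
    ko_per_day: float
    nd_mol: float
    no_mol: float
    tbw_kg: float
    ffm_kg: float
    fm_kg: float
    rco2_mol_day: float
    tee_kcal_day: float
    tee_kcal_min: float
    bmr_kcal_day: float
    paee_kcal_min: float
    flags: list[str] = field(default_factory=list)


def elimination_rate(
    excess_t1: float, excess_t2: float, t1_h: float, t2_h: float
) -> float:
    """Two-point log-linear isotope elimination rate, per day.

    ``k = [ln(excess_t1) - ln(excess_t2)] / ((t2 - t1)/24)`` for post-dose
    excesses (sample minus baseline, ppm) at ``t1 < t2`` hours.
    """
    if excess_t1 <= 0 or excess_t2 <= 0:
        raise FlaggedParticipant("enrichment below baseline")
    if t2_h <= t1_h:
        raise ValueError("t2_h must exceed t1_h")
    return (math.log(excess_t1) - math.log(excess_t2)) / ((t2_h - t1_h) / 24.0)


def dilution_space(
    dose_g: float,
    dose_molar_mass: float,
    dose_enrichment: float,
    excess_at_dose_time_ppm: float,
) -> float:
    """Isotope dilution space in moles of body water.

    ``N = (dose_g / M) * a / (E0 * 1e-6)`` where ``a`` is the fractional
    abundance of label in the dose and ``E0`` the back-extrapolated
    excess enrichment (ppm) at dose time.
    """
    if excess_at_dose_time_ppm <= 0:
        raise FlaggedParticipant("non-positive dose-time excess")
    if dose_g <= 0 or dose_molar_mass <= 0 or dose_enrichment <= 0:
        raise ValueError("dose inputs must be positive")
    moles_label = dose_g / dose_molar_mass * dose_enrichment
    return moles_label / (excess_at_dose_time_ppm * 1e-6)


def total_body_water(
    nd_mol: float, no_mol: float, constants: DlwConstants = DlwConstants()
) -> float:
    """Exchange-corrected total body water, kg.

    Averages the two dilution spaces after dividing out the non-aqueous
    exchange factors: ``TBW_mol = (ND/f_d + NO/f_o)/2``.
    """
    if nd_mol <= 0 or no_mol <= 0:
        raise ValueError("dilution spaces must be positive")
    tbw_mol = (nd_mol / constants.f_d + no_mol / constants.f_o) / 2.0
    return tbw_mol * constants.water_molar_mass / 1000.0


def body_composition(
    tbw_kg: float,
    weight_kg: float,
    sex_code: int,
    age: float,
    table: HydrationTable = HydrationTable(),
) -> tuple[float, float, list[str]]:
    """FFM and FM (kg) from TBW via the hydration coefficient.

    ``FFM = TBW / HC(sex, age)``; ``FM = weight - FFM``.  Implausible
    results (FFM above body weight, negative FM) are flagged, not
    clamped: downstream exclusion is the outlier filter's job.
    """
    hc = table.lookup(sex_code, age)
    ffm = tbw_kg / hc
    fm = weight_kg - ffm
    flags: list[str] = []
    if ffm > weight_kg:
        flags.append("ffm_exceeds_weight")
    if fm < 0:
        flags.append("negative_fat_mass")
    return ffm, fm, flags


def co2_production(
    tbw_mol: float,
    kd_per_day: float,
    ko_per_day: float,
    constants: DlwConstants = DlwConstants(),
) -> float:
    """Schoeller CO2 production rate, mol/day.

    ``rCO2 = 0.4554 * N * (f_o*kO - f_d*kD)`` with ``N`` the corrected
    body-water pool in moles.  A non-positive rate is returned as-is and
    flagged by the caller rather than raised.
    """
    if kd_per_day <= 0 or ko_per_day <= 0:
        raise ValueError("elimination rates must be positive")
    return constants.schoeller_factor * tbw_mol * (
        constants.f_o * ko_per_day - constants.f_d * kd_per_day
    )


def tee_weir(
    rco2_mol_day: float,
    food_quotient: Optional[float] = None,
    constants: DlwConstants = DlwConstants(),
) -> float:
    """Total energy expenditure by the modified Weir equation, kcal/day.

    ``TEE = 22.4 * rCO2 * (3.941/FQ + 1.106)``: the O2 volume is inferred
    from CO2 through the food quotient.
    """
    fq = constants.food_quotient if food_quotient is None else food_quotient
    if rco2_mol_day <= 0:
        raise ValueError("rCO2 must be positive")
    if not 0.7 < fq < 1.0:
        raise ValueError("food quotient outside (0.7, 1.0)")
    vco2_l = rco2_mol_day * constants.molar_volume_co2_l
    return vco2_l * (constants.weir_a_o2 / fq + constants.weir_a_co2)


def bmr_schofield(
    weight_kg: float,
    sex_code: int,
    age: float,
    table: SchofieldTable = SchofieldTable(),
) -> float:
    """Schofield predicted basal metabolic rate, kcal/day."""
    slope, intercept = table.lookup(sex_code, age)
    return slope * weight_kg + intercept


def paee_from_tee(
    tee_kcal_day: float,
    bmr_kcal_day: float,
    constants: DlwConstants = DlwConstants(),
) -> float:
    """Physical activity energy expenditure, kcal/min.

    ``PAEE = ((1 - TEF) * TEE - BMR) / 1440`` with TEF hard-wired as 10%
    of TEE, i.e. the 0.9 multiplier.  Negative values are returned (and
    flagged by the caller), never clamped.
    """
    if tee_kcal_day <= 0 or bmr_kcal_day <= 0:
        raise ValueError("TEE and BMR must be positive")
    awake_fraction = 1.0 - constants.tef_fraction
    return (awake_fraction * tee_kcal_day - bmr_kcal_day) / MINUTES_PER_DAY


def analyze_dlw(
    record: IsotopeRecord,
    weight_kg: float,
    sex_code: int,
    age: float,
    constants: DlwConstants = DlwConstants(),
    schofield: SchofieldTable = SchofieldTable(),
    hydration: HydrationTable = HydrationTable(),
) -> EnergyResult:
    """Run the full isotope-to-PAEE chain for one participant.

    Raises
    ------
    FlaggedParticipant
        If the sample set is incomplete or a post-dose enrichment does
        not exceed baseline (protocol exclusions).  Physiologically
        implausible but computable results are flagged on the returned
        :class:`EnergyResult` instead.
    """
    if record.baseline is None or record.post4h is None or record.day10 is None:
        raise FlaggedParticipant("incomplete sample collection")
    base, s1, s2 = record.baseline, record.post4h, record.day10
    if s2.time_h <= s1.time_h:
        raise ValueError("day10 sample must be later than the 4 h sample")

    ex1_2h = s1.e_2h_ppm - base.e_2h_ppm
    ex2_2h = s2.e_2h_ppm - base.e_2h_ppm
    ex1_18o = s1.e_18o_ppm - base.e_18o_ppm
    ex2_18o = s2.e_18o_ppm - base.e_18o_ppm
    if min(ex1_2h, ex2_2h, ex1_18o, ex2_18o) <= 0:
        raise FlaggedParticipant("enrichment below baseline")

    kd = elimination_rate(ex1_2h, ex2_2h, s1.time_h, s2.time_h)
    ko = elimination_rate(ex1_18o, ex2_18o, s1.time_h, s2.time_h)

    # back-extrapolate the 4 h excess to dose time along the fitted line
    e0_2h = ex1_2h * math.exp(kd * s1.time_h / 24.0)
    e0_18o = ex1_18o * math.exp(ko * s1.time_h / 24.0)

    nd = dilution_space(
        record.dose_2h_g, constants.molar_mass_2h2o,
        record.dose_enrichment_2h, e0_2h,
    )
    no = dilution_space(
        record.dose_18o_g, constants.molar_mass_h218o,
        record.dose_enrichment_18o, e0_18o,
    )

    flags: list[str] = []
    lo, hi = constants.nd_no_band
    if not lo <= nd / no <= hi:
        flags.append("nd_no_ratio_outside_band")

    tbw_kg = total_body_water(nd, no, constants)
    tbw_mol = tbw_kg * 1000.0 / constants.water_molar_mass
    ffm, fm, comp_flags = body_composition(
        tbw_kg, weight_kg, sex_code, age, hydration
    )
    flags.extend(comp_flags)

    rco2 = co2_production(tbw_mol, kd, ko, constants)
    if rco2 <= 0:
        flags.append("non_positive_rco2")
        tee = float("nan")
        paee = float("nan")
        bmr = bmr_schofield(weight_kg, sex_code, age, schofield)
    else:
        tee = tee_weir(rco2, constants.food_quotient, constants)
        bmr = bmr_schofield(weight_kg, sex_code, age, schofield)
        paee = paee_from_tee(tee, bmr, constants)
        if paee < 0:
            flags.append("negative_paee")

    return EnergyResult(
        participant_id=record.participant_id,
        kd_per_day=kd,
        ko_per_day=ko,
        nd_mol=nd,
        no_mol=no,
        tbw_kg=tbw_kg,
        ffm_kg=ffm,
        fm_kg=fm,
        rco2_mol_day=rco2,
        tee_kcal_day=tee,
        tee_kcal_min=tee / MINUTES_PER_DAY,
        bmr_kcal_day=bmr,
        paee_kcal_min=paee,
        flags=flags,
    )


def analyze_cohort(
    records: dict[str, IsotopeRecord],
    cohort,
    constants: DlwConstants = DlwConstants(),
    schofield: SchofieldTable = SchofieldTable(),
    hydration: HydrationTable = HydrationTable(),
) -> tuple[list[EnergyResult], list[tuple[str, str]]]:
    """Analyze every cohort row; flagged participants annotate, not abort.

    Parameters
    ----------
    records
        Mapping of participant_id to :class:`IsotopeRecord`.
    cohort
        DataFrame with columns participant_id, sex_code, age, weight,
        height (see :mod:`paee.data_io`).

    Returns
    -------
    results, exclusions
        Energy results for analysable participants and a list of
        ``(participant_id, reason)`` exclusions.
    """
    results: list[EnergyResult] = []
    exclusions: list[tuple[str, str]] = []
    for row in cohort.itertuples(index=False):
        pid = row.participant_id
        record = records.get(pid)
        if record is None:
            exclusions.append((pid, "no isotope record"))
            continue
        try:
            results.append(
                analyze_dlw(
                    record, row.weight, int(row.sex_code), row.age,
                    constants, schofield, hydration,
                )
            )
        except FlaggedParticipant as err:
            exclusions.append((pid, err.reason))
    return results, exclusions
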