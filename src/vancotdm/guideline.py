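"""Rules engine for AUC-guided vancomycin dosing.

Encodes the consensus PK/PD targets and monitoring rules as pure functions:
efficacy/safety target checks (AUC/MIC >= 400 by broth microdilution,
>= 200 by Etest, AUC <= 600 ug.h/mL for safety), AKI-risk classification
with risk-specific safe-trough cut-offs, TDM-timing recommendations, and the
plateau-concentration <-> AUC conversion for continuous infusion.

Every returned object carries the list of clinical-question rule citations
("CQ5(1)", ...) that fired, so a recommendation is auditable.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field

from .pkmodel import PatientCovariates, Regimen

__all__ = [
    "PKPDTargets",
    "TargetVerdict",
    "RiskAssessment",
    "TDMPlan",
    "target_check",
    "required_auc",
    "aki_risk",
    "tdm_timing",
    "plateau_auc",
    "auc_to_plateau",
]

#: Etest AUC/MIC thresholds reported by individual cited studies; the
#: guideline recommendation itself is 200 (see PKPDTargets).
ETEST_THRESHOLDS_REPORTED = (212, 226)

#: Literature day-2 AUC upper bound (stricter than the 600 recommendation);
#: exposed as an optional policy, default off.
DAY2_AUC_LITERATURE_UPPER = 515.0


class PKPDTargets(BaseModel):
    """Exposure targets and AKI trough cut-offs (all concentrations ug/mL,
    AUCs ug.h/mL)."""

    auc_mic_bmd_min: float = 400.0
    auc_mic_etest_min: float = 200.0
    auc_safety_max: float = 600.0
    day2_efficacy_min: float = 400.0
    day2_safety_max: float = 600.0
    plateau_band: tuple[float, float] = (20.0, 25.0)
    trough_cutoff_overall_aki: float = 19.3
    trough_cutoff_impaired_renal: float = 12.4
    trough_cutoff_pip_tazo: float = 13.5
    trough_cutoff_diuretics: float = 11.7
    #: optional stricter day-2 upper bound from the literature, disabled by
    #: default.
    day2_strict_upper: Optional[float] = None


class TargetVerdict(BaseModel):
    """Outcome of checking an AUC against the efficacy/safety targets."""

    auc: float
    mic: float
    mic_method: Literal["BMD", "Etest"]
    efficacy_met: bool
    safety_met: bool
    in_band: bool
    auc_mic: float
    auc_mic_threshold: float
    required_auc: float
    attainable_within_safety: bool
    citations: list[str]


class RiskAssessment(BaseModel):
    level: Literal["high", "standard"]
    factors: list[str]
    trough_cutoff: float = Field(description="safe-trough cut-off, ug/mL")
    citations: list[str]


class TDMPlan(BaseModel):
    day: int = Field(description="calendar day of first TDM (day 1 = first dose)")
    two_point: bool
    frequent_monitoring: bool = False
    hold_third_dose_advice: bool = False
    notes: list[str] = Field(default_factory=list)
    citations: list[str] = Field(default_factory=list)


def required_auc(
    mic: float, mic_method: Literal["BMD", "Etest"] = "BMD",
    targets: Optional[PKPDTargets] = None,
) -> float:
    """Minimum total-drug AUC (ug.h/mL) reaching the efficacy AUC/MIC ratio
    at the given MIC: 400*MIC for broth microdilution, 200*MIC for Etest."""
    targets = targets or PKPDTargets()
    ratio = (
        targets.auc_mic_bmd_min if mic_method == "BMD" else targets.auc_mic_etest_min
    )
    return ratio * mic


def target_check(
    auc: float,
    mic: float = 1.0,
    mic_method: Literal["BMD", "Etest"] = "BMD",
    targets: Optional[PKPDTargets] = None,
) -> TargetVerdict:
    """Check an AUC against the guideline targets.

    The binding efficacy criterion is AUC >= 400 ug.h/mL irrespective of the
    measured MIC (the recommendation assumes MIC 1 ug/mL because a two-fold
    dilution error would otherwise dominate); AUC/MIC by method is reported
    as information.  Safety requires AUC <= 600 ug.h/mL.
    """
    targets = targets or PKPDTargets()
    if auc < 0 or mic <= 0:
        raise ValueError("auc must be >= 0 and mic > 0")
    threshold = (
        targets.auc_mic_bmd_min if mic_method == "BMD" else targets.auc_mic_etest_min
    )
    need = required_auc(mic, mic_method, targets)
    efficacy = auc >= targets.day2_efficacy_min
    safety = auc <= targets.auc_safety_max
    return TargetVerdict(
        auc=auc,
        mic=mic,
        mic_method=mic_method,
        efficacy_met=efficacy,
        safety_met=safety,
        in_band=efficacy and safety,
        auc_mic=auc / mic,
        auc_mic_threshold=threshold,
        required_auc=need,
        attainable_within_safety=need <= targets.auc_safety_max,
        citations=["CQ6(1)", "CQ6(3)", "CQ6(4)", "CQ6(5)"],
    )


def aki_risk(
    patient: PatientCovariates,
    trough: Optional[float] = None,
    targets: Optional[PKPDTargets] = None,
) -> RiskAssessment:
    """Classify AKI risk and return the applicable safe-trough cut-off.

    Independent risk factors: eGFR < 30 mL/min/1.73 m2 before treatment,
    concomitant piperacillin/tazobactam or diuretics, trough > 20 ug/mL, and
    ICU stay.  When several factor-specific cut-offs apply, the lowest
    (most conservative) is returned; with no factors the overall cut-off
    (19.3 ug/mL) applies.
    """
    targets = targets or PKPDTargets()
    factors: list[str] = []
    cutoffs: list[float] = []
    if patient.egfr is not None and patient.egfr < 30.0:
        factors.append("impaired kidney function (eGFR < 30)")
        cutoffs.append(targets.trough_cutoff_impaired_renal)
    if patient.flags.piperacillin_tazobactam:
        factors.append("concomitant piperacillin/tazobactam")
        cutoffs.append(targets.trough_cutoff_pip_tazo)
    if patient.flags.diuretics:
        factors.append("concomitant diuretics")
        cutoffs.append(targets.trough_cutoff_diuretics)
    if trough is not None and trough > 20.0:
        factors.append("trough level > 20 ug/mL")
    if patient.flags.icu:
        factors.append("ICU stay")
    level = "high" if factors else "standard"
    cutoff = min(cutoffs) if cutoffs else targets.trough_cutoff_overall_aki
    return RiskAssessment(
        level=level,  # type: ignore[arg-type]
        factors=factors,
        trough_cutoff=cutoff,
        citations=["CQ3(2)"],
    )


def tdm_timing(patient: PatientCovariates, regimen: Regimen) -> TDMPlan:
    """When to draw the first TDM samples.

    Serious/complicated infection, high AKI risk, or a once-daily (q24h)
    schedule call for TDM on the morning of day 2, before steady state; mild
    infections without risk factors wait until near steady state (day 3+).
    ICU patients additionally get an earlier-and-frequent monitoring flag.
    """
    from .bayes import recommend_sampling  # shared two-point policy

    risk = aki_risk(patient)
    citations: list[str] = []
    notes: list[str] = []
    early = False
    if patient.flags.serious_infection:
        early = True
        citations.append("CQ5(1)")
        notes.append("serious/complicated infection: TDM on day 2 before steady state")
    if risk.level == "high":
        early = True
        citations.append("CQ5(1)")
        notes.append("high AKI risk: TDM on day 2 before steady state")
    if regimen.interval >= 24.0:
        early = True
        citations.append("CQ5(3)")
        notes.append("q24h schedule: day 1 carries the loading dose only; "
                     "two-point measurement on day 2")
    plan_two_point = recommend_sampling(patient, regimen).two_point
    frequent = bool(patient.flags.icu)
    if frequent:
        citations.append("CQ5(6)")
        notes.append("critically ill ICU patient: earlier and frequent TDM")
        early = True
    if early:
        day = 2
        if patient.flags.icu and regimen.interval == 12.0:
            citations.append("CQ5(2)")
            notes.append("two-point sampling before and 1-2 h after the third dose")
    else:
        day = 3
        citations.append("CQ5(5)")
        notes.append("mild/moderate infection without AKI risk: TDM near steady state")
    hold = False
    if day == 2 and not patient.flags.icu:
        hold = True
        citations.append("CQ5(4)")
        notes.append("if only a trough is drawn on day 2 (non-ICU), the third "
                     "dose may be postponed until the TDM result is available")
    return TDMPlan(
        day=day,
        two_point=plan_two_point,
        frequent_monitoring=frequent,
        hold_third_dose_advice=hold,
        notes=notes,
        citations=sorted(set(citations)),
    )


def plateau_auc(css: float) -> float:
    """24-h AUC corresponding to a continuous-infusion plateau concentration:
    AUC = 24 * Css (so 17.5 ug/mL -> 420, 22.5 ug/mL -> 540 ug.h/mL)."""
    if css < 0:
        raise ValueError("plateau concentration must be >= 0")
    return 24.0 * css


def auc_to_plateau(auc: float) -> float:
    """Inverse of :func:`plateau_auc`."""
    if auc < 0:
        raise ValueError("auc must be >= 0")
    return auc / 24.0
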