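"""Calibration, patient and treatment-decision models.

The outcome networks are calibrated from two kinds of numbers:

* *anchors* — constants printed in the clinical literature the model is built
  from (ADT failure rates, ASTRO sensitivity/specificity, nodal-involvement
  probabilities for the two reference patients, the WPRT toxicity increment,
  the median survival with distant metastases);
* *implementation defaults* — quantities the source studies do not print
  (RPA class control rates, LKB parameter fits, state utilities, shaping
  slopes).  These ship as editable configuration, each tagged with its
  provenance in ``Calibration.sources``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, field_validator, model_validator

AdtChoice = Literal["none", "m3", "m6"]
FieldChoice = Literal["PORT", "WPRT"]
RiskGroup = Literal["intermediate", "high"]
Attitude = Literal["population_average", "minus_2sd", "all_ones"]

#: RPA-class label used for the ADT-trial reference cohort (66 Gy era).
REFERENCE_CLASS = "reference_66gy"


class PatientProfile(BaseModel):
    """Pre-treatment staging evidence."""

    age: int = Field(ge=18, le=110)
    t_stage: str = "T2a"
    gleason: int = Field(default=7, ge=2, le=10)
    psa: float = Field(default=10.0, gt=0)

    @property
    def risk_group(self) -> RiskGroup:
        """NCCN-style recurrence-risk stratum (this model covers only
        intermediate and high risk; low-risk patients classify as intermediate
        for modelling purposes)."""
        high_stages = {"T2c", "T3", "T3a", "T3b", "T4"}
        if self.t_stage in high_stages or self.gleason >= 8 or self.psa > 20:
            return "high"
        return "intermediate"


class TreatmentDecision(BaseModel):
    """Field size, androgen deprivation schedule, prescription, and the
    physician's belief in the cure rate of whole-pelvic nodal irradiation."""

    field_choice: FieldChoice = "PORT"
    adt: AdtChoice = "none"
    prescription: float = Field(default=76.0, ge=60.0, le=86.0)
    wprt_cure_rate: float = Field(default=0.0, ge=0.0, le=1.0)


class NtcpOrganParams(BaseModel):
    td50: float = Field(gt=0)
    m: float = Field(gt=0)
    n: float = Field(gt=0, le=1)


class DosimetricRule(BaseModel):
    """Retrospective dose-volume predictor: if V(dose_gy) exceeds
    ``volume_fraction`` the complication odds are multiplied by ``odds``."""

    dose_gy: float
    volume_fraction: float = Field(ge=0, le=1)
    odds: float = Field(gt=0)


class BnedPrimeShaping(BaseModel):
    """Logistic shaping of the dose-modified control probability."""

    slope_eud_per_gy: float = 0.08
    slope_cold_spot: float = 4.0
    cold_spot_ref: float = 0.05


class HotspotShaping(BaseModel):
    """Odds multiplier exp(beta * (d0 - d)/d0), clamped to [1/kappa, kappa]."""

    beta: float = 0.5
    d0_mm: float = 10.0
    kappa: float = 2.0


class UtilityConfig(BaseModel):
    state_utilities: dict[str, float]
    disutility_rectal: float = Field(ge=0, le=1)
    disutility_bladder: float = Field(ge=0, le=1)

    @field_validator("state_utilities")
    @classmethod
    def _bounded(cls, v: dict[str, float]) -> dict[str, float]:
        for s, u in v.items():
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"utility for {s} must lie in [0,1]")
        return v


class Calibration(BaseModel):
    """Every constant the outcome model and cohort simulation consume."""

    # -- printed anchors ------------------------------------------------------
    adt_failure_anchors: dict[AdtChoice, float] = {
        "none": 0.28, "m3": 0.17, "m6": 0.12}
    astro_sensitivity: float = 0.73
    astro_specificity: float = 0.76
    lni_anchor_high: float = 0.26
    lni_anchor_intermediate: float = 0.10
    wprt_toxicity_increment: float = 0.08  # additive probability points
    dm_median_survival_months: float = 19.0
    late_bf_rate_ratio: float = 1.0 / 3.0

    # -- time windows (years post-RT) ----------------------------------------
    bf_onset_window_years: int = 5
    dm_without_bf_window_years: int = 5
    dm_entry_cutoff_years: int = 15
    bf_onset_horizon_years: float = 5.0
    dm_fail_horizon_years: float = 3.0
    dm_control_horizon_years: float = 5.0

    # -- configurable tables (not printed in the source studies) -------------
    rpa_bned_table: dict[str, float] = {
        REFERENCE_CLASS: 0.72,  # 1 - 0.28, the no-ADT reference failure anchor
        "class1": 0.85, "class2": 0.76, "class3": 0.62, "class4": 0.45,
    }
    risk_group_rpa_class: dict[RiskGroup, str] = {
        "intermediate": "class2", "high": "class3"}
    dm_given_failure_3y: dict[RiskGroup, float] = {
        "intermediate": 0.25, "high": 0.45}
    dm_without_bf_5y: dict[RiskGroup, float] = {
        "intermediate": 0.02, "high": 0.05}
    p_dm2_given_lni: float = 0.60
    ntcp: dict[str, NtcpOrganParams] = {
        "rectum": NtcpOrganParams(td50=76.9, m=0.13, n=0.09),
        "bladder": NtcpOrganParams(td50=80.0, m=0.11, n=0.50),
    }
    dosimetric_rules: dict[str, list[DosimetricRule]] = {
        "rectum": [
            DosimetricRule(dose_gy=50.0, volume_fraction=0.50, odds=1.20),
            DosimetricRule(dose_gy=60.0, volume_fraction=0.35, odds=1.25),
            DosimetricRule(dose_gy=70.0, volume_fraction=0.25, odds=1.30),
        ],
        "bladder": [
            DosimetricRule(dose_gy=65.0, volume_fraction=0.50, odds=1.20),
            DosimetricRule(dose_gy=70.0, volume_fraction=0.35, odds=1.25),
            DosimetricRule(dose_gy=75.0, volume_fraction=0.25, odds=1.30),
        ],
    }
    bned_prime: BnedPrimeShaping = BnedPrimeShaping()
    hotspot: HotspotShaping = HotspotShaping()
    eud_exponent_ptv: float = -10.0
    utilities: dict[str, UtilityConfig] = {
        "population_average": UtilityConfig(
            state_utilities={"POST_RT": 1.0, "BF_YEAR1": 0.95, "BF_YEAR2": 0.95,
                             "BF_YEAR3": 0.95, "BF_LATE": 0.95, "DM": 0.25},
            disutility_rectal=0.92, disutility_bladder=0.94),
        "minus_2sd": UtilityConfig(
            state_utilities={"POST_RT": 1.0, "BF_YEAR1": 0.90, "BF_YEAR2": 0.90,
                             "BF_YEAR3": 0.90, "BF_LATE": 0.90, "DM": 0.10},
            disutility_rectal=0.70, disutility_bladder=0.78),
    }

    #: provenance per field: "paper_anchor" values reproduce printed constants;
    #: "implementation_default" values stand in for unpublished calibration.
    sources: dict[str, str] = {
        "adt_failure_anchors": "paper_anchor",
        "astro_sensitivity": "paper_anchor",
        "astro_specificity": "paper_anchor",
        "lni_anchor_high": "paper_anchor",
        "lni_anchor_intermediate": "paper_anchor",
        "wprt_toxicity_increment": "paper_anchor",
        "dm_median_survival_months": "paper_anchor",
        "late_bf_rate_ratio": "paper_anchor",
        "rpa_bned_table": "implementation_default",
        "dm_given_failure_3y": "implementation_default",
        "dm_without_bf_5y": "implementation_default",
        "p_dm2_given_lni": "implementation_default",
        "ntcp": "implementation_default",
        "dosimetric_rules": "implementation_default",
        "bned_prime": "implementation_default",
        "hotspot": "implementation_default",
        "utilities": "implementation_default",
    }

    @model_validator(mode="after")
    def _probabilities_bounded(self) -> "Calibration":
        for name in ("astro_sensitivity", "astro_specificity",
                     "lni_anchor_high", "lni_anchor_intermediate",
                     "wprt_toxicity_increment", "p_dm2_given_lni"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")
        for table in (self.adt_failure_anchors, self.rpa_bned_table,
                      self.dm_given_failure_3y, self.dm_without_bf_5y):
            for k, v in table.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"probability {k}={v} out of [0,1]")
        return self

    def to_json(self, path: str | Path | None = None) -> str:
        text = self.model_dump_json(indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Calibration":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.model_validate(json.loads(text))


def default_calibration() -> Calibration:
    return Calibration()


def get_by_path(model: BaseModel, path: str):
    """Fetch a nested value by dotted path, e.g. ``utilities.population_average.disutility_rectal``."""
    obj = model
    for part in path.split("."):
        if isinstance(obj, BaseModel):
            obj = getattr(obj, part)
        elif isinstance(obj, dict):
            obj = obj[part]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(part)]
        else:
            raise KeyError(f"cannot descend into {type(obj).__name__} at {part!r}")
    return obj


def set_by_path(model: Calibration, path: str, value) -> Calibration:
    """Return a new validated Calibration with one nested value replaced."""
    data = model.model_dump()
    parts = path.split(".")
    obj = data
    for part in parts[:-1]:
        obj = obj[part] if not isinstance(obj, list) else obj[int(part)]
    last = parts[-1]
    if isinstance(obj, list):
        obj[int(last)] = value
    else:
        obj[last] = value
    return Calibration.model_validate(data)
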