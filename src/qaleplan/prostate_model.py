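"""Prostate-cancer outcome networks: tumour control and normal-tissue toxicity.

Two small discrete Bayesian networks turn a plan's dosimetry plus the
patient's staging into the probabilities the cohort simulation needs:

* the *tumour-control* network chains staging -> RPA prognostic class ->
  baseline 5-year biochemical control, modified by androgen deprivation (ADT)
  and by plan dosimetry (EUD, cold spot), and routes two distant-metastasis
  pathways — DM1 (progression signalled by a rising PSA, observed with the
  ASTRO definition's imperfect sensitivity/specificity) and DM2 (progression
  of occult lymph-node disease, interruptible by whole-pelvic irradiation) —
  into a deterministic OR node;
* the *toxicity* network maps each organ-at-risk DVH through the LKB NTCP
  model, adjusts the odds for hotspot proximity and retrospective dose-volume
  predictors, and adds a fixed increment when the field is whole-pelvic.

ADT and field-size nodes carry uniform priors; the chosen treatment enters as
evidence at query time, which is what lets the same network answer
counterfactual policy questions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import bayes_net as bn
from . import dose_metrics as dm
from .config import (
    REFERENCE_CLASS,
    AdtChoice,
    Calibration,
    PatientProfile,
    TreatmentDecision,
)

__all__ = [
    "TumorControlOutputs",
    "ToxicityOutputs",
    "adt_failure_probability",
    "adt_rate_ratio",
    "bned_prime_modifier",
    "build_tumor_control_network",
    "tumor_control_probs",
    "reference_cohort_failure",
    "build_toxicity_network",
    "toxicity_probs",
    "hotspot_odds_multiplier",
    "dosimetric_odds_multiplier",
    "volume_at_dose",
]


@dataclass(frozen=True)
class TumorControlOutputs:
    p_bned_5y: float  # probability of biochemical control at 5 years
    p_dm_given_control: float
    p_dm_given_failure: float
    p_lni: float

    def __post_init__(self) -> None:
        for name in ("p_bned_5y", "p_dm_given_control",
                     "p_dm_given_failure", "p_lni"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} out of [0,1]")


@dataclass(frozen=True)
class ToxicityOutputs:
    p_rectal: float
    p_bladder: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_rectal <= 1 and 0 <= self.p_bladder <= 1):
            raise ValueError("toxicity probabilities must lie in [0,1]")


# --- ADT effect --------------------------------------------------------------

def adt_failure_probability(adt: AdtChoice, calib: Calibration) -> float:
    """5-year biochemical failure probability for the reference cohort."""
    try:
        return calib.adt_failure_anchors[adt]
    except KeyError:
        raise ValueError(f"unknown ADT schedule {adt!r}") from None


def adt_rate_ratio(adt: AdtChoice, calib: Calibration) -> float:
    """Hazard-rate ratio rate(adt)/rate(none) implied by the failure anchors.

    Anchors are converted to constant annual rates over the 5-year horizon;
    applying the ratio to any baseline reproduces the anchors exactly on the
    reference cohort and extends the ADT effect multiplicatively elsewhere.
    """
    p_none = adt_failure_probability("none", calib)
    p_adt = adt_failure_probability(adt, calib)
    return math.log1p(-p_adt) / math.log1p(-p_none)


def _failure_with_adt(p_fail_none: float, adt: AdtChoice,
                      calib: Calibration) -> float:
    """Apply the ADT rate ratio to a baseline 5-year failure probability."""
    if p_fail_none <= 0.0:
        return 0.0
    if p_fail_none >= 1.0:
        return 1.0
    ratio = adt_rate_ratio(adt, calib)
    return 1.0 - (1.0 - p_fail_none) ** ratio


# --- dosimetric modifier of control ------------------------------------------

def bned_prime_modifier(eud: float, cold_spot: float, calib: Calibration,
                        prescription: float) -> float:
    """Multiplier on the control probability from plan dosimetry.

    Product of two rescaled logistics — one rising in (EUD - prescription),
    one falling in (cold spot - reference) — each equal to 1 at the
    calibration reference point so the printed anchors are preserved there.
    """
    if eud <= 0:
        raise ValueError("eud must be positive")
    if not (0.0 <= cold_spot <= 1.0):
        raise ValueError("cold_spot must lie in [0,1]")
    s = calib.bned_prime
    f_eud = 2.0 / (1.0 + math.exp(-s.slope_eud_per_gy * (eud - prescription)))
    f_cold = 2.0 / (1.0 + math.exp(s.slope_cold_spot * (cold_spot - s.cold_spot_ref)))
    return f_eud * f_cold


# --- tumour-control network ---------------------------------------------------

_ADT_STATES = ("none", "m3", "m6")


def build_tumor_control_network(patient: PatientProfile,
                                plan: dm.PlanSummary,
                                decision: TreatmentDecision,
                                calib: Calibration,
                                reference_cohort: bool = False) -> bn.Network:
    """Assemble the tumour-control network for one (patient, plan, decision).

    With ``reference_cohort=True`` the RPA class is pinned to the ADT-trial
    reference stratum (66 Gy era), which is how the calibration anchors are
    audited.
    """
    classes = tuple(sorted(calib.rpa_bned_table))
    for g, c in calib.risk_group_rpa_class.items():
        if c not in calib.rpa_bned_table:
            raise ValueError(f"calibration maps {g} to unknown RPA class {c!r}")

    net = bn.Network()
    groups = ("intermediate", "high")
    prior = [1.0 if g == patient.risk_group else 0.0 for g in groups]
    net.add(bn.NodeSpec("RISK_GROUP", groups, (), np.array([prior])))

    rows = []
    for g in groups:
        target = REFERENCE_CLASS if reference_cohort else calib.risk_group_rpa_class[g]
        rows.append([1.0 if c == target else 0.0 for c in classes])
    net.add(bn.NodeSpec("RPA_CLASS", classes, ("RISK_GROUP",), np.array(rows)))

    net.add(bn.NodeSpec("ADT", _ADT_STATES, (),
                        np.full((1, 3), 1.0 / 3.0)))

    mult = bned_prime_modifier(plan.eud_ptv, plan.cold_spot_fraction,
                               calib, decision.prescription)
    bned_rows, prime_rows = [], []
    for c in classes:
        p_fail_none = 1.0 - calib.rpa_bned_table[c]
        for adt in _ADT_STATES:
            p_fail = _failure_with_adt(p_fail_none, adt, calib)
            bned_rows.append([1.0 - p_fail, p_fail])
            p_ctrl_prime = min(1.0, max(0.0, (1.0 - p_fail) * mult))
            prime_rows.append([p_ctrl_prime, 1.0 - p_ctrl_prime])
    net.add(bn.NodeSpec("BNED", ("control", "failure"),
                        ("RPA_CLASS", "ADT"), np.array(bned_rows)))
    net.add(bn.NodeSpec("BNED_PRIME", ("control", "failure"),
                        ("RPA_CLASS", "ADT"), np.array(prime_rows)))

    p_hi, p_int = calib.lni_anchor_high, calib.lni_anchor_intermediate
    net.add(bn.NodeSpec("LNI", ("yes", "no"), ("RISK_GROUP",),
                        np.array([[p_int, 1 - p_int], [p_hi, 1 - p_hi]])))

    sens, spec = calib.astro_sensitivity, calib.astro_specificity
    # rows: BNED_PRIME = control, failure
    net.add(bn.NodeSpec("PSA_FAILURE", ("yes", "no"), ("BNED_PRIME",),
                        np.array([[1 - spec, spec], [sens, 1 - sens]])))

    dm1_rows = []
    for state in ("control", "failure"):
        for g in groups:
            p = (calib.dm_given_failure_3y[g] if state == "failure"
                 else calib.dm_without_bf_5y[g])
            dm1_rows.append([p, 1 - p])
    net.add(bn.NodeSpec("DM1", ("yes", "no"), ("BNED_PRIME", "RISK_GROUP"),
                        np.array(dm1_rows)))

    p_cured = decision.wprt_cure_rate if decision.field_choice == "WPRT" else 0.0
    net.add(bn.NodeSpec("WPRT_CURED", ("yes", "no"), (),
                        np.array([[p_cured, 1 - p_cured]])))
    p2 = calib.p_dm2_given_lni
    # rows: (LNI, WPRT_CURED) = (yes,yes), (yes,no), (no,yes), (no,no)
    net.add(bn.NodeSpec("DM2", ("yes", "no"), ("LNI", "WPRT_CURED"),
                        np.array([[0.0, 1.0], [p2, 1 - p2],
                                  [0.0, 1.0], [0.0, 1.0]])))

    net.add(bn.or_node("DISTANT_METASTASIS", ["DM1", "DM2"], net))

    errors = bn.validate(net)
    if errors:
        raise ValueError("tumour-control network invalid: " + "; ".join(errors))
    return net


def tumor_control_probs(network: bn.Network,
                        decision: TreatmentDecision) -> TumorControlOutputs:
    """Query the three Markov inputs plus the nodal-involvement probability."""
    ev = {"ADT": decision.adt}
    p_ctrl = bn.query(network, "BNED_PRIME", ev)["control"]
    p_lni = bn.query(network, "LNI", ev)["yes"]
    p_dm_fail = bn.query(network, "DISTANT_METASTASIS",
                         {**ev, "PSA_FAILURE": "yes"})["yes"]
    p_dm_ctrl = bn.query(network, "DISTANT_METASTASIS",
                         {**ev, "PSA_FAILURE": "no"})["yes"]
    return TumorControlOutputs(p_bned_5y=p_ctrl,
                               p_dm_given_control=p_dm_ctrl,
                               p_dm_given_failure=p_dm_fail,
                               p_lni=p_lni)


def reference_cohort_failure(calib: Calibration, adt: AdtChoice,
                             patient: PatientProfile | None = None) -> float:
    """5-year biochemical failure of the reference cohort under an ADT choice.

    Builds the network pinned to the reference stratum with a dosimetrically
    neutral plan and reads P(failure) off the baseline control node with the
    ADT evidence entered; reproduces the failure-rate anchors by construction.
    """
    patient = patient or PatientProfile(age=60, t_stage="T2a", gleason=7, psa=15.0)
    decision = TreatmentDecision(adt=adt)
    plan = _neutral_plan(calib, decision.prescription)
    net = build_tumor_control_network(patient, plan, decision, calib,
                                      reference_cohort=True)
    return bn.query(net, "BNED", {"ADT": adt})["failure"]


def _neutral_plan(calib: Calibration, prescription: float) -> dm.PlanSummary:
    """A plan at the dosimetric calibration reference point (modifier = 1)."""
    return dm.PlanSummary(plan_id="reference",
                          eud_ptv=prescription,
                          cold_spot_fraction=calib.bned_prime.cold_spot_ref,
                          d95=prescription)


# --- toxicity network ---------------------------------------------------------

def volume_at_dose(dvh: dm.DVH, dose: float) -> float:
    """Fraction of the structure receiving at least ``dose`` Gy (bin-exact)."""
    idx = np.searchsorted(dvh.bin_edges, dose, side="right") - 1
    if idx < 0:
        return 1.0
    return float(dvh.cumulative_fraction[idx])


def hotspot_odds_multiplier(distance_mm: float | None,
                            calib: Calibration) -> float:
    """Odds multiplier for hotspot proximity; 1.0 when no hotspot exists."""
    if distance_mm is None:
        return 1.0
    h = calib.hotspot
    raw = math.exp(h.beta * (h.d0_mm - distance_mm) / h.d0_mm)
    return min(max(raw, 1.0 / h.kappa), h.kappa)


def dosimetric_odds_multiplier(dvh: dm.DVH, organ: str,
                               calib: Calibration) -> float:
    """Combined odds multiplier from the retrospective dose-volume predictors."""
    mult = 1.0
    for rule in calib.dosimetric_rules.get(organ, []):
        if volume_at_dose(dvh, rule.dose_gy) > rule.volume_fraction:
            mult *= rule.odds
    return mult


def _apply_odds(p: float, mult: float) -> float:
    if p <= 0.0:
        return 0.0
    if p >= 1.0:
        return 1.0
    o = p / (1.0 - p) * mult
    return o / (1.0 + o)


def _organ_base_probability(plan: dm.PlanSummary, organ: str,
                            calib: Calibration) -> float:
    try:
        dvh = plan.dvhs[organ]
    except KeyError:
        raise ValueError(f"plan {plan.plan_id!r} lacks a DVH for {organ!r}") from None
    ntcp = dm.lkb_ntcp(dvh, dm.NtcpParams(**calib.ntcp[organ].model_dump()))
    distance = (plan.hotspot_distance_rectum if organ == "rectum"
                else plan.hotspot_distance_bladder)
    mult = hotspot_odds_multiplier(distance, calib) \
        * dosimetric_odds_multiplier(dvh, organ, calib)
    return _apply_odds(ntcp, mult)


def build_toxicity_network(plan: dm.PlanSummary, decision: TreatmentDecision,
                           calib: Calibration) -> bn.Network:
    """Per-organ complication nodes conditioned on the field-size decision."""
    net = bn.Network()
    net.add(bn.NodeSpec("FIELD", ("PORT", "WPRT"), (), np.array([[0.5, 0.5]])))
    for organ in ("rectum", "bladder"):
        base = _organ_base_probability(plan, organ, calib)
        wprt = min(1.0, max(0.0, base + calib.wprt_toxicity_increment))
        net.add(bn.NodeSpec(f"{organ.upper()}_COMPLICATION", ("yes", "no"),
                            ("FIELD",),
                            np.array([[base, 1 - base], [wprt, 1 - wprt]])))
    errors = bn.validate(net)
    if errors:
        raise ValueError("toxicity network invalid: " + "; ".join(errors))
    return net


def toxicity_probs(network: bn.Network,
                   decision: TreatmentDecision) -> ToxicityOutputs:
    ev = {"FIELD": decision.field_choice}
    return ToxicityOutputs(
        p_rectal=bn.query(network, "RECTUM_COMPLICATION", ev)["yes"],
        p_bladder=bn.query(network, "BLADDER_COMPLICATION", ev)["yes"],
    )
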