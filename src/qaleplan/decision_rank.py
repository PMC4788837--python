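"""End-to-end plan evaluation, ranking, and treatment-policy comparison.

``evaluate_plan`` composes the pipeline deterministically:
dose metrics -> outcome networks -> Markov cohort -> QALE.  ``rank_plans``
orders a plan set by QALE (the decision endpoint), and ``compare_policies``
evaluates the PORT / WPRT field decision across physician beliefs in the
cure rate of nodal irradiation and across patient attitudes to toxicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import markov_qale as mk
from . import prostate_model as pm
from .config import Attitude, Calibration, PatientProfile, TreatmentDecision
from .dose_metrics import PlanSummary

__all__ = ["PlanEvaluation", "PolicyTable", "evaluate_plan", "rank_plans",
           "compare_policies"]


@dataclass(frozen=True)
class PlanEvaluation:
    plan_id: str
    plan: PlanSummary
    tumor_control: pm.TumorControlOutputs
    toxicity: pm.ToxicityOutputs
    result: mk.QaleResult

    def report(self) -> dict:
        return {
            "plan_id": self.plan_id,
            "d95_gy": self.plan.d95,
            "eud_ptv_gy": self.plan.eud_ptv,
            "cold_spot_fraction": self.plan.cold_spot_fraction,
            "p_bned_5y": self.tumor_control.p_bned_5y,
            "p_lni": self.tumor_control.p_lni,
            "p_dm_given_control": self.tumor_control.p_dm_given_control,
            "p_dm_given_failure": self.tumor_control.p_dm_given_failure,
            "p_rectal": self.toxicity.p_rectal,
            "p_bladder": self.toxicity.p_bladder,
            "life_expectancy_years": self.result.life_expectancy,
            "qale_years": self.result.qale,
        }


def evaluate_plan(plan: PlanSummary, patient: PatientProfile,
                  decision: TreatmentDecision, calib: Calibration,
                  life_table: mk.LifeTable,
                  attitude: Attitude = "population_average") -> PlanEvaluation:
    """Deterministic pipeline composition for one plan."""
    tc_net = pm.build_tumor_control_network(patient, plan, decision, calib)
    tc = pm.tumor_control_probs(tc_net, decision)
    tox_net = pm.build_toxicity_network(plan, decision, calib)
    tox = pm.toxicity_probs(tox_net, decision)
    schedule = mk.build_schedule(tc, life_table, patient.age, calib)
    trace = mk.run_cohort(schedule, mode="deterministic")
    utilities = mk.UtilitySet.from_calibration(calib, attitude)
    result = mk.qale(trace, utilities, tox)
    return PlanEvaluation(plan_id=plan.plan_id, plan=plan,
                          tumor_control=tc, toxicity=tox, result=result)


def rank_plans(evaluations: list[PlanEvaluation]) -> list[PlanEvaluation]:
    """Descending QALE, ties broken by plan id (stable, order-independent)."""
    if not evaluations:
        raise ValueError("no plans to rank")
    return sorted(evaluations, key=lambda e: (-e.result.qale, e.plan_id))


@dataclass(frozen=True)
class PolicyTable:
    """QALE by (age, risk group, attitude) row and field-policy column."""

    rows: pd.DataFrame  # columns: age, risk_group, attitude, PORT, WPRT@b..., optimal

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def compare_policies(patient: PatientProfile, plan: PlanSummary,
                     beliefs: list[float], attitudes: list[Attitude],
                     calib: Calibration, life_table: mk.LifeTable,
                     adt: str = "none",
                     prescription: float = 76.0) -> PolicyTable:
    """Evaluate PORT against WPRT at each cure-rate belief for each attitude.

    All cells share the plan's dosimetry; only the field decision (toxicity
    increment plus nodal-pathway gating) differs, mirroring a policy choice
    made before planning differences are known.
    """
    for b in beliefs:
        if not (0.0 <= b <= 1.0):
            raise ValueError("cure-rate beliefs must lie in [0,1]")
    records = []
    for attitude in attitudes:
        cells: dict[str, float] = {}
        port = evaluate_plan(plan, patient,
                             TreatmentDecision(field_choice="PORT", adt=adt,
                                               prescription=prescription),
                             calib, life_table, attitude)
        cells["PORT"] = port.result.qale
        for b in beliefs:
            wprt = evaluate_plan(plan, patient,
                                 TreatmentDecision(field_choice="WPRT", adt=adt,
                                                   prescription=prescription,
                                                   wprt_cure_rate=b),
                                 calib, life_table, attitude)
            cells[f"WPRT@{b:g}"] = wprt.result.qale
        best = max(cells.values())
        winners = sorted(k for k, v in cells.items() if v == best)
        records.append({"age": patient.age, "risk_group": patient.risk_group,
                        "attitude": attitude, **cells,
                        "optimal": "|".join(winners)})
    return PolicyTable(rows=pd.DataFrame.from_records(records))
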