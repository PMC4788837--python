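"""Sensitivity machinery: one-way sweeps, two-way threshold maps, and
probabilistic sensitivity analysis (PSA) with a linear-regression metamodel.

Parameters are addressed by dotted path into the calibration (e.g.
``utilities.population_average.disutility_rectal``); the PSA draws each
parameter from a normal distribution truncated to its physical bounds using
the inverse-CDF method, evaluates the full pipeline per draw, and ranks
parameter importance by standardized ordinary-least-squares coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import truncnorm

from . import markov_qale as mk
from .config import Attitude, Calibration, PatientProfile, TreatmentDecision, set_by_path
from .decision_rank import evaluate_plan
from .dose_metrics import PlanSummary

__all__ = [
    "ParameterSpec", "PsaResult", "ThresholdMap",
    "one_way_sweep", "two_way_threshold", "probabilistic_sa", "fit_metamodel",
]


@dataclass(frozen=True)
class ParameterSpec:
    """A calibration entry with either a sampling distribution or a sweep grid."""

    path: str
    mean: float | None = None
    sd: float | None = None
    lo: float = 0.0
    hi: float = 1.0
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError(f"{self.path}: lo must be < hi")
        if self.grid is not None:
            g = np.asarray(self.grid, dtype=float)
            object.__setattr__(self, "grid", g)
            if np.any((g < self.lo) | (g > self.hi)):
                raise ValueError(f"{self.path}: grid leaves [{self.lo}, {self.hi}]")


@dataclass
class PsaResult:
    specs: list[ParameterSpec]
    draws: np.ndarray  # (n, p)
    outcomes: dict[str, np.ndarray]  # strategy -> (n,) QALY
    dropped: list[str] = field(default_factory=list)
    coefficients: pd.DataFrame | None = None
    r_squared: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ThresholdMap:
    p_lni_grid: np.ndarray
    p_cure_grid: np.ndarray
    winner: np.ndarray  # (len(p_lni), len(p_cure)) of strategy labels
    delta_qaly: np.ndarray  # QALE(WPRT) - QALE(PORT)

    def to_csv(self, path) -> None:
        rows = []
        for i, y in enumerate(self.p_lni_grid):
            for j, x in enumerate(self.p_cure_grid):
                rows.append({"p_lni": y, "p_cure": x,
                             "winner": self.winner[i, j],
                             "delta_qaly": self.delta_qaly[i, j]})
        pd.DataFrame(rows).to_csv(path, index=False)


def _strategy_decision(strategy: str, cure_rate: float,
                       adt: str, prescription: float) -> TreatmentDecision:
    if strategy == "PORT":
        return TreatmentDecision(field_choice="PORT", adt=adt,
                                 prescription=prescription)
    if strategy == "WPRT":
        return TreatmentDecision(field_choice="WPRT", adt=adt,
                                 prescription=prescription,
                                 wprt_cure_rate=cure_rate)
    raise ValueError(f"unknown strategy {strategy!r}")


def _evaluate(calib: Calibration, patient: PatientProfile, plan: PlanSummary,
              strategy: str, life_table: mk.LifeTable, attitude: Attitude,
              cure_rate: float, adt: str, prescription: float) -> float:
    decision = _strategy_decision(strategy, cure_rate, adt, prescription)
    ev = evaluate_plan(plan, patient, decision, calib, life_table, attitude)
    return ev.result.qale


def one_way_sweep(param: ParameterSpec, patient: PatientProfile,
                  plan: PlanSummary, strategies: list[str],
                  calib: Calibration, life_table: mk.LifeTable,
                  attitude: Attitude = "population_average",
                  cure_rate: float = 0.5, adt: str = "none",
                  prescription: float = 76.0) -> pd.DataFrame:
    """QALY per grid point per strategy, everything else held fixed."""
    if param.grid is None:
        raise ValueError("one_way_sweep requires a grid in the ParameterSpec")
    records = []
    for value in param.grid:
        calib_v = set_by_path(calib, param.path, float(value))
        row = {"value": float(value)}
        for s in strategies:
            row[s] = _evaluate(calib_v, patient, plan, s, life_table,
                               attitude, cure_rate, adt, prescription)
        records.append(row)
    return pd.DataFrame.from_records(records)


def two_way_threshold(p_lni_grid, p_cure_grid, patient: PatientProfile,
                      plan: PlanSummary, calib: Calibration,
                      life_table: mk.LifeTable,
                      attitude: Attitude = "population_average",
                      adt: str = "none",
                      prescription: float = 76.0) -> ThresholdMap:
    """Dominant field strategy over a (P(LNI), P(cure)) grid.

    Each cell overrides the nodal-involvement probability for the patient's
    risk group, evaluates both strategies, and labels the maximum (ties go
    to PORT, the less toxic default)."""
    p_lni_grid = np.asarray(p_lni_grid, dtype=float)
    p_cure_grid = np.asarray(p_cure_grid, dtype=float)
    if np.any((p_lni_grid < 0) | (p_lni_grid > 1)) \
            or np.any((p_cure_grid < 0) | (p_cure_grid > 1)):
        raise ValueError("grids must lie within [0,1]")
    lni_path = ("lni_anchor_high" if patient.risk_group == "high"
                else "lni_anchor_intermediate")
    winner = np.empty((p_lni_grid.size, p_cure_grid.size), dtype=object)
    delta = np.zeros_like(winner, dtype=float)
    for i, p_lni in enumerate(p_lni_grid):
        calib_i = set_by_path(calib, lni_path, float(p_lni))
        q_port = _evaluate(calib_i, patient, plan, "PORT", life_table,
                           attitude, 0.0, adt, prescription)
        for j, p_cure in enumerate(p_cure_grid):
            q_wprt = _evaluate(calib_i, patient, plan, "WPRT", life_table,
                               attitude, float(p_cure), adt, prescription)
            delta[i, j] = q_wprt - q_port
            winner[i, j] = "WPRT" if q_wprt > q_port else "PORT"
    return ThresholdMap(p_lni_grid=p_lni_grid, p_cure_grid=p_cure_grid,
                        winner=winner, delta_qaly=delta)


def probabilistic_sa(specs: list[ParameterSpec], n: int, seed: int,
                     patient: PatientProfile, plan: PlanSummary,
                     strategies: list[str], calib: Calibration,
                     life_table: mk.LifeTable,
                     attitude: Attitude = "population_average",
                     cure_rate: float = 0.5, adt: str = "none",
                     prescription: float = 76.0) -> PsaResult:
    """Seeded truncated-normal PSA: each draw is an alternative cohort.

    Sampling uses the inverse CDF on the truncated interval, so draws are
    exactly reproducible for a seed and always respect the bounds."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    draws = np.empty((n, len(specs)))
    for j, spec in enumerate(specs):
        if spec.mean is None or spec.sd is None:
            raise ValueError(f"{spec.path}: PSA requires mean and sd")
        if spec.sd == 0.0:
            draws[:, j] = spec.mean
            continue
        a = (spec.lo - spec.mean) / spec.sd
        b = (spec.hi - spec.mean) / spec.sd
        u = rng.uniform(size=n)
        draws[:, j] = truncnorm.ppf(u, a, b, loc=spec.mean, scale=spec.sd)
    outcomes = {s: np.empty(n) for s in strategies}
    for i in range(n):
        calib_i = calib
        for j, spec in enumerate(specs):
            calib_i = set_by_path(calib_i, spec.path, float(draws[i, j]))
        for s in strategies:
            outcomes[s][i] = _evaluate(calib_i, patient, plan, s, life_table,
                                       attitude, cure_rate, adt, prescription)
    return PsaResult(specs=list(specs), draws=draws, outcomes=outcomes)


def fit_metamodel(psa: PsaResult, strategy: str | None = None) -> PsaResult:
    """Standardized OLS of outcome on inputs; coefficients rank importance.

    Zero-variance inputs (degenerate truncations) are dropped and recorded.
    """
    strategies = [strategy] if strategy else list(psa.outcomes)
    X = psa.draws
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    psa.dropped = [s.path for s, k in zip(psa.specs, keep) if not k]
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    names = [s.path for s, k in zip(psa.specs, keep) if k]
    n, p = Xs.shape
    if n <= p + 1:
        raise ValueError("need n > p + 1 draws to fit the metamodel")
    frames = []
    for s in strategies:
        y = psa.outcomes[s]
        model = sm.OLS(y, sm.add_constant(Xs)).fit()
        df = pd.DataFrame({
            "strategy": s,
            "parameter": ["const"] + names,
            "coefficient": model.params,
            "std_error": model.bse,
        })
        df["abs_rank"] = (-df["coefficient"].abs()).where(df["parameter"] != "const").rank()
        frames.append(df)
        psa.r_squared[s] = float(model.rsquared)
    psa.coefficients = pd.concat(frames, ignore_index=True)
    return psa
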