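"""Markov cohort simulation of post-radiotherapy health-state evolution.

States
------
``POST_RT`` (biochemically controlled), three biochemical-failure tunnel
states ``BF_YEAR1..3`` (no self-transition; they give the first three years
after a PSA rise a higher metastasis rate), ``BF_LATE`` (rate one third of
the tunnel rate), ``DM`` (distant metastases), and the absorbing ``DEAD``.

Conventions
-----------
* Cycle length is 1 year; the model runs from radiotherapy until the patient
  would be 119, the last age the life table covers.
* Cycle ``t`` spans years ``[t-1, t)`` post-RT; the life-table lookup uses the
  attained age ``start_age + t - 1`` at the start of the cycle.
* No half-cycle correction: a cycle of occupancy is credited per cycle
  survived, i.e. life expectancy sums the post-transition alive occupancy of
  every cycle (so a constant death probability ``p`` yields LE ``(1-p)/p``).
* Competing risks within a cycle combine as independent hazards,
  ``p_total = 1 - prod(1 - p_k)``, allocated across destinations
  proportionally to the individual ``p_k``.

The five-year cumulative probabilities produced by the outcome network are
converted to annual transition probabilities through a constant-rate
assumption: ``p_c = 1 - exp(-r a t)`` inverted for the annual rate, then
``p_a = 1 - exp(-r_a)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Attitude, Calibration
from .prostate_model import ToxicityOutputs, TumorControlOutputs

__all__ = [
    "STATES",
    "LifeTable",
    "UtilitySet",
    "TransitionSchedule",
    "CohortTrace",
    "QaleResult",
    "annual_rate_from_cumulative",
    "annual_prob_from_rate",
    "rate_from_median",
    "build_schedule",
    "run_cohort",
    "qale",
]

STATES: tuple[str, ...] = (
    "POST_RT", "BF_YEAR1", "BF_YEAR2", "BF_YEAR3", "BF_LATE", "DM", "DEAD")
TUNNEL_STATES = ("BF_YEAR1", "BF_YEAR2", "BF_YEAR3")
ALIVE_STATES = STATES[:-1]
MAX_AGE = 119

_IDX = {s: i for i, s in enumerate(STATES)}


# --- probability / rate conversions ------------------------------------------

def annual_rate_from_cumulative(p_c: float, t: float) -> float:
    """Constant annual rate implied by a t-year cumulative probability."""
    if not (0.0 <= p_c < 1.0):
        raise ValueError("cumulative probability must lie in [0, 1)")
    if t <= 0:
        raise ValueError("horizon t must be positive")
    return -np.log1p(-p_c) / t


def annual_prob_from_rate(r: float) -> float:
    """Annual transition probability from a constant annual rate."""
    if r < 0:
        raise ValueError("rate must be non-negative")
    return float(-np.expm1(-r))


def rate_from_median(median_years: float) -> float:
    """Constant exit rate implied by a median residence time."""
    if median_years <= 0:
        raise ValueError("median must be positive")
    return float(np.log(2.0) / median_years)


# --- life table ---------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Annual death probability indexed by integer attained age."""

    ages: np.ndarray
    annual_death_prob: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        probs = np.asarray(self.annual_death_prob, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "annual_death_prob", probs)
        if ages.size != probs.size or ages.size == 0:
            raise ValueError("ages and probabilities must be non-empty and aligned")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be consecutive integers")
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("death probabilities must lie in [0,1]")

    def death_prob(self, age: int) -> float:
        i = age - int(self.ages[0])
        if i < 0 or i >= self.ages.size:
            raise KeyError(f"life table does not cover age {age}")
        return float(self.annual_death_prob[i])

    def covers(self, lo: int, hi: int) -> bool:
        return int(self.ages[0]) <= lo and int(self.ages[-1]) >= hi

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(ages=df["age"].to_numpy(int),
                   annual_death_prob=df["annual_death_prob"].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages,
                      "annual_death_prob": self.annual_death_prob}
                     ).to_csv(path, index=False)


# --- utilities ----------------------------------------------------------------

@dataclass(frozen=True)
class UtilitySet:
    """State utilities plus multiplicative complication disutility factors."""

    state_utilities: dict[str, float]
    disutility_rectal: float
    disutility_bladder: float
    attitude: Attitude

    def __post_init__(self) -> None:
        missing = set(ALIVE_STATES) - set(self.state_utilities)
        if missing:
            raise ValueError(f"utilities missing states: {sorted(missing)}")
        for v in (*self.state_utilities.values(),
                  self.disutility_rectal, self.disutility_bladder):
            if not (0.0 <= v <= 1.0):
                raise ValueError("utilities and disutility factors must lie in [0,1]")

    @classmethod
    def from_calibration(cls, calib: Calibration, attitude: Attitude) -> "UtilitySet":
        if attitude == "all_ones":
            return cls(state_utilities={s: 1.0 for s in ALIVE_STATES},
                       disutility_rectal=1.0, disutility_bladder=1.0,
                       attitude="all_ones")
        cfg = calib.utilities[attitude]
        return cls(state_utilities=dict(cfg.state_utilities),
                   disutility_rectal=cfg.disutility_rectal,
                   disutility_bladder=cfg.disutility_bladder,
                   attitude=attitude)


# --- transition schedule -------------------------------------------------------

@dataclass(frozen=True)
class TransitionSchedule:
    """Time-indexed annual transition probabilities for the cohort model."""

    start_age: int
    n_cycles: int
    life_table: LifeTable
    p_bf_annual: float
    p_dm_no_bf_annual: float
    p_dm_bf_early_annual: float
    p_dm_bf_late_annual: float
    p_dm_death_annual: float
    bf_onset_window: int = 5
    dm_no_bf_window: int = 5
    dm_entry_cutoff: int = 15

    def transition_matrix(self, cycle: int) -> np.ndarray:
        """Row-stochastic matrix for cycle ``cycle`` (1-based)."""
        if not (1 <= cycle <= self.n_cycles):
            raise ValueError(f"cycle {cycle} outside 1..{self.n_cycles}")
        age = self.start_age + cycle - 1
        q = self.life_table.death_prob(age)
        years_post_rt = cycle - 1  # at the start of the cycle
        dm_open = years_post_rt < self.dm_entry_cutoff

        m = np.zeros((len(STATES), len(STATES)))

        def fill(row: str, risks: list[tuple[str, float]], survivor: str) -> None:
            i = _IDX[row]
            probs = np.array([p for _, p in risks], dtype=float)
            stay = float(np.prod(1.0 - probs))
            total = 1.0 - stay
            s = probs.sum()
            for (dest, _), p in zip(risks, probs):
                m[i, _IDX[dest]] += total * p / s if s > 0 else 0.0
            m[i, _IDX[survivor]] += stay

        p_bf = self.p_bf_annual if cycle <= self.bf_onset_window else 0.0
        p_dm_nb = (self.p_dm_no_bf_annual
                   if cycle <= self.dm_no_bf_window and dm_open else 0.0)
        fill("POST_RT", [("DEAD", q), ("BF_YEAR1", p_bf), ("DM", p_dm_nb)],
             survivor="POST_RT")

        p_early = self.p_dm_bf_early_annual if dm_open else 0.0
        p_late = self.p_dm_bf_late_annual if dm_open else 0.0
        fill("BF_YEAR1", [("DEAD", q), ("DM", p_early)], survivor="BF_YEAR2")
        fill("BF_YEAR2", [("DEAD", q), ("DM", p_early)], survivor="BF_YEAR3")
        fill("BF_YEAR3", [("DEAD", q), ("DM", p_early)], survivor="BF_LATE")
        fill("BF_LATE", [("DEAD", q), ("DM", p_late)], survivor="BF_LATE")

        p_death_dm = 1.0 - (1.0 - self.p_dm_death_annual) * (1.0 - q)
        m[_IDX["DM"], _IDX["DEAD"]] = p_death_dm
        m[_IDX["DM"], _IDX["DM"]] = 1.0 - p_death_dm
        m[_IDX["DEAD"], _IDX["DEAD"]] = 1.0

        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise AssertionError("transition rows must sum to 1")
        return m


def build_schedule(tc: TumorControlOutputs, life_table: LifeTable,
                   start_age: int, calib: Calibration) -> TransitionSchedule:
    """Convert network outputs into the full time-indexed schedule."""
    n_cycles = MAX_AGE - start_age
    if n_cycles < 1:
        raise ValueError("start age leaves no cycles before the horizon")
    if not life_table.covers(start_age, MAX_AGE - 1):
        raise KeyError("life table does not cover the simulation horizon")

    p_fail_5y = 1.0 - tc.p_bned_5y
    r_bf = annual_rate_from_cumulative(min(p_fail_5y, 1 - 1e-12),
                                       calib.bf_onset_horizon_years)
    r_dm_nb = annual_rate_from_cumulative(min(tc.p_dm_given_control, 1 - 1e-12),
                                          calib.dm_control_horizon_years)
    r_dm_bf = annual_rate_from_cumulative(min(tc.p_dm_given_failure, 1 - 1e-12),
                                          calib.dm_fail_horizon_years)
    r_dm_death = rate_from_median(calib.dm_median_survival_months / 12.0)

    return TransitionSchedule(
        start_age=start_age,
        n_cycles=n_cycles,
        life_table=life_table,
        p_bf_annual=annual_prob_from_rate(r_bf),
        p_dm_no_bf_annual=annual_prob_from_rate(r_dm_nb),
        p_dm_bf_early_annual=annual_prob_from_rate(r_dm_bf),
        p_dm_bf_late_annual=annual_prob_from_rate(r_dm_bf * calib.late_bf_rate_ratio),
        p_dm_death_annual=annual_prob_from_rate(r_dm_death),
        bf_onset_window=calib.bf_onset_window_years,
        dm_no_bf_window=calib.dm_without_bf_window_years,
        dm_entry_cutoff=calib.dm_entry_cutoff_years,
    )


# --- cohort propagation --------------------------------------------------------

@dataclass(frozen=True)
class CohortTrace:
    """Post-transition state occupancy fractions, one row per cycle."""

    occupancy: np.ndarray  # shape (n_cycles, n_states)
    states: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != len(self.states):
            raise ValueError("occupancy must be (n_cycles, n_states)")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("occupancy rows must sum to 1")
        dead = occ[:, _IDX["DEAD"]]
        if np.any(np.diff(dead) < -1e-12):
            raise ValueError("DEAD occupancy must be non-decreasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.occupancy, columns=list(self.states)).to_csv(
            path, index_label="cycle")


def run_cohort(schedule: TransitionSchedule,
               mode: str = "deterministic",
               cohort_size: int = 100_000,
               seed: int | None = None) -> CohortTrace:
    """Propagate the cohort through the schedule.

    ``deterministic`` propagates occupancy fractions exactly; ``monte_carlo``
    simulates ``cohort_size`` individuals with multinomial draws.
    """
    n = len(STATES)
    if mode == "deterministic":
        occ = np.zeros(n)
        occ[_IDX["POST_RT"]] = 1.0
        rows = []
        for t in range(1, schedule.n_cycles + 1):
            occ = occ @ schedule.transition_matrix(t)
            rows.append(occ.copy())
        return CohortTrace(occupancy=np.array(rows))
    if mode == "monte_carlo":
        if cohort_size < 1:
            raise ValueError("cohort_size must be >= 1 in monte_carlo mode")
        rng = np.random.default_rng(seed)
        counts = np.zeros(n, dtype=np.int64)
        counts[_IDX["POST_RT"]] = cohort_size
        rows = []
        for t in range(1, schedule.n_cycles + 1):
            m = schedule.transition_matrix(t)
            new = np.zeros(n, dtype=np.int64)
            for i in range(n):
                if counts[i] > 0:
                    new += rng.multinomial(counts[i], m[i])
            counts = new
            rows.append(counts / cohort_size)
        return CohortTrace(occupancy=np.array(rows))
    raise ValueError(f"unknown mode {mode!r}")


# --- QALE ----------------------------------------------------------------------

@dataclass(frozen=True)
class QaleResult:
    life_expectancy: float
    qale: float
    state_years: dict[str, float]

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.qale <= self.life_expectancy + 1e-9):
            raise ValueError("qale must lie in [0, life_expectancy]")


#: complications are late effects, modelled as present from this cycle onward
COMPLICATION_ONSET_CYCLE = 3


def qale(trace: CohortTrace, utilities: UtilitySet,
         tox: ToxicityOutputs) -> QaleResult:
    """Life expectancy and quality-adjusted life expectancy from a trace.

    Complication status mixes four independent branches (none / rectal /
    bladder / both) weighted by the lifetime toxicity probabilities; the
    disutility factors apply from :data:`COMPLICATION_ONSET_CYCLE` onward,
    in every alive state except ``DM`` (metastatic disease dominates quality
    of life there).
    """
    occ = trace.occupancy
    alive = occ[:, [_IDX[s] for s in ALIVE_STATES]]
    le = float(alive.sum())
    state_years = {s: float(occ[:, _IDX[s]].sum()) for s in STATES}

    pr, pb = tox.p_rectal, tox.p_bladder
    weights = {
        (False, False): (1 - pr) * (1 - pb),
        (True, False): pr * (1 - pb),
        (False, True): (1 - pr) * pb,
        (True, True): pr * pb,
    }
    u_base = np.array([utilities.state_utilities[s] for s in ALIVE_STATES])
    dm_col = ALIVE_STATES.index("DM")
    total = 0.0
    for (rectal, bladder), w in weights.items():
        if w == 0.0:
            continue
        factor = ((utilities.disutility_rectal if rectal else 1.0)
                  * (utilities.disutility_bladder if bladder else 1.0))
        u_comp = u_base * factor
        u_comp[dm_col] = u_base[dm_col]  # complications neglected with metastases
        for t0 in range(occ.shape[0]):
            u = u_base if (t0 + 1) < COMPLICATION_ONSET_CYCLE else u_comp
            total += w * float(alive[t0] @ u)
    return QaleResult(life_expectancy=le, qale=total, state_years=state_years)
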