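"""Reduced-scale multiobjective evolutionary IMRT planner.

The planner works on a 2-D dose-influence phantom (see
:mod:`qaleplan.fixtures_io`).  Each *gene* holds the weights and dose targets
of a set of convex quadratic dosimetric objectives; an inner non-negative
solve produces the fluence map for a gene; a configurable set of *decision
criteria* (coverage and complication metrics, not the inner objectives)
drives Pareto selection, and the archive keeps every mutually non-dominated
plan found.

Objective semantics: target objectives penalize deviation on both sides of
the dose target; organ-at-risk objectives penalize overdose only (one-sided
quadratic), the standard planning convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import dose_metrics as dm
from .config import Calibration

__all__ = [
    "Phantom", "ObjectiveSpec", "Gene", "Plan", "CriteriaVector",
    "ParetoArchive", "PlannerConfig", "inner_solve", "decision_criteria",
    "dominates", "update_archive", "evolve", "hypervolume",
]


@dataclass(frozen=True)
class Phantom:
    """2-D slice with structure masks and a precomputed dose-influence matrix."""

    nx: int
    ny: int
    spacing_mm: float
    masks: dict[str, np.ndarray]  # structure -> boolean (ny, nx)
    influence: np.ndarray  # (n_voxels, n_beamlets), Gy per unit fluence

    def __post_init__(self) -> None:
        if np.any(self.influence < 0):
            raise ValueError("dose-influence matrix must be non-negative")
        for name, mask in self.masks.items():
            if mask.shape != (self.ny, self.nx):
                raise ValueError(f"mask {name!r} does not match the grid")
            if not mask.any():
                raise ValueError(f"structure {name!r} is empty")

    def structure_doses(self, dose_flat: np.ndarray, structure: str) -> np.ndarray:
        return dose_flat[self.masks[structure].reshape(-1)]


@dataclass(frozen=True)
class ObjectiveSpec:
    structure: str
    one_sided: bool  # True: penalize overdose only (organ at risk)


@dataclass(frozen=True)
class Gene:
    """Per-objective weights (>= 0) and dose targets (Gy)."""

    weights: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "targets", t)
        if w.shape != t.shape or w.ndim != 1:
            raise ValueError("weights and targets must be 1-D and aligned")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative with at least one positive")
        if np.any((t < 0) | (t > 100)):
            raise ValueError("dose targets must lie in [0, 100] Gy")


@dataclass(frozen=True)
class Plan:
    fluence: np.ndarray
    dose: np.ndarray
    objective_value: float
    converged: bool


@dataclass(frozen=True)
class CriteriaVector:
    names: tuple[str, ...]
    values: np.ndarray
    higher_better: tuple[bool, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("criteria values must be finite")
        if not (len(self.names) == v.size == len(self.higher_better)):
            raise ValueError("criteria fields must align")

    def oriented(self) -> np.ndarray:
        """Values flipped so that larger is always better."""
        sign = np.where(np.asarray(self.higher_better), 1.0, -1.0)
        return self.values * sign


@dataclass
class ArchiveEntry:
    gene: Gene
    plan: Plan
    criteria: CriteriaVector


@dataclass
class ParetoArchive:
    entries: list[ArchiveEntry] = field(default_factory=list)

    def criteria_matrix(self) -> np.ndarray:
        return np.array([e.criteria.values for e in self.entries])


@dataclass
class PlannerConfig:
    prescription: float = 76.0
    objectives: tuple[ObjectiveSpec, ...] = (
        ObjectiveSpec("ptv", one_sided=False),
        ObjectiveSpec("rectum", one_sided=True),
        ObjectiveSpec("bladder", one_sided=True),
        ObjectiveSpec("normal", one_sided=True),
    )
    calibration: Calibration = field(default_factory=Calibration)
    eud_a_ptv: float = -10.0
    d95_constraint: float | None = None  # Gy; gate on PTV D95 when set
    population: int = 20
    generations: int = 50
    mutation_sd_logw: float = 0.5
    mutation_sd_dose: float = 2.0
    crossover_rate: float = 0.5
    archive_cap: int | None = None
    hv_reference: tuple[float, ...] = (101.0, 101.0, 1.1, 1.1, 1.1)


# --- inner convex solve -------------------------------------------------------

def _objective_and_grad(x: np.ndarray, gene: Gene, phantom: Phantom,
                        config: PlannerConfig) -> tuple[float, np.ndarray]:
    d = phantom.influence @ x
    total = 0.0
    g_d = np.zeros_like(d)
    for j, spec in enumerate(config.objectives):
        w = gene.weights[j]
        if w == 0.0:
            continue
        idx = phantom.masks[spec.structure].reshape(-1)
        r = d[idx] - gene.targets[j]
        if spec.one_sided:
            r = np.maximum(r, 0.0)
        total += w * float(r @ r)
        g = np.zeros_like(d)
        g[idx] = 2.0 * w * r
        g_d += g
    return total, phantom.influence.T @ g_d


def inner_solve(gene: Gene, phantom: Phantom, config: PlannerConfig,
                tol: float = 1e-8, max_iter: int = 500) -> Plan:
    """Minimize the weighted quadratic objective over non-negative fluence."""
    if len(gene.weights) != len(config.objectives):
        raise ValueError("gene length does not match configured objectives")
    n = phantom.influence.shape[1]
    x0 = np.full(n, config.prescription / max(phantom.influence.sum(axis=1).max(), 1e-9))
    res = minimize(
        _objective_and_grad, x0, args=(gene, phantom, config), jac=True,
        method="L-BFGS-B", bounds=[(0.0, None)] * n,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    x = np.maximum(res.x, 0.0)
    return Plan(fluence=x, dose=phantom.influence @ x,
                objective_value=float(res.fun), converged=bool(res.success))


# --- decision criteria --------------------------------------------------------

CRITERIA_NAMES = ("ptv_d95", "ptv_eud", "cold_spot", "ntcp_rectum", "ntcp_bladder")
CRITERIA_HIGHER = (True, True, False, False, False)


def decision_criteria(plan: Plan, phantom: Phantom,
                      config: PlannerConfig) -> CriteriaVector:
    """Coverage and complication metrics used for Pareto selection."""
    for s in ("ptv", "rectum", "bladder"):
        if s not in phantom.masks:
            raise KeyError(f"phantom lacks structure {s!r}")
    ptv = phantom.structure_doses(plan.dose, "ptv")
    dvh_ptv = dm.build_cumulative_dvh(ptv, structure_name="ptv")
    d95 = dm.dose_at_volume(dvh_ptv, 0.95)
    eud = dm.equivalent_uniform_dose(ptv, dm.EudParams(a=config.eud_a_ptv))
    cold = dm.cold_spot_fraction(ptv, config.prescription)
    calib = config.calibration
    ntcps = {}
    for organ in ("rectum", "bladder"):
        doses = phantom.structure_doses(plan.dose, organ)
        dvh = dm.build_cumulative_dvh(doses, structure_name=organ)
        params = dm.NtcpParams(**calib.ntcp[organ].model_dump())
        ntcps[organ] = dm.lkb_ntcp(dvh, params)
    return CriteriaVector(
        names=CRITERIA_NAMES,
        values=np.array([d95, eud, cold, ntcps["rectum"], ntcps["bladder"]]),
        higher_better=CRITERIA_HIGHER,
    )


# --- Pareto machinery ---------------------------------------------------------

def dominates(a: CriteriaVector, b: CriteriaVector) -> bool:
    """True iff ``a`` is at least as good everywhere and better somewhere."""
    if a.names != b.names or a.higher_better != b.higher_better:
        raise ValueError("criteria sets do not match")
    ao, bo = a.oriented(), b.oriented()
    return bool(np.all(ao >= bo) and np.any(ao > bo))


def update_archive(archive: ParetoArchive, candidate: ArchiveEntry) -> ParetoArchive:
    """Insert iff non-dominated; evict members the candidate dominates."""
    for e in archive.entries:
        if dominates(e.criteria, candidate.criteria):
            return archive
    kept = [e for e in archive.entries
            if not dominates(candidate.criteria, e.criteria)]
    kept.append(candidate)
    archive.entries = kept
    return archive


def _crowding_prune(archive: ParetoArchive, cap: int) -> None:
    if len(archive.entries) <= cap:
        return
    vals = np.array([e.criteria.oriented() for e in archive.entries])
    n, m = vals.shape
    crowd = np.zeros(n)
    for j in range(m):
        order = np.argsort(vals[:, j], kind="stable")
        crowd[order[0]] = crowd[order[-1]] = np.inf
        span = vals[order[-1], j] - vals[order[0], j]
        if span <= 0:
            continue
        for k in range(1, n - 1):
            crowd[order[k]] += (vals[order[k + 1], j] - vals[order[k - 1], j]) / span
    keep = np.argsort(-crowd, kind="stable")[:cap]
    archive.entries = [archive.entries[i] for i in sorted(keep)]


# --- hypervolume (exact, WFG recursion; fine at archive scale) ----------------

def _nondominated_min(points: list[np.ndarray]) -> list[np.ndarray]:
    out = []
    for p in points:
        if not any(np.all(q <= p) and np.any(q < p) for q in points if q is not p):
            if not any(np.array_equal(p, q) for q in out):
                out.append(p)
    return out


def hypervolume(criteria: list[CriteriaVector], reference: tuple[float, ...]) -> float:
    """Exact dominated hypervolume (all criteria mapped to minimization)."""
    ref = np.asarray(reference, dtype=float)
    pts = []
    for c in criteria:
        sign = np.where(np.asarray(c.higher_better), -1.0, 1.0)
        offset = np.where(np.asarray(c.higher_better), 100.0, 0.0)
        pts.append(offset + sign * c.values)  # min-form, non-negative
    pts = [p for p in pts if np.all(p < ref)]
    pts = _nondominated_min(pts)

    def wfg(s: list[np.ndarray]) -> float:
        total = 0.0
        for i, p in enumerate(s):
            limited = _nondominated_min([np.maximum(p, q) for q in s[i + 1:]])
            total += float(np.prod(ref - p)) - wfg(limited)
        return total

    return wfg(sorted(pts, key=lambda p: tuple(p)))


# --- evolutionary loop --------------------------------------------------------

def _random_gene(rng: np.random.Generator, config: PlannerConfig) -> Gene:
    n = len(config.objectives)
    logw = rng.normal(0.0, 1.0, size=n)
    weights = np.exp(logw)
    targets = np.empty(n)
    for j, spec in enumerate(config.objectives):
        if spec.one_sided:
            targets[j] = rng.uniform(0.0, 0.8 * config.prescription)
        else:
            targets[j] = config.prescription + rng.normal(0.0, 1.0)
    return Gene(weights=weights, targets=np.clip(targets, 0.0, 100.0))


def _mutate_crossover(parents: tuple[Gene, Gene], rng: np.random.Generator,
                      config: PlannerConfig) -> Gene:
    a, b = parents
    take_b = rng.random(len(a.weights)) < config.crossover_rate
    w = np.where(take_b, b.weights, a.weights)
    t = np.where(take_b, b.targets, a.targets)
    w = np.exp(np.log(np.maximum(w, 1e-12))
               + rng.normal(0.0, config.mutation_sd_logw, size=w.size))
    t = np.clip(t + rng.normal(0.0, config.mutation_sd_dose, size=t.size), 0.0, 100.0)
    if not np.any(w > 0):  # pragma: no cover - exp() is always positive
        w[0] = 1.0
    return Gene(weights=w, targets=t)


def _feasible(criteria: CriteriaVector, config: PlannerConfig) -> bool:
    if config.d95_constraint is None:
        return True
    return float(criteria.values[criteria.names.index("ptv_d95")]) >= config.d95_constraint


def evolve(phantom: Phantom, config: PlannerConfig,
           seed: int = 0) -> tuple[ParetoArchive, list[dict]]:
    """Seeded evolutionary loop; returns the archive and per-generation history."""
    if config.population < 2:
        raise ValueError("population must be at least 2")
    rng = np.random.default_rng(seed)
    archive = ParetoArchive()
    infeasible_pool: list[ArchiveEntry] = []
    history: list[dict] = []

    def offer(gene: Gene) -> None:
        try:
            plan = inner_solve(gene, phantom, config)
            crit = decision_criteria(plan, phantom, config)
        except (ValueError, FloatingPointError):
            return  # defective gene: log-free discard at this scale
        entry = ArchiveEntry(gene=gene, plan=plan, criteria=crit)
        if _feasible(crit, config):
            update_archive(archive, entry)
            if config.archive_cap is not None:
                _crowding_prune(archive, config.archive_cap)
        else:
            infeasible_pool.append(entry)  # kept for breeding, not archived

    for _ in range(config.population):
        offer(_random_gene(rng, config))

    for gen in range(config.generations):
        pool = archive.entries or infeasible_pool
        if not pool:
            for _ in range(config.population):
                offer(_random_gene(rng, config))
            pool = archive.entries or infeasible_pool
            if not pool:
                break
        for _ in range(config.population):
            i, j = rng.integers(0, len(pool), size=2)
            child = _mutate_crossover((pool[i].gene, pool[j].gene), rng, config)
            offer(child)
        history.append({
            "generation": gen,
            "archive_size": len(archive.entries),
            "hypervolume": hypervolume([e.criteria for e in archive.entries],
                                       config.hv_reference),
        })
    return archive, history
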