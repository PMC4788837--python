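"""Synthetic fixtures and file I/O.

Nothing in this package requires external downloads: a 2-D dose-influence
phantom stands in for patient anatomy and radiation transport, a parametric
Gompertz-Makeham hazard stands in for an actuarial life table (a CSV loader
accepts a real one), a seeded DVH library emulates the coverage-vs-sparing
trade-off spread a multiobjective planner produces, and two reference
patients (intermediate and high recurrence risk) anchor the patient-level
studies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from . import dose_metrics as dm
from .config import Calibration, PatientProfile
from .markov_qale import MAX_AGE, LifeTable
from .moea_planner import Phantom

__all__ = [
    "PhantomConfig", "GompertzMakehamParams", "make_phantom",
    "make_dvh_library", "make_life_table", "reference_patients",
    "write_calibration", "load_calibration", "provenance_hash",
]


class PhantomConfig(BaseModel):
    nx: int = Field(default=40, ge=10)
    ny: int = Field(default=40, ge=10)
    spacing_mm: float = Field(default=2.5, gt=0)
    ptv_radius_mm: float = Field(default=12.0, gt=0)
    rectum_offset_mm: float = 22.0  # centre offset below the PTV
    bladder_offset_mm: float = 24.0  # centre offset above the PTV
    oar_semi_axes_mm: tuple[float, float] = (14.0, 8.0)
    n_beams: int = Field(default=5, ge=1)
    beamlets_per_beam: int = Field(default=9, ge=1)
    beamlet_spacing_mm: float = Field(default=5.0, gt=0)
    attenuation_per_mm: float = Field(default=0.004, gt=0)
    penumbra_sigma_mm: float = Field(default=3.0, gt=0)


def make_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Build the 2-D phantom and its dose-influence matrix.

    Structures are a circular PTV at the grid centre with elliptical rectum
    (below) and bladder (above); each beamlet deposits exponential depth
    attenuation times a Gaussian lateral profile along its ray.  Fully
    deterministic for a given config.
    """
    cfg = config or PhantomConfig()
    extent_x = cfg.nx * cfg.spacing_mm
    extent_y = cfg.ny * cfg.spacing_mm
    cx, cy = extent_x / 2.0, extent_y / 2.0
    xs = (np.arange(cfg.nx) + 0.5) * cfg.spacing_mm
    ys = (np.arange(cfg.ny) + 0.5) * cfg.spacing_mm
    X, Y = np.meshgrid(xs, ys)

    def ellipse(cx_, cy_, ax_, ay_):
        return ((X - cx_) / ax_) ** 2 + ((Y - cy_) / ay_) ** 2 <= 1.0

    ptv = ellipse(cx, cy, cfg.ptv_radius_mm, cfg.ptv_radius_mm)
    rectum = ellipse(cx, cy - cfg.rectum_offset_mm, *cfg.oar_semi_axes_mm) & ~ptv
    bladder = ellipse(cx, cy + cfg.bladder_offset_mm, *cfg.oar_semi_axes_mm) & ~ptv
    normal = ~(ptv | rectum | bladder)
    for name, mask, centre_y in (("rectum", rectum, cy - cfg.rectum_offset_mm),
                                 ("bladder", bladder, cy + cfg.bladder_offset_mm)):
        if not mask.any():
            raise ValueError(f"structure {name} fell outside the grid")
        if not (0 < centre_y < extent_y):
            raise ValueError(f"structure {name} centre outside the grid")

    pos = np.column_stack([X.reshape(-1), Y.reshape(-1)])  # mm
    angles = np.arange(cfg.n_beams) * (2 * np.pi / cfg.n_beams)
    offsets = (np.arange(cfg.beamlets_per_beam)
               - (cfg.beamlets_per_beam - 1) / 2.0) * cfg.beamlet_spacing_mm
    cols = []
    for theta in angles:
        u = np.array([np.cos(theta), np.sin(theta)])   # beam direction
        v = np.array([-np.sin(theta), np.cos(theta)])  # lateral direction
        depth = (pos - np.array([cx, cy])) @ u
        depth = depth - depth.min()  # depth from the entry surface
        lateral0 = (pos - np.array([cx, cy])) @ v
        for off in offsets:
            lat = lateral0 - off
            dose = np.exp(-cfg.attenuation_per_mm * depth) \
                * np.exp(-0.5 * (lat / cfg.penumbra_sigma_mm) ** 2)
            cols.append(dose)
    influence = np.column_stack(cols)
    return Phantom(nx=cfg.nx, ny=cfg.ny, spacing_mm=cfg.spacing_mm,
                   masks={"ptv": ptv, "rectum": rectum,
                          "bladder": bladder, "normal": normal},
                   influence=influence)


def make_dvh_library(n: int, seed: int = 0, prescription: float = 76.0,
                     calib: Calibration | None = None) -> list[dm.PlanSummary]:
    """Seeded library of plan summaries spanning a coverage/sparing trade-off.

    Plans are ordered along a frontier parameter: pushing target coverage up
    (higher D95 and EUD, smaller cold spot) drags the rectum and bladder DVHs
    up with it, so sorting by rectum NTCP weakly reverse-sorts PTV EUD.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    calib = calib or Calibration()
    rng = np.random.default_rng(seed)
    plans = []
    alphas = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    n_vox = 400
    quantiles = (np.arange(n_vox) + 0.5) / n_vox  # deterministic spread
    for k, alpha in enumerate(alphas):
        # alpha = 0: conservative (cooler target, spared OARs); 1: aggressive
        ptv_mean = prescription + 0.8 + 1.2 * alpha
        ptv = rng.normal(ptv_mean, 0.8, size=n_vox).clip(min=0.0)
        rectum_scale = 0.80 + 0.15 * alpha
        rectum = prescription * rectum_scale * quantiles ** 0.35 \
            * rng.uniform(0.99, 1.01, size=n_vox)
        bladder_scale = 0.78 + 0.15 * alpha
        bladder = prescription * bladder_scale * quantiles ** 0.45 \
            * rng.uniform(0.99, 1.01, size=n_vox)
        dvhs = {
            "ptv": dm.build_cumulative_dvh(ptv, structure_name="ptv"),
            "rectum": dm.build_cumulative_dvh(rectum, structure_name="rectum"),
            "bladder": dm.build_cumulative_dvh(bladder, structure_name="bladder"),
        }
        hotspot_r = None if alpha < 0.5 else float(20.0 * (1.0 - alpha) + 2.0)
        plans.append(dm.PlanSummary(
            plan_id=f"plan_{k:03d}",
            dvhs=dvhs,
            eud_ptv=dm.equivalent_uniform_dose(ptv, dm.EudParams(a=calib.eud_exponent_ptv)),
            cold_spot_fraction=dm.cold_spot_fraction(ptv, prescription),
            d95=dm.dose_at_volume(dvhs["ptv"], 0.95),
            ntcp_rectum=dm.lkb_ntcp(dvhs["rectum"],
                                    dm.NtcpParams(**calib.ntcp["rectum"].model_dump())),
            ntcp_bladder=dm.lkb_ntcp(dvhs["bladder"],
                                     dm.NtcpParams(**calib.ntcp["bladder"].model_dump())),
            hotspot_distance_rectum=hotspot_r,
            hotspot_distance_bladder=None,
        ))
    return plans


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard h(age) = lam + alpha * exp(beta * age), per year."""

    lam: float = 5e-4
    alpha: float = 3e-5
    beta: float = 0.095

    def __post_init__(self) -> None:
        if self.lam < 0 or self.alpha < 0 or self.beta <= 0:
            raise ValueError("hazard parameters must be positive")


def make_life_table(params: GompertzMakehamParams | None = None,
                    start_age: int = 40) -> LifeTable:
    """Annual death probabilities from a Gompertz-Makeham hazard.

    Covers ``start_age`` .. 119 (the simulation horizon); probabilities are
    ``1 - exp(-h(age))`` capped at 1.
    """
    p = params or GompertzMakehamParams()
    ages = np.arange(start_age, MAX_AGE + 1)
    hazard = p.lam + p.alpha * np.exp(p.beta * ages)
    probs = np.minimum(1.0 - np.exp(-hazard), 1.0)
    return LifeTable(ages=ages, annual_death_prob=probs)


def reference_patients(age: int = 60) -> tuple[PatientProfile, PatientProfile]:
    """The two study patients: high risk (T2c, PSA 25, Gleason 8) and
    intermediate risk (T2a, PSA 15, Gleason 7)."""
    high = PatientProfile(age=age, t_stage="T2c", psa=25.0, gleason=8)
    intermediate = PatientProfile(age=age, t_stage="T2a", psa=15.0, gleason=7)
    return high, intermediate


def write_calibration(path: str | Path, calib: Calibration | None = None) -> Path:
    path = Path(path)
    (calib or Calibration()).to_json(path)
    return path


def load_calibration(path: str | Path) -> Calibration:
    return Calibration.from_json(Path(path))


def provenance_hash(obj) -> str:
    """Short deterministic hash of a JSON-serializable config, for output stamping."""
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
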