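"""Dosimetric summaries consumed by the outcome model.

Everything downstream of treatment planning speaks in a handful of scalar
summaries of the 3-D dose distribution: the cumulative dose-volume histogram
(DVH), D95, the cold-spot fraction of the target, the generalized equivalent
uniform dose (gEUD), the Lyman-Kutcher-Burman (LKB) normal tissue complication
probability (NTCP), and the proximity of hotspots to an organ at risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "DVH",
    "EudParams",
    "NtcpParams",
    "PlanSummary",
    "build_cumulative_dvh",
    "dose_at_volume",
    "cold_spot_fraction",
    "equivalent_uniform_dose",
    "lkb_ntcp",
    "hotspot_distance",
    "read_dvh_csv",
    "write_dvh_csv",
]


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram for a single structure.

    ``cumulative_fraction[i]`` is the fraction of the structure volume
    receiving at least ``bin_edges[i]`` Gy.
    """

    structure_name: str
    bin_edges: np.ndarray  # Gy, strictly increasing, starts at 0
    cumulative_fraction: np.ndarray  # unitless, non-increasing, starts at 1

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        frac = np.asarray(self.cumulative_fraction, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "cumulative_fraction", frac)
        if edges.ndim != 1 or frac.ndim != 1 or edges.size != frac.size:
            raise ValueError("bin_edges and cumulative_fraction must be 1-D and equal length")
        if edges.size == 0:
            raise ValueError("empty DVH")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if abs(frac[0] - 1.0) > 1e-9:
            raise ValueError("cumulative_fraction must start at 1.0")
        if np.any(np.diff(frac) > 1e-12):
            raise ValueError("cumulative_fraction must be non-increasing")
        if np.any(frac < -1e-12) or np.any(frac > 1 + 1e-12):
            raise ValueError("cumulative_fraction values must lie in [0, 1]")


@dataclass(frozen=True)
class EudParams:
    """Exponent of the generalized power-mean EUD; ``a`` must be nonzero."""

    a: float

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("EUD exponent a must be nonzero")


@dataclass(frozen=True)
class NtcpParams:
    """Lyman-Kutcher-Burman parameters: TD50 (Gy), slope m, volume exponent n."""

    td50: float
    m: float
    n: float

    def __post_init__(self) -> None:
        if self.td50 <= 0:
            raise ValueError("td50 must be positive")
        if self.m <= 0:
            raise ValueError("m must be positive")
        if not (0 < self.n <= 1):
            raise ValueError("n must lie in (0, 1]")


@dataclass
class PlanSummary:
    """The dosimetric evidence a single plan feeds to the outcome networks."""

    plan_id: str
    dvhs: dict[str, DVH] = field(default_factory=dict)
    eud_ptv: float = 0.0  # Gy
    cold_spot_fraction: float = 0.0
    d95: float = 0.0  # Gy
    ntcp_rectum: float = 0.0
    ntcp_bladder: float = 0.0
    hotspot_distance_rectum: float | None = None  # mm; None means no hotspot
    hotspot_distance_bladder: float | None = None

    def __post_init__(self) -> None:
        for name, p in (("cold_spot_fraction", self.cold_spot_fraction),
                        ("ntcp_rectum", self.ntcp_rectum),
                        ("ntcp_bladder", self.ntcp_bladder)):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


def build_cumulative_dvh(voxel_doses, bin_width: float = 0.1,
                         structure_name: str = "structure") -> DVH:
    """Bin voxel doses into a cumulative DVH.

    The fraction at bin edge ``b`` is the exact count fraction of voxels with
    dose >= b; bin edges run from 0 past the maximum dose in steps of
    ``bin_width``.
    """
    doses = np.asarray(voxel_doses, dtype=float)
    if doses.size == 0:
        raise ValueError("voxel_doses must be non-empty")
    if np.any(doses < 0):
        raise ValueError("voxel doses must be non-negative")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.floor(doses.max() / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    frac = (doses[None, :] >= edges[:, None]).mean(axis=1)
    return DVH(structure_name=structure_name, bin_edges=edges, cumulative_fraction=frac)


def dose_at_volume(dvh: DVH, fraction: float) -> float:
    """Largest binned dose D with cumulative_fraction(D) >= fraction.

    Bin-exact by convention (no interpolation); ``fraction=0.95`` gives D95.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    ok = dvh.cumulative_fraction >= fraction - 1e-12
    if not ok.any():
        return 0.0
    return float(dvh.bin_edges[np.nonzero(ok)[0][-1]])


def cold_spot_fraction(voxel_doses, prescription: float) -> float:
    """Fraction of target voxels receiving less than the prescription dose."""
    doses = np.asarray(voxel_doses, dtype=float)
    if doses.size == 0:
        raise ValueError("voxel_doses must be non-empty")
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    return float((doses < prescription).mean())


def equivalent_uniform_dose(voxel_doses, params: EudParams) -> float:
    """Generalized EUD: the power mean ``(mean(d^a))^(1/a)``.

    Large negative ``a`` makes cold voxels dominate (tumour convention);
    large positive ``a`` approaches the maximum dose (serial-organ convention).
    Computed in log space for numerical stability at large |a|.
    """
    doses = np.asarray(voxel_doses, dtype=float)
    if doses.size == 0:
        raise ValueError("voxel_doses must be non-empty")
    a = params.a
    if np.all(doses == 0):
        return 0.0
    if a < 0 and np.any(doses == 0):
        return 0.0  # a single zero voxel dominates a negative power mean
    with np.errstate(divide="ignore"):
        logd = np.log(doses)
    # log-sum-exp of a*log(d) avoids overflow for |a| ~ 40
    z = a * logd
    zmax = z.max()
    return float(np.exp((zmax + np.log(np.mean(np.exp(z - zmax)))) / a))


def _effective_uniform_dose(dvh: DVH, n: float) -> float:
    """LKB DVH reduction: gEUD with exponent a = 1/n over differential volumes."""
    frac = dvh.cumulative_fraction
    edges = dvh.bin_edges
    # differential volume in each bin, attributed to the bin's lower edge dose
    diff = np.empty_like(frac)
    diff[:-1] = frac[:-1] - frac[1:]
    diff[-1] = frac[-1]
    a = 1.0 / n  # n in (0, 1] so a >= 1; zero-dose bins contribute nothing
    mask = diff > 0
    if not mask.any():
        return 0.0
    d = edges[mask]
    v = diff[mask]
    v = v / v.sum()
    return float(np.sum(v * d**a) ** (1.0 / a))


def lkb_ntcp(dvh: DVH, params: NtcpParams) -> float:
    """Lyman-Kutcher-Burman NTCP.

    The DVH is reduced to an effective uniform dose D_eff via the volume-effect
    exponent n (power-mean with a = 1/n), then
    ``NTCP = Phi((D_eff - TD50) / (m * TD50))``.
    """
    d_eff = _effective_uniform_dose(dvh, params.n)
    t = (d_eff - params.td50) / (params.m * params.td50)
    return float(norm.cdf(t))


def hotspot_distance(dose_grid, oar_mask, threshold: float,
                     spacing_mm: float | tuple[float, ...] = 1.0) -> float | None:
    """Minimum Euclidean distance (mm) from the OAR to any voxel above threshold.

    Returns 0.0 if a hotspot voxel lies inside the OAR and None when no voxel
    exceeds the threshold.
    """
    dose = np.asarray(dose_grid, dtype=float)
    mask = np.asarray(oar_mask, dtype=bool)
    if dose.shape != mask.shape:
        raise ValueError("dose grid and OAR mask must share geometry")
    spacing = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (dose.ndim,))
    hot = dose > threshold
    if not hot.any():
        return None
    if (hot & mask).any():
        return 0.0
    hot_idx = np.argwhere(hot) * spacing
    oar_idx = np.argwhere(mask) * spacing
    # pairwise distances; grids here are small (phantom scale)
    d2 = ((hot_idx[:, None, :] - oar_idx[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def read_dvh_csv(path, structure_name: str | None = None) -> DVH:
    """Read a DVH from CSV with header ``dose_gy,cum_fraction``."""
    import pandas as pd

    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["dose_gy", "cum_fraction"]:
        raise ValueError("DVH CSV must have header dose_gy,cum_fraction")
    name = structure_name or str(getattr(path, "stem", path))
    return DVH(structure_name=name,
               bin_edges=df["dose_gy"].to_numpy(float),
               cumulative_fraction=df["cum_fraction"].to_numpy(float))


def write_dvh_csv(dvh: DVH, path) -> None:
    import pandas as pd

    pd.DataFrame({"dose_gy": dvh.bin_edges,
                  "cum_fraction": dvh.cumulative_fraction}).to_csv(path, index=False)
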