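"""Capture-pattern cooperativity and a CNT wetting model of seeded nucleation.

Seeded growth of tile lattices is templated by *capture* strands on the
seed's lateral surface.  A capture **pair** (capture 0 + capture 1 at the
same site) enables double-domain tile binding; the spatial arrangement of
pairs sets the nucleation mode: fully cooperative (all sites are pairs),
partially cooperative (some pairs) or non-cooperative (no pairs).  Vertical
(z-axis) continuity of pairs is what makes a partial pattern an effective
seed.

The thermodynamics are a two-dimensional classical-nucleation-theory (CNT)
stand-in, appropriate for planar tile-lattice growth: a disc nucleus with
edge free energy Γ (per unit length) in a supersaturated tile bath,

    ΔG*_homo(T) = π Γ² / Δg(T),      Δg(T) = Δh (T_m − T) / T_m,

with T absolute.  Heterogeneous nucleation on the seed surface reduces the
barrier by the wetting shape factor f(ψ) = (ψ − sin ψ cos ψ)/π of the
contact angle ψ (2D cap geometry): f→0 for perfect wetting, f=1 for ψ=180°
(no surface advantage).  Rates follow Arrhenius forms in reduced units
(k=1).  These are standard textbook CNT forms, adopted here as the model of
the seeded-tile system and constrained to the qualitative behaviour the
experiments document: the seed/bulk rate ratio R = N_hetero/N_homo grows
towards the melting temperature, and stronger wetting elevates R across the
whole temperature range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CELSIUS_OFFSET = 273.15

FULLY = "fully"
PARTIALLY = "partially"
NON_COOPERATIVE = "non_cooperative"

#: default mapping from nucleation mode to an effective contact angle (deg).
#: The values are arbitrary but ordered: full cooperativity wets strongly,
#: z-continuous partial patterns wet moderately, everything else not at all.
DEFAULT_CONTACT_ANGLES = {
    FULLY: 30.0,
    PARTIALLY: 90.0,  # only when pairs are z-continuous (max_z_run >= 2)
    NON_COOPERATIVE: 180.0,
}


# ---------------------------------------------------------------------------
# capture patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapturePattern:
    """Boolean capture flags on a (z, x) site grid of one seed face."""

    has_capture0: np.ndarray  # (nz, nx) bool
    has_capture1: np.ndarray  # (nz, nx) bool

    def __post_init__(self) -> None:
        c0 = np.atleast_2d(np.asarray(self.has_capture0, bool))
        c1 = np.atleast_2d(np.asarray(self.has_capture1, bool))
        if c0.shape != c1.shape:
            raise ValueError("capture flag grids must share a shape")
        if c0.size == 0:
            raise ValueError("capture grid must be at least 1x1")
        object.__setattr__(self, "has_capture0", c0)
        object.__setattr__(self, "has_capture1", c1)

    @property
    def pairs(self) -> np.ndarray:
        """A site hosts a capture pair iff both flags are set."""
        return self.has_capture0 & self.has_capture1


@dataclass(frozen=True)
class CaptureClassification:
    mode: str
    pair_count: int
    max_z_run: int


def _max_run(column: np.ndarray) -> int:
    best = run = 0
    for v in column:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def classify_capture_pattern(pattern: CapturePattern) -> CaptureClassification:
    """Classify a capture pattern into its nucleation mode.

    ``fully`` if every site is a pair, ``non_cooperative`` if no site is,
    ``partially`` otherwise.  ``max_z_run`` is the longest vertical
    (z-direction) run of pair sites in any column — the continuity measure
    that separates effective partial seeds from ineffective ones.
    """
    pairs = pattern.pairs
    n_pairs = int(pairs.sum())
    if n_pairs == pairs.size:
        mode = FULLY
    elif n_pairs == 0:
        mode = NON_COOPERATIVE
    else:
        mode = PARTIALLY
    max_run = max((_max_run(pairs[:, j]) for j in range(pairs.shape[1])), default=0)
    return CaptureClassification(mode=mode, pair_count=n_pairs, max_z_run=max_run)


def contact_angle_for_pattern(
    cls: CaptureClassification, mapping: Optional[dict] = None
) -> float:
    """Effective contact angle ψ (deg) for a classified capture pattern.

    z-discontinuous partial patterns (max_z_run == 1) seed no better than
    non-cooperative ones and map to ψ = 180°.
    """
    mapping = DEFAULT_CONTACT_ANGLES if mapping is None else mapping
    if cls.mode == FULLY:
        return mapping[FULLY]
    if cls.mode == PARTIALLY and cls.max_z_run >= 2:
        return mapping[PARTIALLY]
    return mapping[NON_COOPERATIVE]


# ---------------------------------------------------------------------------
# CNT thermodynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TileThermo:
    """Reduced-unit tile thermodynamics (k = 1, temperatures absolute inside).

    Defaults place the model in the regime of the seeded square-lattice
    system: bulk nucleation effectively suppressed a few degrees below the
    melting temperature but active ~10 °C lower.
    """

    T_m_C: float = 45.0
    delta_h: float = 200.0  # per-tile condensation enthalpy
    gamma: float = 50.0  # edge free energy per unit length
    A_homo: float = 5.0e4  # kinetic prefactors
    A_het: float = 5.0e4
    site_density_ratio: float = 1.0e-3  # seed-site vs bulk site density

    def __post_init__(self) -> None:
        if self.T_m_C + CELSIUS_OFFSET <= 0:
            raise ValueError("melting temperature must be positive (absolute)")
        if self.delta_h <= 0 or self.gamma <= 0:
            raise ValueError("delta_h and gamma must be > 0")

    @property
    def T_m_K(self) -> float:
        return self.T_m_C + CELSIUS_OFFSET


@dataclass(frozen=True)
class WettingSpec:
    """Heterogeneous-nucleation wetting: a contact angle ψ or a direct factor f."""

    contact_angle_deg: Optional[float] = None
    factor: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.contact_angle_deg is None) == (self.factor is None):
            raise ValueError("supply exactly one of contact_angle_deg / factor")
        if self.factor is not None and not 0.0 < self.factor <= 1.0:
            raise ValueError("wetting factor must lie in (0, 1]")

    @property
    def f(self) -> float:
        if self.factor is not None:
            return self.factor
        return wetting_factor(self.contact_angle_deg)


def wetting_factor(psi_deg: float) -> float:
    """2D heterogeneous barrier shape factor f(ψ) = (ψ − sinψ·cosψ)/π.

    Monotone increasing on (0°, 180°]; f(90°)=1/2, f(180°)=1, f→0 as ψ→0.
    """
    if not 0.0 < psi_deg <= 180.0:
        raise ValueError("contact angle must lie in (0, 180] degrees")
    psi = math.radians(psi_deg)
    return (psi - math.sin(psi) * math.cos(psi)) / math.pi


def barrier_homo(T_C: float, thermo: TileThermo) -> float:
    """Homogeneous 2D disc-nucleus barrier ΔG* = πΓ²/Δg(T); inf at/above T_m."""
    T = T_C + CELSIUS_OFFSET
    if T <= 0:
        raise ValueError("temperature must be positive on the absolute scale")
    if T >= thermo.T_m_K:
        return math.inf
    delta_g = thermo.delta_h * (thermo.T_m_K - T) / thermo.T_m_K
    return math.pi * thermo.gamma**2 / delta_g


@dataclass(frozen=True)
class NucleationCurves:
    T_C: np.ndarray
    N_homo: np.ndarray
    N_hetero: np.ndarray
    R: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "T_C": self.T_C,
                "N_homo": self.N_homo,
                "N_hetero": self.N_hetero,
                "R": self.R,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.semilogy(self.T_C, self.N_homo, label="N_homo")
        ax.semilogy(self.T_C, self.N_hetero, label="N_hetero")
        ax2 = ax.twinx()
        ax2.semilogy(self.T_C, self.R, "k--", label="R")
        ax.set_xlabel("T (°C)")
        ax.set_ylabel("nucleation rate (reduced)")
        ax2.set_ylabel("R = N_hetero / N_homo")
        ax.legend(loc="lower left")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def nucleation_rates(
    T_grid_C, thermo: TileThermo, wetting: WettingSpec
) -> NucleationCurves:
    """Homogeneous/heterogeneous rates and their ratio on a temperature grid.

    N_homo = A_homo·exp(−ΔG*/kT);
    N_hetero = A_het·site_density_ratio·exp(−f·ΔG*/kT), per seed site.
    """
    T_grid_C = np.asarray(T_grid_C, dtype=float)
    if T_grid_C.size == 0:
        raise ValueError("temperature grid must not be empty")
    f = wetting.f
    T_K = T_grid_C + CELSIUS_OFFSET
    barriers = np.array([barrier_homo(t, thermo) for t in T_grid_C])
    with np.errstate(over="ignore"):
        N_homo = thermo.A_homo * np.exp(-barriers / T_K)
        N_het = thermo.A_het * thermo.site_density_ratio * np.exp(-f * barriers / T_K)
    R = np.full_like(N_homo, np.nan)
    nz = N_homo > 0
    R[nz] = N_het[nz] / N_homo[nz]
    return NucleationCurves(T_C=T_grid_C, N_homo=N_homo, N_hetero=N_het, R=R)
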