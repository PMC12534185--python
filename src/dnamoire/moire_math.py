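"""Closed-form moiré relations and gradient orientation-field models.

Two identical lattices of constant ``a_sub`` overlaid at a twist ``θ``
produce a moiré superlattice of periodicity

    p_M = a_sub / (2 sin(θ/2)),

the exact (non-small-angle) relation used throughout.  In reciprocal space
the moiré wavevectors are the pairwise differences between the first-order
stars of the two layers; for identical layers the smallest nonzero moiré
wavevector has magnitude ``2|g| sin(θ/2)``, the reciprocal of the moiré
*interplanar spacing* (which equals ``p_M`` for square lattices and
``p_M·√3/2`` for hexagonal stars).

A gradient superlattice has a local twist that varies with azimuth around
the seed: linear interpolation from the tilted-face twist ``θ_a`` to the
parallel-face twist ``θ_b`` along the gradual direction, with a single sharp
discontinuity at a boundary azimuth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .sublattice import ReciprocalPeaks, rotation_matrix

#: sentinel for an untwisted stack (infinite moiré period)
INFINITE_PERIOD = math.inf


@dataclass(frozen=True)
class MoireResult:
    a_sub_nm: float
    theta_deg: float
    p_M_nm: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "a_sub_nm": self.a_sub_nm,
                "theta_deg": self.theta_deg,
                "p_M_nm": None if math.isinf(self.p_M_nm) else self.p_M_nm,
            }
        )


def moire_period(a_sub_nm: float, theta_deg: float):
    """Moiré periodicity p_M = a/(2 sin(θ/2)), nm; θ=0 → inf sentinel."""
    if a_sub_nm <= 0:
        raise ValueError("a_sub must be > 0")
    if not 0.0 <= theta_deg <= 180.0:
        raise ValueError("theta must lie in [0, 180] degrees")
    if theta_deg == 0.0:
        return INFINITE_PERIOD
    return a_sub_nm / (2.0 * math.sin(math.radians(theta_deg) / 2.0))


def small_angle_period(a_sub_nm: float, theta_deg: float):
    """Small-angle helper p ≈ a/θ; documented approximation only."""
    if theta_deg == 0.0:
        return INFINITE_PERIOD
    return a_sub_nm / math.radians(theta_deg)


def twist_from_period(a_sub_nm: float, p_M_nm: float) -> float:
    """Invert the moiré relation: θ = 2 arcsin(a/(2 p_M)), degrees."""
    if a_sub_nm <= 0 or p_M_nm <= 0:
        raise ValueError("a_sub and p_M must be > 0")
    x = a_sub_nm / (2.0 * p_M_nm)
    if x > 1.0:
        raise ValueError("p_M < a_sub/2 has no real twist solution")
    return math.degrees(2.0 * math.asin(x))


def moire_result(a_sub_nm: float, theta_deg: float) -> MoireResult:
    return MoireResult(a_sub_nm, theta_deg, moire_period(a_sub_nm, theta_deg))


# ---------------------------------------------------------------------------
# reciprocal-space moiré vectors
# ---------------------------------------------------------------------------

def _star(peaks: ReciprocalPeaks) -> np.ndarray:
    reps = np.asarray(peaks.g_vectors, float)
    return np.vstack([reps, -reps])


def moire_reciprocal(
    layer1: ReciprocalPeaks, layer2: ReciprocalPeaks, theta_deg: float
) -> np.ndarray:
    """All pairwise moiré wavevectors g1 − R(θ)·g2 between first-order stars.

    Layer 2's star is rotated by θ (counter-clockwise positive).  For
    identical layers the minimum nonzero magnitude equals 2|g| sin(θ/2).
    """
    g1 = _star(layer1)
    g2 = _star(layer2) @ rotation_matrix(theta_deg).T
    diff = g1[:, None, :] - g2[None, :, :]
    return diff.reshape(-1, 2)


def min_moire_wavevector(
    layer1: ReciprocalPeaks, layer2: ReciprocalPeaks, theta_deg: float
) -> float:
    """Smallest moiré wavevector magnitude, nm⁻¹.

    Returns 0 when the difference set contains the zero vector (coincident
    stars, i.e. no moiré); otherwise the smallest nonzero |g_m|.
    """
    gm = moire_reciprocal(layer1, layer2, theta_deg)
    mags = np.hypot(gm[:, 0], gm[:, 1])
    scale = max(np.hypot(*g) for g in np.asarray(layer1.g_vectors))
    if np.any(mags <= 1e-9 * scale):
        return 0.0
    return float(mags.min())


# ---------------------------------------------------------------------------
# gradient orientation fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationFieldSpec:
    """Azimuthal model of the local second-layer twist around a gradient seed.

    The field is continuous everywhere except at ``boundary_azimuth_deg``:
    starting at the tilted-face twist ``theta_a_deg`` just past the boundary,
    it interpolates linearly (in azimuth) down to the parallel-face twist
    ``theta_b_deg`` over the full gradual sector, running clockwise or
    counter-clockwise.
    """

    theta_b_deg: float
    theta_a_deg: float
    boundary_azimuth_deg: float = 0.0
    gradual_direction: str = "cw"

    def __post_init__(self) -> None:
        if self.gradual_direction not in ("cw", "ccw"):
            raise ValueError("gradual_direction must be 'cw' or 'ccw'")


def gradient_orientation_field(
    spec: OrientationFieldSpec, azimuth_deg
) -> np.ndarray:
    """Local twist Δθ(φ) (deg) on an azimuth grid (deg, ccw positive).

    Exactly at the boundary azimuth the tilted-face value ``theta_a`` is
    returned; approaching the boundary from the gradual side the field tends
    to ``theta_b``, producing one jump of magnitude |θ_a − θ_b|.
    """
    az = np.asarray(azimuth_deg, dtype=float)
    s = -1.0 if spec.gradual_direction == "cw" else 1.0
    frac = (s * (az - spec.boundary_azimuth_deg)) % 360.0 / 360.0
    return spec.theta_a_deg + (spec.theta_b_deg - spec.theta_a_deg) * frac


def local_period_map(field_deg, a_sub_nm: float) -> np.ndarray:
    """Pointwise p_M of a local-twist field; inf sentinel where twist is 0."""
    field = np.asarray(field_deg, dtype=float)
    if np.any(field < 0) or np.any(field > 180):
        raise ValueError("field values must lie in [0, 180] degrees")
    out = np.full(field.shape, INFINITE_PERIOD)
    nz = field > 0
    out[nz] = a_sub_nm / (2.0 * np.sin(np.deg2rad(field[nz]) / 2.0))
    return out
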