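"""Square, kagome and honeycomb SST sublattices and their reciprocal stars.

The three tile-lattice symmetries are described by a Bravais lattice plus a
fractional basis:

* square — square Bravais, one site per cell;
* kagome — hexagonal Bravais of constant ``a_k`` with the three-site kagome
  basis (corner-sharing triangles).  Equivalently this is the underlying fine
  triangular net of spacing ``a_k/2`` with one of every four sites removed,
  which is how the tile lattice arises from the square net after strain
  relief (``a_k = 2 a_s``);
* honeycomb — hexagonal Bravais with a two-site basis.

Lattice constants carry a hydration preset: constants measured under cryo
conditions versus on dried grids (drying shrinks the lattices).

Reciprocal-space conventions are crystallographic without the 2π factor,
``|g| = 1/d`` for interplanar spacing ``d``.  For hexagonal stars the
first-order spacing relates to the lattice constant as ``d = a·√3/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: printed lattice constants (nm) per hydration state
LATTICE_CONSTANTS_NM = {
    "cryo": {"square": 2.8, "kagome": 5.4, "honeycomb": 4.4},
    "dried": {"square": 2.2, "kagome": 4.4, "honeycomb": 3.5},
}

SYMMETRIES = ("square", "kagome", "honeycomb")

#: ratio of first-order interplanar spacing to lattice constant
D_OVER_A = {"square": 1.0, "kagome": np.sqrt(3) / 2, "honeycomb": np.sqrt(3) / 2}

#: fundamental zone (deg) of the first-order reciprocal star, used when
#: folding orientations/twists
FOLD_DEG = {"square": 90.0, "kagome": 60.0, "honeycomb": 60.0}

_EPS = 1e-9


@dataclass(frozen=True)
class LatticeSpec:
    symmetry: str
    a_sub_nm: float
    hydration: Optional[str] = None

    def __post_init__(self) -> None:
        if self.symmetry not in SYMMETRIES:
            raise ValueError(f"unknown symmetry {self.symmetry!r}")
        if self.a_sub_nm <= 0:
            raise ValueError("a_sub must be > 0")


def lattice_spec(symmetry: str, hydration: str = "dried") -> LatticeSpec:
    """Named preset carrying the measured lattice constant."""
    if hydration not in LATTICE_CONSTANTS_NM:
        raise ValueError(f"unknown hydration preset {hydration!r}")
    return LatticeSpec(
        symmetry=symmetry,
        a_sub_nm=LATTICE_CONSTANTS_NM[hydration][symmetry],
        hydration=hydration,
    )


@dataclass(frozen=True)
class PointSet:
    """2D lattice points of one layer, in nm."""

    coords: np.ndarray  # (n, 2)
    layer_id: int = 0
    orientation_deg: float = 0.0
    origin: tuple = (0.0, 0.0)

    def __len__(self) -> int:
        return len(self.coords)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "x_nm": self.coords[:, 0],
                "y_nm": self.coords[:, 1],
                "layer_id": self.layer_id,
            }
        ).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "PointSet":
        df = pd.read_csv(path)
        layer = int(df["layer_id"].iloc[0]) if len(df) else 0
        return PointSet(coords=df[["x_nm", "y_nm"]].to_numpy(float), layer_id=layer)


@dataclass(frozen=True)
class ReciprocalPeaks:
    """First-order reciprocal families (one representative per ±g pair)."""

    g_vectors: np.ndarray  # (m, 2) nm^-1, azimuths folded into [0, 180)
    d_spacings_nm: np.ndarray  # (m,)
    interplane_angles_deg: np.ndarray  # sorted pairwise angles between families
    weights: np.ndarray  # |structure factor| per family


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def bravais_and_basis(spec: LatticeSpec):
    """Lattice-vector matrix (columns a1, a2; nm) and fractional basis."""
    a = spec.a_sub_nm
    if spec.symmetry == "square":
        A = a * np.eye(2)
        basis = np.array([[0.0, 0.0]])
    else:
        A = a * np.array([[1.0, 0.5], [0.0, np.sqrt(3) / 2]])
        if spec.symmetry == "honeycomb":
            basis = np.array([[0.0, 0.0], [1 / 3, 1 / 3]])
        else:  # kagome: corner-sharing triangles
            basis = np.array([[0.0, 0.0], [0.5, 0.0], [0.0, 0.5]])
    return A, basis


def rotation_matrix(angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def _region_bounds(region) -> tuple:
    region = tuple(region)
    if len(region) == 2:
        w, h = region
        return -w / 2, w / 2, -h / 2, h / 2
    if len(region) == 4:
        return region
    raise ValueError("region must be (W, H) or (xmin, xmax, ymin, ymax)")


def generate_lattice(
    spec: LatticeSpec,
    region,
    orientation_deg: float = 0.0,
    origin=(0.0, 0.0),
    layer_id: int = 0,
) -> PointSet:
    """All lattice+basis points of the rotated, translated lattice in a region.

    ``region`` is either ``(W, H)`` (centred on the coordinate origin) or an
    explicit ``(xmin, xmax, ymin, ymax)`` box, in nm.  Boundaries are closed:
    points numerically on the edge are included.  Deterministic.
    """
    xmin, xmax, ymin, ymax = _region_bounds(region)
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("region area must be > 0")
    A, basis = bravais_and_basis(spec)
    M = rotation_matrix(orientation_deg) @ A
    origin = np.asarray(origin, float)

    # integer ranges covering the region: map corners through M^-1
    corners = np.array(
        [[xmin, ymin], [xmin, ymax], [xmax, ymin], [xmax, ymax]]
    ) - origin
    frac = corners @ np.linalg.inv(M).T
    n1_lo, n2_lo = np.floor(frac.min(axis=0)).astype(int) - 2
    n1_hi, n2_hi = np.ceil(frac.max(axis=0)).astype(int) + 2
    n1, n2 = np.meshgrid(
        np.arange(n1_lo, n1_hi + 1), np.arange(n2_lo, n2_hi + 1), indexing="ij"
    )
    cells = np.stack([n1.ravel(), n2.ravel()], axis=1).astype(float)
    pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 2) @ M.T + origin

    eps = _EPS * spec.a_sub_nm
    keep = (
        (pts[:, 0] >= xmin - eps)
        & (pts[:, 0] <= xmax + eps)
        & (pts[:, 1] >= ymin - eps)
        & (pts[:, 1] <= ymax + eps)
    )
    return PointSet(
        coords=pts[keep],
        layer_id=layer_id,
        orientation_deg=orientation_deg,
        origin=tuple(origin),
    )


def point_density(spec: LatticeSpec) -> float:
    """Sites per nm²: basis size over unit-cell area."""
    A, basis = bravais_and_basis(spec)
    return len(basis) / abs(np.linalg.det(A))


# ---------------------------------------------------------------------------
# reciprocal space
# ---------------------------------------------------------------------------

def reciprocal_shells(spec: LatticeSpec, max_index: int = 3):
    """Reciprocal shells with non-vanishing structure factor.

    Returns a list of ``(g_array, |F|)`` sorted by |g|; each ``g_array``
    holds the full star of that shell (all ±g members), in nm⁻¹.
    """
    A, basis = bravais_and_basis(spec)
    B = np.linalg.inv(A).T  # columns b1, b2 with a_i·b_j = δ_ij
    shells = {}
    for h in range(-max_index, max_index + 1):
        for k in range(-max_index, max_index + 1):
            if h == 0 and k == 0:
                continue
            F = np.sum(np.exp(2j * np.pi * (h * basis[:, 0] + k * basis[:, 1])))
            if abs(F) < 1e-9:
                continue
            g = B @ np.array([h, k], float)
            key = round(float(np.hypot(*g)), 9)
            shells.setdefault(key, ([], []))
            shells[key][0].append(g)
            shells[key][1].append(abs(F))
    out = []
    for key in sorted(shells):
        gs, Fs = shells[key]
        out.append((np.array(gs), float(np.mean(Fs))))
    return out


def reciprocal_basis(spec: LatticeSpec) -> ReciprocalPeaks:
    """First-order g-vector families with d-spacings and mutual angles.

    Families merge conjugate pairs (±g) and are represented with azimuth in
    [0°, 180°).  Square lattices give two families 90° apart; hexagonal
    stars (kagome, honeycomb) give three families at mutual 60°/120°.
    """
    star, weight = reciprocal_shells(spec, max_index=2)[0]
    reps = []
    for g in star:
        az = np.rad2deg(np.arctan2(g[1], g[0])) % 360.0
        if az >= 180.0 - 1e-9:
            g = -g
            az -= 180.0
        if not any(np.allclose(g, r, atol=1e-12) for r in reps):
            reps.append(g)
    reps = np.array(sorted(reps, key=lambda v: np.arctan2(v[1], v[0]) % np.pi))
    mags = np.hypot(reps[:, 0], reps[:, 1])
    az = np.rad2deg(np.arctan2(reps[:, 1], reps[:, 0])) % 180.0
    angles = []
    for i in range(len(az)):
        for j in range(i + 1, len(az)):
            angles.append(abs(az[i] - az[j]))
    angles = np.array(sorted(angles))
    return ReciprocalPeaks(
        g_vectors=reps,
        d_spacings_nm=1.0 / mags,
        interplane_angles_deg=angles,
        weights=np.full(len(reps), weight),
    )


def first_order_star(spec: LatticeSpec) -> np.ndarray:
    """Full first-order star (all ±g members), nm⁻¹."""
    return reciprocal_shells(spec, max_index=2)[0][0]


# ---------------------------------------------------------------------------
# kagome from square
# ---------------------------------------------------------------------------

VOID_PATTERNS = {"2x2_one_removed": 0.25, "none": 0.0}


def kagome_void_fraction(void_pattern: str = "2x2_one_removed") -> float:
    """Fraction of fine-net sites removed by the chosen periodic void pattern."""
    if void_pattern not in VOID_PATTERNS:
        raise ValueError(f"unknown void pattern {void_pattern!r}")
    return VOID_PATTERNS[void_pattern]


def kagome_from_square(
    square_spec: LatticeSpec, void_pattern: str = "2x2_one_removed"
) -> LatticeSpec:
    """Derive the kagome tile lattice from its parent square net.

    The kagome lattice is the loosely packed fine net with one of every four
    sites (one per 2×2 block) removed, after the square→kagome strain-relief
    shear; the kagome constant doubles the parent square constant
    (``a_k = 2 a_s``, e.g. dried 2.2 nm → 4.4 nm).  With an empty void
    pattern the site set stays that of the parent square lattice.
    """
    if square_spec.symmetry != "square":
        raise ValueError("kagome_from_square expects a square input spec")
    frac = kagome_void_fraction(void_pattern)
    if frac == 0.0:
        return square_spec
    return LatticeSpec(
        symmetry="kagome",
        a_sub_nm=2.0 * square_spec.a_sub_nm,
        hydration=square_spec.hydration,
    )
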