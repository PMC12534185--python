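"""Geometric model of twisted DNA origami seeds.

A seed is a hollow multi-helix DNA origami bundle whose axis (z) carries an
ordered sequence of functional segments.  *Growth* segments (Z1, Z3, Z5)
template the nucleation of one 2D single-stranded-tile (SST) sublattice each;
*spacer/twister* segments (Z2, Z4) set the interlayer gap and imprint a
right-handed twist between consecutive sublattices.  Compiling a seed design
therefore yields the z-interval and in-plane orientation of every templated
layer — the stacking registry of the resulting moiré superlattice.

Units: lengths in nm, angles in degrees (right-handed about +z positive),
axial rise in nm per base pair (canonical B-DNA: 0.34 nm/bp).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

#: canonical B-DNA axial rise, nm per base pair
DEFAULT_RISE_NM_PER_BP = 0.34

#: centre-to-centre interhelical pitch of packed origami helices, nm
HELIX_PITCH_NM = 2.6

#: calibration constants for the twist imprinted per spacer base pair.
#: These come from coarse-grained mechanical relaxation of the two bundle
#: architectures (square-array spacer: 3.8° over 32 bp; honeycomb-array
#: spacer: 1.2° over 36 bp); they are inputs here, not predictions.
TWIST_RATE_DEG_PER_BP = {
    "square": 3.8 / 32.0,
    "honeycomb": 1.2 / 36.0,
}

GROWTH = "growth"
SPACER = "spacer_twister"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientTaper:
    """Trapezoidal cross-section taper of a gradient seed.

    The tilted growth face contributes an additional in-plane rotation
    ``delta_theta_deg`` on top of the spacer twist, so the two opposite
    faces of one growth segment template different local twists.
    """

    delta_theta_deg: float
    tilted_face: str = "a"

    def __post_init__(self) -> None:
        if self.delta_theta_deg < 0:
            raise ValueError("taper delta_theta_deg must be >= 0")
        if self.tilted_face not in ("a", "b"):
            raise ValueError("tilted_face must be 'a' or 'b'")


@dataclass(frozen=True)
class CrossSectionSpec:
    """Hollow rim/pore cross-section of a seed bundle, counted in helices."""

    array_type: str  # 'square' | 'honeycomb'
    rim_cols: int
    rim_rows: int
    pore_cols: int
    pore_rows: int
    taper: Optional[GradientTaper] = None

    def __post_init__(self) -> None:
        if self.array_type not in ("square", "honeycomb"):
            raise ValueError(f"unknown array_type {self.array_type!r}")
        for name in ("rim_cols", "rim_rows", "pore_cols", "pore_rows"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pore_cols > self.rim_cols or self.pore_rows > self.rim_rows:
            raise ValueError("pore cannot be larger than rim")


@dataclass(frozen=True)
class HelixLayout:
    """Helix centre coordinates (nm) of one cross-section."""

    centres: np.ndarray  # (n, 2)
    helix_count: int
    degenerate: bool = False


@dataclass(frozen=True)
class SeedSegment:
    id: str
    role: str  # GROWTH or SPACER
    bp: int
    twist_deg: float = 0.0
    captures: Optional[object] = None  # CapturePattern, see dnamoire.nucleation

    def __post_init__(self) -> None:
        if self.role not in (GROWTH, SPACER):
            raise ValueError(f"unknown segment role {self.role!r}")
        if self.bp < 0:
            raise ValueError("segment bp must be >= 0")
        # growth segments relax to the untwisted sublattice: all imprinted
        # twist is carried by spacer/twister segments
        if self.role == GROWTH and self.twist_deg != 0.0:
            raise ValueError("growth segments carry no twist after relaxation")


@dataclass(frozen=True)
class SeedDesign:
    name: str
    cross_section: CrossSectionSpec
    segments: tuple
    rise_nm_per_bp: float = DEFAULT_RISE_NM_PER_BP
    twist_rate_deg_per_bp: Optional[float] = None
    sublattice_symmetry: Optional[str] = None  # symmetry of templated layers

    def __post_init__(self) -> None:
        if self.rise_nm_per_bp <= 0:
            raise ValueError("rise must be > 0")
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        roles = [s.role for s in segs]
        if roles:
            expected = [GROWTH if i % 2 == 0 else SPACER for i in range(len(roles))]
            if roles != expected or roles[-1] != GROWTH:
                raise ValueError(
                    "segments must alternate growth/spacer_twister, "
                    "starting and ending with a growth segment"
                )

    @property
    def symmetry(self) -> str:
        if self.sublattice_symmetry is not None:
            return self.sublattice_symmetry
        return "square" if self.cross_section.array_type == "square" else "honeycomb"


@dataclass(frozen=True)
class StackLayer:
    layer_index: int  # 1-based
    z_lo_nm: float
    z_hi_nm: float
    orientation_deg: float
    symmetry: str


@dataclass(frozen=True)
class StackSpec:
    layers: tuple

    def to_json(self) -> str:
        return json.dumps(
            {
                "layers": [
                    {
                        "layer_index": l.layer_index,
                        "z_lo_nm": round(l.z_lo_nm, 4),
                        "z_hi_nm": round(l.z_hi_nm, 4),
                        "orientation_deg": round(l.orientation_deg, 4),
                        "symmetry": l.symmetry,
                    }
                    for l in self.layers
                ]
            },
            indent=2,
        )

    @property
    def orientations_deg(self) -> list:
        return [l.orientation_deg for l in self.layers]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_cross_section(spec: CrossSectionSpec) -> HelixLayout:
    """Lay out helix centres of a hollow rim/pore bundle cross-section.

    Square arrays sit on a square grid of pitch ``HELIX_PITCH_NM``;
    honeycomb arrays on a staggered packing with the same nearest-neighbour
    pitch.  The pore block is removed from the centre of the rim, so
    ``helix_count == rim_cols*rim_rows - pore_cols*pore_rows``.
    """
    p = HELIX_PITCH_NM
    rows, cols = spec.rim_rows, spec.rim_cols
    r0 = (spec.rim_rows - spec.pore_rows) // 2
    c0 = (spec.rim_cols - spec.pore_cols) // 2
    pore = {
        (r, c)
        for r in range(r0, r0 + spec.pore_rows)
        for c in range(c0, c0 + spec.pore_cols)
    }
    pts = []
    for r in range(rows):
        for c in range(cols):
            if (r, c) in pore:
                continue
            if spec.array_type == "square":
                pts.append((c * p, r * p))
            else:
                # staggered honeycomb packing, nearest-neighbour distance p
                x = c * p * np.sqrt(3) / 2.0
                y = r * p * 1.5 + 0.5 * p * ((r + c) % 2)
                pts.append((x, y))
    centres = np.asarray(pts, dtype=float).reshape(-1, 2)
    if centres.size:
        centres = centres - centres.mean(axis=0)
    n = len(centres)
    return HelixLayout(centres=centres, helix_count=n, degenerate=(n == 0))


def segment_height(bp: int, rise_nm_per_bp: float = DEFAULT_RISE_NM_PER_BP) -> float:
    """Axial height of ``bp`` base pairs, nm (rounded to 0.1 nm)."""
    if bp < 0:
        raise ValueError("bp must be >= 0")
    if rise_nm_per_bp <= 0:
        raise ValueError("rise must be > 0")
    return round(bp * rise_nm_per_bp, 1)


def segment_twist(bp: int, twist_rate_deg_per_bp: float) -> float:
    """Right-handed twist (deg) accumulated over ``bp`` spacer base pairs."""
    if bp < 0:
        raise ValueError("bp must be >= 0")
    return bp * twist_rate_deg_per_bp


def compile_stack(seed: SeedDesign) -> StackSpec:
    """Compile a seed design into per-layer z-intervals and orientations.

    Each growth segment becomes one layer.  A layer starts at the cumulative
    height of all preceding segments; its in-plane orientation is the sum of
    the twists of all preceding spacer segments (layer 1 at 0°).
    """
    layers = []
    z = 0.0
    orientation = 0.0
    index = 0
    for seg in seed.segments:
        h = seg.bp * seed.rise_nm_per_bp
        if seg.role == GROWTH:
            index += 1
            layers.append(
                StackLayer(
                    layer_index=index,
                    z_lo_nm=z,
                    z_hi_nm=z + h,
                    orientation_deg=orientation,
                    symmetry=seed.symmetry,
                )
            )
        else:
            orientation += seg.twist_deg
        z += h
    return StackSpec(layers=tuple(layers))


def gradient_face_orientations(seed: SeedDesign) -> tuple:
    """Second-layer twists templated by the two faces of a gradient seed.

    Returns ``(theta_b, theta_a)``: the non-tilted face b carries the plain
    spacer twist; the tilted face a adds the taper contribution on top.
    """
    taper = seed.cross_section.taper
    if taper is None:
        raise ValueError(
            "seed has no gradient taper; use compile_stack for uniform seeds"
        )
    spacers = [s for s in seed.segments if s.role == SPACER]
    theta = spacers[0].twist_deg if spacers else 0.0
    theta_b = theta
    theta_a = theta + taper.delta_theta_deg
    if taper.tilted_face == "b":
        theta_b, theta_a = theta_a, theta_b
    return theta_b, theta_a


# ---------------------------------------------------------------------------
# config I/O and presets
# ---------------------------------------------------------------------------

def _design_from_dict(d: dict) -> SeedDesign:
    cs = dict(d["cross_section"])
    taper = cs.pop("taper", None)
    if taper is not None:
        taper = GradientTaper(
            delta_theta_deg=float(taper["delta_theta_deg"]),
            tilted_face=taper.get("tilted_face", "a"),
        )
    spec = CrossSectionSpec(taper=taper, **cs)
    segments = tuple(
        SeedSegment(
            id=str(s["id"]),
            role=s["role"],
            bp=int(s["bp"]),
            twist_deg=float(s.get("twist_deg", 0.0)),
        )
        for s in d["segments"]
    )
    return SeedDesign(
        name=d["name"],
        cross_section=spec,
        segments=segments,
        rise_nm_per_bp=float(d.get("rise_nm_per_bp", DEFAULT_RISE_NM_PER_BP)),
        twist_rate_deg_per_bp=d.get("twist_rate_deg_per_bp"),
        sublattice_symmetry=d.get("sublattice"),
    )


def load_seed_design(path) -> SeedDesign:
    """Read a seed design from a YAML or JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return _design_from_dict(data)


def seed_preset(name: str) -> SeedDesign:
    """Load a packaged seed preset: 'seed-S', 'seed-H' or 'seed-SG'."""
    fname = {"seed-S": "seed_S.yaml", "seed-H": "seed_H.yaml", "seed-SG": "seed_SG.yaml"}
    if name not in fname:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(fname)}")
    ref = resources.files("dnamoire").joinpath("presets", fname[name])
    return _design_from_dict(yaml.safe_load(ref.read_text()))
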