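"""Synthetic micrograph-like renderer for layered tile lattices.

Scenes are sums of 2D point lattices (one per layer) rendered as isotropic
Gaussian spots on a calibrated pixel grid, optionally with a central seed
disc, then passed through a contrast transform and a noise model:

* ``contrast='linear'`` — the image is the spot-density field itself; the
  rendering is then exactly linear in the point sets.
* ``contrast='absorption'`` (default) — Beer–Lambert attenuation
  ``1 − exp(−strength·D)`` of the density ``D``, emulating stain
  mass–thickness contrast.  The nonlinearity is what puts moiré difference
  frequencies into the spectrum of a stacked scene, as in real micrographs;
  a strictly linear superposition of two lattices has no spectral weight at
  the moiré wavevectors.

Every fixture carries an exact ground-truth record (per-layer symmetry,
lattice constant and orientation, pairwise twist, expected moiré period) so
recovery code can be scored against the truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from PIL import Image as PILImage
from scipy.ndimage import gaussian_filter
import tifffile

from . import moire_math, seed_model, sublattice
from .moire_math import OrientationFieldSpec, gradient_orientation_field, moire_period
from .sublattice import LatticeSpec, PointSet, generate_lattice, lattice_spec

SCENARIOS = ("monolayer", "bilayer", "trilayer", "hybrid", "gradient")


@dataclass(frozen=True)
class RenderParams:
    pixel_size_nm: float = 0.5
    image_size: int = 1024  # square field, pixels
    spot_sigma_nm: float = 0.6
    layer_weights: Optional[tuple] = None
    noise_gaussian_sd: float = 0.02  # fraction of dynamic range
    noise_poisson_scale: float = 0.0  # photons per unit intensity; 0 = off
    seed_disc: Optional[tuple] = None  # (radius_nm, intensity)
    rng_seed: int = 0
    contrast: str = "absorption"  # 'absorption' or 'linear'
    absorption_strength: float = 1.0
    supersample: int = 2  # internal oversampling; the contrast transform is
    # applied on the fine grid and anti-alias filtered before decimation, so
    # lattice harmonics beyond the output Nyquist do not alias into the
    # moiré band

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.spot_sigma_nm <= 0:
            raise ValueError("pixel_size and spot_sigma must be > 0")
        if self.contrast not in ("absorption", "linear"):
            raise ValueError("contrast must be 'absorption' or 'linear'")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")

    @property
    def field_nm(self) -> float:
        return self.pixel_size_nm * self.image_size


@dataclass(frozen=True)
class GroundTruth:
    """Exact scene truth: layers as (symmetry, a_sub_nm, orientation_deg)."""

    layers: tuple
    twist_deg: Optional[tuple] = None  # consecutive-pair twists
    expected_p_M_nm: Optional[float] = None
    field_spec: Optional[OrientationFieldSpec] = None
    expected_p_M_range_nm: Optional[tuple] = None  # (min, max) for gradients

    def validate(self) -> None:
        """Self-consistency: stored p_M must equal the closed form."""
        if self.twist_deg:
            pairs = [
                round(self.layers[i + 1][2] - self.layers[i][2], 9)
                for i in range(len(self.layers) - 1)
            ]
            assert pairs == [round(t, 9) for t in self.twist_deg]
        if self.expected_p_M_nm is not None and self.twist_deg:
            a = self.layers[0][1]
            assert self.expected_p_M_nm == moire_period(a, self.twist_deg[0])

    def to_json(self) -> str:
        d = {
            "layers": [list(l) for l in self.layers],
            "twist_deg": list(self.twist_deg) if self.twist_deg else None,
            "expected_p_M_nm": self.expected_p_M_nm,
            "expected_p_M_range_nm": list(self.expected_p_M_range_nm)
            if self.expected_p_M_range_nm
            else None,
        }
        if self.field_spec is not None:
            d["field_spec"] = asdict(self.field_spec)
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _stamp_spots(
    points_nm: np.ndarray,
    weight: float,
    n: int,
    px_nm: float,
    sigma_px: float,
    out: np.ndarray,
    chunk: int = 20000,
) -> None:
    """Accumulate unit-peak Gaussian spots by direct (exact) evaluation.

    Evaluating the continuous Gaussian at the pixel centres keeps the render
    free of the delta-comb aliasing a splat-then-blur scheme would inject
    into the low-frequency (moiré) band: a spot of width σ has no spectral
    weight anywhere near the sampling frequency.
    """
    if len(points_nm) == 0:
        return
    half = int(math.ceil(4.0 * sigma_px))
    offs = np.arange(-half, half + 1)
    fx = points_nm[:, 0] / px_nm + n / 2.0
    fy = points_nm[:, 1] / px_nm + n / 2.0
    for lo in range(0, len(fx), chunk):
        cx = fx[lo : lo + chunk]
        cy = fy[lo : lo + chunk]
        ix = np.rint(cx).astype(int)
        iy = np.rint(cy).astype(int)
        gx = np.exp(-((ix[:, None] + offs - cx[:, None]) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((iy[:, None] + offs - cy[:, None]) ** 2) / (2 * sigma_px**2))
        patch = weight * gy[:, :, None] * gx[:, None, :]
        yy = (iy[:, None, None] + offs[None, :, None]).repeat(len(offs), axis=2)
        xx = (ix[:, None, None] + offs[None, None, :]).repeat(len(offs), axis=1)
        ok = (xx >= 0) & (xx < n) & (yy >= 0) & (yy < n)
        np.add.at(out, (yy[ok], xx[ok]), patch[ok])


def render_layers(
    point_sets: Sequence[PointSet],
    params: RenderParams,
    finest_a_sub_nm: Optional[float] = None,
) -> np.ndarray:
    """Render layered point sets to a float image (arbitrary intensity units).

    Each layer contributes unit-peak-height Gaussian spots scaled by its
    layer weight; an optional seed disc is added to the density before the
    contrast transform; Gaussian read noise and optional Poisson shot noise
    are applied last.  Deterministic given ``params.rng_seed``.
    """
    if finest_a_sub_nm is not None and params.pixel_size_nm > finest_a_sub_nm / 4:
        raise ValueError(
            "pixel size violates the Nyquist margin for the finest lattice; "
            f"use pixel_size_nm <= {finest_a_sub_nm / 4:.3f}"
        )
    ss = params.supersample
    n = params.image_size * ss
    px = params.pixel_size_nm / ss
    weights = params.layer_weights or (1.0,) * len(point_sets)
    sigma_px = params.spot_sigma_nm / px
    density = np.zeros((n, n))
    for ps, w in zip(point_sets, weights):
        _stamp_spots(ps.coords, w, n, px, sigma_px, density)

    if params.seed_disc is not None:
        radius_nm, intensity = params.seed_disc
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(xx - n / 2.0, yy - n / 2.0) * px
        density += intensity * (r <= radius_nm)

    if params.contrast == "linear":
        img = density
    else:
        img = 1.0 - np.exp(-params.absorption_strength * density)

    if ss > 1:  # anti-alias filter before decimation to the output grid
        img = gaussian_filter(img, 0.6 * ss, mode="nearest")
        img = img[ss // 2 :: ss, ss // 2 :: ss]

    rng = np.random.default_rng(params.rng_seed)
    dyn = float(img.max() - img.min()) or 1.0
    if params.noise_poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * params.noise_poisson_scale) / (
            params.noise_poisson_scale
        )
    if params.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, params.noise_gaussian_sd * dyn, img.shape)
    return img


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _uniform_layers(specs, orientations, region):
    return [
        generate_lattice(spec, region, orientation_deg=o, layer_id=i)
        for i, (spec, o) in enumerate(zip(specs, orientations))
    ]


def _gradient_layer(
    spec: LatticeSpec,
    field_spec: OrientationFieldSpec,
    region,
    n_sectors: int = 72,
    layer_id: int = 1,
) -> PointSet:
    """Second layer of a gradient scene: orientation varies with azimuth.

    The field of view is carved into azimuthal sectors around the seed; each
    sector is filled from a lattice generated at the sector-centre local
    twist.  Sector joins are left unreconstructed (the physical lattice
    relaxes them; at rendering resolution the difference is negligible).
    """
    edges = np.linspace(0.0, 360.0, n_sectors + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    local = gradient_orientation_field(field_spec, centres)
    coords = []
    for lo, hi, theta in zip(edges[:-1], edges[1:], local):
        ps = generate_lattice(spec, region, orientation_deg=theta)
        az = np.rad2deg(np.arctan2(ps.coords[:, 1], ps.coords[:, 0])) % 360.0
        sel = (az >= lo) & (az < hi)
        coords.append(ps.coords[sel])
    return PointSet(
        coords=np.vstack(coords), layer_id=layer_id, orientation_deg=math.nan
    )


def make_fixture(scenario: str, rng_seed: int = 0, **overrides):
    """Compose seed/sublattice/moiré models into a scene plus exact truth.

    Returns ``(image, truth, params)``.  Default scenarios: square bilayer
    at θ=3.9°, trilayer at 0/3.8/7.6°, square–kagome hybrid at 3.8°, and a
    gradient bilayer with θ_b=2.8° / θ_a=13.7°.  Overrides: ``symmetry``,
    ``a_sub_nm``, ``twist_deg``, ``orientations``, ``hydration``, plus any
    ``RenderParams`` field.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")

    symmetry = overrides.pop("symmetry", "square")
    hydration = overrides.pop("hydration", "dried")
    a_sub = overrides.pop("a_sub_nm", None)
    twist = overrides.pop("twist_deg", None)
    orientations = overrides.pop("orientations", None)
    theta_b = overrides.pop("theta_b_deg", 2.8)
    theta_a = overrides.pop("theta_a_deg", 13.7)
    boundary = overrides.pop("boundary_azimuth_deg", 90.0)
    direction = overrides.pop("gradual_direction", "cw")
    n_sectors = overrides.pop("n_sectors", 72)

    spec = lattice_spec(symmetry, hydration)
    if a_sub is not None:
        spec = LatticeSpec(symmetry=symmetry, a_sub_nm=a_sub, hydration=None)
    params = RenderParams(rng_seed=rng_seed, **overrides)
    region = (params.field_nm, params.field_nm)

    if scenario == "monolayer":
        orientations = orientations or [0.0]
        layers = _uniform_layers([spec], orientations, region)
        truth = GroundTruth(layers=((symmetry, spec.a_sub_nm, orientations[0]),))
    elif scenario == "bilayer":
        t = 3.9 if twist is None else twist
        orientations = orientations or [0.0, t]
        layers = _uniform_layers([spec, spec], orientations, region)
        t = orientations[1] - orientations[0]
        truth = GroundTruth(
            layers=tuple((symmetry, spec.a_sub_nm, o) for o in orientations),
            twist_deg=(t,),
            expected_p_M_nm=moire_period(spec.a_sub_nm, abs(t)),
        )
    elif scenario == "trilayer":
        stack = seed_model.compile_stack(seed_model.seed_preset("seed-S"))
        orientations = orientations or stack.orientations_deg
        layers = _uniform_layers([spec] * len(orientations), orientations, region)
        twists = tuple(
            orientations[i + 1] - orientations[i]
            for i in range(len(orientations) - 1)
        )
        truth = GroundTruth(
            layers=tuple((symmetry, spec.a_sub_nm, o) for o in orientations),
            twist_deg=twists,
            expected_p_M_nm=moire_period(spec.a_sub_nm, abs(twists[0])),
        )
    elif scenario == "hybrid":
        t = 3.8 if twist is None else twist
        sq = lattice_spec("square", hydration)
        kg = lattice_spec("kagome", hydration)
        layers = _uniform_layers([sq, kg], [0.0, t], region)
        truth = GroundTruth(
            layers=(("square", sq.a_sub_nm, 0.0), ("kagome", kg.a_sub_nm, t)),
            twist_deg=(t,),
        )
    else:  # gradient
        fs = OrientationFieldSpec(
            theta_b_deg=theta_b,
            theta_a_deg=theta_a,
            boundary_azimuth_deg=boundary,
            gradual_direction=direction,
        )
        first = generate_lattice(spec, region, orientation_deg=0.0, layer_id=0)
        second = _gradient_layer(spec, fs, region, n_sectors=n_sectors)
        layers = [first, second]
        truth = GroundTruth(
            layers=((symmetry, spec.a_sub_nm, 0.0), (symmetry, spec.a_sub_nm, math.nan)),
            field_spec=fs,
            expected_p_M_range_nm=(
                moire_period(spec.a_sub_nm, max(theta_a, theta_b)),
                moire_period(spec.a_sub_nm, min(theta_a, theta_b)),
            ),
        )

    image = render_layers(layers, params, finest_a_sub_nm=spec.a_sub_nm)
    return image, truth, params


def shrinkage(spec: LatticeSpec, preset: str) -> LatticeSpec:
    """Swap a lattice spec between hydration states (cryo ↔ dried constants)."""
    if preset not in sublattice.LATTICE_CONSTANTS_NM:
        raise ValueError(f"unknown hydration preset {preset!r}")
    if spec.symmetry not in sublattice.LATTICE_CONSTANTS_NM[preset]:
        raise ValueError(f"unknown symmetry {spec.symmetry!r}")
    return LatticeSpec(
        symmetry=spec.symmetry,
        a_sub_nm=sublattice.LATTICE_CONSTANTS_NM[preset][spec.symmetry],
        hydration=preset,
    )


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def write_image(
    basename,
    image: np.ndarray,
    params: RenderParams,
    truth: Optional[GroundTruth] = None,
) -> None:
    """Write a 16-bit TIFF, an 8-bit PNG preview and a JSON sidecar."""
    base = str(basename)
    lo, hi = float(image.min()), float(image.max())
    scale = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    tifffile.imwrite(base + ".tif", (scale * 65535).astype(np.uint16))
    PILImage.fromarray((scale * 255).astype(np.uint8)).save(base + ".png")
    sidecar = {"pixel_size_nm": params.pixel_size_nm, "image_size": params.image_size}
    if truth is not None:
        sidecar["ground_truth"] = json.loads(truth.to_json())
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_image(path) -> np.ndarray:
    """Read a TIFF or PNG image back as float64."""
    p = str(path)
    if p.endswith((".tif", ".tiff")):
        return tifffile.imread(p).astype(float)
    return np.asarray(PILImage.open(p).convert("I")).astype(float)
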