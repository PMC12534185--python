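"""FFT recovery of lattice constants, twist angles and moiré periodicity.

The measurement chain mirrors how micrographs of stacked lattices are
analysed: window → 2D power spectrum with calibrated nm⁻¹ axes → peak
detection in an annulus with sub-bin centre-of-mass refinement → clustering
of peak azimuths into per-layer families → twist = circular difference of
family azimuths folded into the lattice symmetry's fundamental zone
(square: 90°, hexagonal stars: 60°) → moiré periodicity from the
low-frequency band below the sublattice ring.

Conventions: ``|g| = 1/d``; lattice constants are reported from first-order
interplanar spacings via the per-symmetry ratio d/a (1 for square, √3/2 for
the hexagonal kagome/honeycomb stars).  The moiré-band estimator picks the
*smallest-|g|* significant peak — the moiré fundamental — rather than the
most intense one, because for lattices whose strongest Fourier shell is a
higher-order one (kagome {20}, honeycomb {11}) the brightest moiré
difference peak is a harmonic of the fundamental.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .moire_math import moire_period
from .sublattice import D_OVER_A, FOLD_DEG


@dataclass(frozen=True)
class Spectrum:
    power: np.ndarray  # fftshifted |FFT|^2
    gx: np.ndarray  # 1D axes, nm^-1 (fftshifted)
    gy: np.ndarray
    pixel_size_nm: float

    @property
    def bin_nm_inv(self) -> float:
        return float(self.gx[1] - self.gx[0])


@dataclass(frozen=True)
class Peak:
    g: np.ndarray  # (2,) nm^-1
    magnitude: float
    azimuth_deg: float  # in [0, 180)
    d_nm: float


@dataclass(frozen=True)
class PeakList:
    peaks: tuple  # sorted by magnitude descending, DC excluded

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class LayerEstimate:
    a_sub_nm: float
    orientation_deg: float
    n_peaks: int


@dataclass(frozen=True)
class RecoveryReport:
    layers: tuple  # LayerEstimate, sorted by orientation
    twist_deg: Optional[float]
    monolayer: bool
    p_M_nm: Optional[float] = None
    quality: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# spectra and peaks
# ---------------------------------------------------------------------------

def power_spectrum(
    image: np.ndarray, pixel_size_nm: float, window: str = "hann"
) -> Spectrum:
    """Windowed 2D power spectrum with axes calibrated from the pixel size."""
    if pixel_size_nm is None or pixel_size_nm <= 0:
        raise ValueError("pixel calibration (pixel_size_nm) is required")
    image = np.asarray(image, float)
    if min(image.shape) < 64:
        raise ValueError("image must be at least 64x64 pixels")
    if window not in ("none", "hann"):
        raise ValueError("window must be 'none' or 'hann'")
    img = image - image.mean()
    if window == "hann":
        wy = np.hanning(image.shape[0])
        wx = np.hanning(image.shape[1])
        img = img * np.outer(wy, wx)
    F = np.fft.fftshift(np.fft.fft2(img))
    gy = np.fft.fftshift(np.fft.fftfreq(image.shape[0], d=pixel_size_nm))
    gx = np.fft.fftshift(np.fft.fftfreq(image.shape[1], d=pixel_size_nm))
    return Spectrum(power=np.abs(F) ** 2, gx=gx, gy=gy, pixel_size_nm=pixel_size_nm)


def _radius_grid(spectrum: Spectrum) -> np.ndarray:
    GX, GY = np.meshgrid(spectrum.gx, spectrum.gy)
    return np.hypot(GX, GY)


def detect_peaks(
    spectrum: Spectrum,
    min_snr: float = 5.0,
    annulus: tuple = None,
    max_peaks: int = 24,
) -> PeakList:
    """Local spectral maxima in an annulus, refined to sub-bin precision.

    A peak must exceed ``min_snr`` times the annulus median power; its
    position is refined by a 3×3 centre of mass and conjugate-symmetric
    partners are merged (azimuths reported in [0°, 180°)).  Sorted by
    magnitude, ties broken by smaller |g|.
    """
    if annulus is None:
        raise ValueError("an annulus (g_lo, g_hi) is required")
    g_lo, g_hi = annulus
    if not g_lo < g_hi:
        raise ValueError("annulus must satisfy g_lo < g_hi")
    R = _radius_grid(spectrum)
    mask = (R >= g_lo) & (R <= g_hi)
    if not mask.any():
        raise ValueError("annulus contains no frequency bins")
    P = spectrum.power
    floor = float(np.median(P[mask]))
    thresh = min_snr * floor if floor > 0 else min_snr
    local_max = ndimage.maximum_filter(P, size=5, mode="constant") == P
    cand = np.argwhere(local_max & mask & (P > thresh))

    dg = spectrum.bin_nm_inv
    found = []
    for iy, ix in cand:
        sl = P[max(iy - 1, 0) : iy + 2, max(ix - 1, 0) : ix + 2]
        oy, ox = np.mgrid[max(iy - 1, 0) : iy + 2, max(ix - 1, 0) : ix + 2]
        w = sl.sum()
        cy = float((sl * oy).sum() / w)
        cx = float((sl * ox).sum() / w)
        g = np.array(
            [np.interp(cx, np.arange(len(spectrum.gx)), spectrum.gx),
             np.interp(cy, np.arange(len(spectrum.gy)), spectrum.gy)]
        )
        found.append((g, float(P[iy, ix])))

    # merge conjugate partners (g, -g)
    merged = []
    for g, mag in found:
        az = math.degrees(math.atan2(g[1], g[0])) % 360.0
        if az >= 180.0:
            g = -g
            az -= 180.0
        for j, (g2, mag2, az2) in enumerate(merged):
            if np.hypot(*(g - g2)) < 1.5 * dg:
                if mag > mag2:
                    merged[j] = (g, mag, az)
                break
        else:
            merged.append((g, mag, az))

    peaks = [
        Peak(g=g, magnitude=mag, azimuth_deg=az, d_nm=1.0 / np.hypot(*g))
        for g, mag, az in merged
        if np.hypot(*g) > 0
    ]
    peaks.sort(key=lambda p: (-p.magnitude, np.hypot(*p.g)))
    return PeakList(peaks=tuple(peaks[:max_peaks]))


def sublattice_annulus(expected_a_sub_nm: float, symmetry: str) -> tuple:
    """±30% annulus around the expected first-order |g| of a symmetry."""
    g0 = 1.0 / (expected_a_sub_nm * D_OVER_A[symmetry])
    return (g0 / 1.3, g0 * 1.3)


# ---------------------------------------------------------------------------
# lattice and twist estimation
# ---------------------------------------------------------------------------

def _circular_mean(angles_deg, weights, modulus: float) -> float:
    """Weighted circular mean of angles defined modulo ``modulus`` degrees."""
    angles = np.asarray(angles_deg, float) * (360.0 / modulus)
    w = np.asarray(weights, float)
    z = np.sum(w * np.exp(1j * np.deg2rad(angles)))
    mean = np.rad2deg(np.angle(z)) % 360.0
    return mean * (modulus / 360.0)


def _circular_diff(a: float, b: float, modulus: float) -> float:
    d = (a - b) % modulus
    return d if d <= modulus / 2 else d - modulus


def estimate_lattice(
    peaks: PeakList,
    symmetry: str,
    min_split_deg: float = 0.75,
    max_peaks: int = 12,
    rel_magnitude: float = 0.02,
) -> RecoveryReport:
    """Per-layer lattice constants and orientations, plus the twist.

    Only peaks within ``rel_magnitude`` of the strongest are used: first-
    order Bragg families dominate their moiré satellites and grid artefacts
    by orders of magnitude.  Peak azimuths folded into the symmetry's
    fundamental zone are split into two clusters at the largest circular
    gaps; clusters closer than ``min_split_deg`` are treated as a single
    family (monolayer flag, twist undefined).  Orientations are magnitude-
    weighted circular means; the twist is the folded circular difference of
    the two family orientations.
    """
    fold = FOLD_DEG[symmetry]
    ratio = D_OVER_A[symmetry]
    use = list(peaks)
    if len(use) == 0:
        raise ValueError("no peaks supplied")
    top = max(p.magnitude for p in use)
    use = [p for p in use if p.magnitude >= rel_magnitude * top][:max_peaks]
    az = np.array([p.azimuth_deg % fold for p in use])
    mag = np.array([p.magnitude for p in use])
    d = np.array([p.d_nm for p in use])

    def layer(sel) -> LayerEstimate:
        return LayerEstimate(
            a_sub_nm=float(np.average(d[sel], weights=mag[sel])) / ratio,
            orientation_deg=_circular_mean(az[sel], mag[sel], fold),
            n_peaks=int(np.sum(sel)),
        )

    if len(use) == 1:
        return RecoveryReport(
            layers=(layer(np.array([True])),), twist_deg=None, monolayer=True
        )

    order = np.argsort(az)
    sorted_az = az[order]
    gaps = np.diff(np.concatenate([sorted_az, [sorted_az[0] + fold]]))
    split = int(np.argmax(gaps))
    # start the circular ordering just past the largest gap, then split the
    # remaining run at its own largest internal gap (the two largest circular
    # gaps bound the two families)
    idx = np.concatenate([order[split + 1 :], order[: split + 1]])
    wrapped_az = (az[idx] - az[idx[0]]) % fold
    inner_gaps = np.diff(wrapped_az)
    if len(inner_gaps) == 0 or inner_gaps.max() < min_split_deg:
        sel = np.ones(len(use), bool)
        return RecoveryReport(layers=(layer(sel),), twist_deg=None, monolayer=True)
    cut = int(np.argmax(inner_gaps)) + 1
    sel_a = np.zeros(len(use), bool)
    sel_a[idx[:cut]] = True
    sel_b = ~sel_a

    la, lb = layer(sel_a), layer(sel_b)
    twist = abs(_circular_diff(la.orientation_deg, lb.orientation_deg, fold))
    if twist < min_split_deg:
        sel = np.ones(len(use), bool)
        return RecoveryReport(layers=(layer(sel),), twist_deg=None, monolayer=True)
    layers = tuple(sorted((la, lb), key=lambda l: l.orientation_deg))
    return RecoveryReport(
        layers=layers,
        twist_deg=float(twist),
        monolayer=False,
        quality={"n_peaks": len(use)},
    )


# ---------------------------------------------------------------------------
# moiré periodicity
# ---------------------------------------------------------------------------

def estimate_moire_period(
    spectrum: Spectrum,
    symmetry: str = "square",
    expected_a_sub_nm: Optional[float] = None,
    min_snr: float = 6.0,
    lo_bins: int = 4,
    rel_magnitude: float = 0.05,
) -> Optional[float]:
    """Moiré periodicity from the low-frequency band below the lattice ring.

    The band spans from ``lo_bins`` frequency bins above DC (skipping the
    window main lobe) to 60% of the first-order sublattice |g|.  The moiré
    fundamental is the smallest-|g| peak among those within
    ``rel_magnitude`` of the strongest in-band peak (weak higher-order
    combination tones sit below that cut); its reciprocal is the moiré
    interplanar spacing, converted to the moiré lattice constant via the
    symmetry's d/a ratio.  Returns ``None`` when nothing is detected
    (untwisted or unresolved moiré).
    """
    if expected_a_sub_nm is not None:
        g_sub = 1.0 / (expected_a_sub_nm * D_OVER_A[symmetry])
    else:
        full = detect_peaks(
            spectrum,
            min_snr=min_snr,
            annulus=(lo_bins * spectrum.bin_nm_inv, float(np.max(spectrum.gx))),
        )
        if len(full) == 0:
            return None
        g_sub = float(np.hypot(*max(full, key=lambda p: p.magnitude).g))
    g_lo = lo_bins * spectrum.bin_nm_inv
    g_hi = 0.6 * g_sub
    if g_hi <= g_lo:
        return None
    # significance floor: the maximum of n exponential noise bins is ~ln(n)
    # times the mean, so demand a clear multiple of that before calling a
    # moiré peak detected
    R = _radius_grid(spectrum)
    n_bins = int(np.sum((R >= g_lo) & (R <= g_hi)))
    eff_snr = max(min_snr, 3.0 * math.log(max(n_bins, 2)))
    try:
        plist = detect_peaks(spectrum, min_snr=eff_snr, annulus=(g_lo, g_hi))
    except ValueError:
        return None
    if len(plist) == 0:
        return None
    top = max(p.magnitude for p in plist)
    strong = [p for p in plist if p.magnitude >= rel_magnitude * top]
    fundamental = min(strong, key=lambda p: np.hypot(*p.g))
    d_m = float(fundamental.d_nm)
    return d_m / D_OVER_A[symmetry]


# ---------------------------------------------------------------------------
# windowed orientation / period maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationField:
    centre_x_nm: np.ndarray  # 2D grids
    centre_y_nm: np.ndarray
    twist_deg: np.ndarray  # NaN where unresolved
    orientation_deg: np.ndarray  # first-family orientation, NaN where unresolved
    p_M_nm: np.ndarray  # inf sentinel where twist is 0, NaN where unresolved
    window_px: int
    stride_px: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_nm": self.centre_x_nm.ravel(),
                "y_nm": self.centre_y_nm.ravel(),
                "twist_deg": self.twist_deg.ravel(),
                "orientation_deg": self.orientation_deg.ravel(),
                "p_M_nm": self.p_M_nm.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def orientation_map(
    image: np.ndarray,
    pixel_size_nm: float,
    symmetry: str,
    expected_a_sub_nm: float,
    window_px: int = 128,
    stride_px: int = 64,
    min_snr: float = 4.0,
) -> OrientationField:
    """Windowed-FFT map of local twist and local moiré period.

    Square windows on a regular grid; each window runs the peak-detection /
    lattice-estimation chain and converts local twist to local p_M through
    the closed-form moiré relation.  Windows where two families cannot be
    resolved are NaN.
    """
    image = np.asarray(image, float)
    if window_px < 64:
        raise ValueError("window must be at least 64 px")
    if stride_px > window_px:
        import warnings

        warnings.warn("stride larger than window leaves coverage gaps")
    n_y, n_x = image.shape
    ys = np.arange(0, n_y - window_px + 1, stride_px)
    xs = np.arange(0, n_x - window_px + 1, stride_px)
    annulus = sublattice_annulus(expected_a_sub_nm, symmetry)

    shape = (len(ys), len(xs))
    twist = np.full(shape, np.nan)
    orient = np.full(shape, np.nan)
    p_map = np.full(shape, np.nan)
    cx = np.zeros(shape)
    cy = np.zeros(shape)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            sub = image[y0 : y0 + window_px, x0 : x0 + window_px]
            cy[i, j] = (y0 + window_px / 2.0 - n_y / 2.0) * pixel_size_nm
            cx[i, j] = (x0 + window_px / 2.0 - n_x / 2.0) * pixel_size_nm
            try:
                spec = power_spectrum(sub, pixel_size_nm)
                plist = detect_peaks(spec, min_snr=min_snr, annulus=annulus)
                if len(plist) < 2:
                    continue
                report = estimate_lattice(plist, symmetry)
            except ValueError:
                continue
            if report.monolayer or report.twist_deg is None:
                continue
            a_est = float(np.mean([l.a_sub_nm for l in report.layers]))
            twist[i, j] = report.twist_deg
            orient[i, j] = report.layers[0].orientation_deg
            p_map[i, j] = moire_period(a_est, report.twist_deg)
    return OrientationField(
        centre_x_nm=cx,
        centre_y_nm=cy,
        twist_deg=twist,
        orientation_deg=orient,
        p_M_nm=p_map,
        window_px=window_px,
        stride_px=stride_px,
    )


def ring_profile(
    field: OrientationField,
    r_lo_nm: float,
    r_hi_nm: float,
    median_window: int = 1,
):
    """Azimuth-sorted (azimuth_deg, twist_deg, p_M_nm) of cells in a radius band.

    ``median_window`` > 1 applies a circular running median to the twist
    profile (and recomputes p_M from the filtered twist), suppressing
    isolated mis-estimated windows before gradient analysis.
    """
    r = np.hypot(field.centre_x_nm, field.centre_y_nm)
    sel = (r >= r_lo_nm) & (r <= r_hi_nm) & np.isfinite(field.twist_deg)
    az = np.rad2deg(
        np.arctan2(field.centre_y_nm[sel], field.centre_x_nm[sel])
    ) % 360.0
    order = np.argsort(az)
    az = az[order]
    twist = field.twist_deg[sel][order]
    p = field.p_M_nm[sel][order]
    if median_window > 1 and len(twist) >= median_window:
        half = median_window // 2
        padded = np.concatenate([twist[-half:], twist, twist[:half]])
        filt = np.array(
            [np.median(padded[i : i + median_window]) for i in range(len(twist))]
        )
        a_eff = 2.0 * p * np.sin(np.deg2rad(twist) / 2.0)  # per-cell a_sub
        twist = filt
        p = a_eff / (2.0 * np.sin(np.deg2rad(np.maximum(filt, 1e-9)) / 2.0))
    return az, twist, p


def azimuthal_discontinuities(
    azimuth_deg: np.ndarray, values: np.ndarray, jump_threshold: float
) -> int:
    """Count circular jumps exceeding ``jump_threshold`` against the local trend.

    For a field that increases gradually with azimuth except for sharp
    drops, this counts the significant decreases (including the wrap-around
    step), i.e. the number of discontinuities.
    """
    v = np.asarray(values, float)
    dv = np.diff(np.concatenate([v, v[:1]]))
    return int(np.sum(dv < -jump_threshold))
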