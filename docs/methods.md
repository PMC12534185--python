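# Methods

## Seed geometry

A DNA origami seed is modelled as an ordered list of axial segments over a
fixed cross-section. Growth segments template one SST sublattice each;
spacer/twister segments contribute height and a right-handed in-plane
rotation. Compiling a design is pure arithmetic: layer k spans the
cumulative height of the preceding segments (axial rise 0.34 nm/bp,
canonical B-DNA; configurable) and is oriented at the sum of the preceding
spacer twists, with layer 1 at 0°. This reproduces the designed registries
exactly: 128 bp → 43.5 nm, 32 bp → 10.9 nm, 36 bp → 12.2 nm, 126 bp →
42.8 nm, and trilayer orientations 0°/3.8°/7.6° for the square-array seed.

Twist-per-segment values are **calibration constants**, not predictions:
the mechanical relaxation that turns a spacer's base-pair count into ≈3.8°
(square array, 32 bp) or ≈1.2° (honeycomb array, 36 bp) comes from
coarse-grained simulation outside this package's scope. Gradient seeds
store the tilted-face contribution Δθ (≈10.9°) directly for the same
reason; the trapezoid's base-pair-level construction is not modelled, and
the spacer length of the gradient preset is nominal (only its 2.8° twist
propagates).

Cross-sections are laid out on a 2.6 nm interhelical pitch (square grid or
staggered honeycomb packing with the same nearest-neighbour pitch) with the
pore block removed from the rim centre; the pitch affects only rendering,
never helix counts (8×8 − 4×4 = 48; 12×6 − 6×3 = 54).

## Sublattices

Each symmetry is a Bravais lattice plus basis: square (one site), honeycomb
(hexagonal, two sites), kagome (hexagonal, three corner-sharing-triangle
sites). The kagome lattice is treated as what it is geometrically — the
fine triangular net of spacing `a_k/2` with one of every four sites
removed. This keeps the empirical constant relation `a_k = 2·a_s` (dried
2.2 → 4.4 nm, hydrated 2.8 → 5.4 nm) while giving the hexagonal
first-order star the measured FFT patterns show; the voided-net derivation
is exposed as `kagome_from_square`, with the specific in-plane void/shear
arrangement at tile level left open (it is not derivable from the
information available here). Lattice constants carry hydration presets
(cryo: 2.8/5.4/4.4 nm; dried: 2.2/4.4/3.5 nm) and `shrinkage` converts
between them.

Reciprocal space uses the crystallographic convention `|g| = 1/d`. Note the
distinction between lattice constant and first-order interplanar spacing:
`d = a` for square but `d = a·√3/2` for the hexagonal stars; all
conversions between measured spacings and reported constants go through
this single ratio. Structure factors matter for the imaging stage: the
brightest Fourier shell of the kagome lattice is {20} (|F| = 3 versus 1 for
{10}) and of the honeycomb {11} (|F| = 2), so measurement annuli of ±30%
around the expected first-order |g| are used to isolate the first-order
families.

## Moiré relations

The exact relation `p_M = a_sub/(2 sin(θ/2))` and its inverse are used
everywhere; the small-angle form `p ≈ a/θ` exists only as a documented
helper. Published measured pairs for kagome and honeycomb bilayers are
independent measurements, not formula-consistent pairs, and are not
asserted anywhere. Moiré reciprocal vectors are the pairwise differences
between the (rotated) first-order stars; for identical layers the smallest
nonzero magnitude is `2|g| sin(θ/2)`, the reciprocal of the moiré
*interplanar spacing* — the same d↔a ratio as above converts it to `p_M`.

Gradient superlattices are described by an azimuthal orientation field:
local twist interpolating **linearly in azimuth** from the tilted-face
value θ_a (13.7°) down to the parallel-face value θ_b (2.8°) along the
gradual direction, with a single sharp discontinuity at a boundary azimuth.
Linearity is a modelling choice (only "gradual" is known); the functional
form is confined to `gradient_orientation_field` and configurable.

## Nucleation model

Capture patterns are boolean (z, x) grids of the two capture species; a
site is a capture pair iff both are present. The classifier reports the
mode (fully / partially / non-cooperative), the pair count, and the longest
vertical run of pairs — z-continuity being the property that separates
effective partial seeds from ineffective ones. The mapping from mode to an
effective contact angle (fully → 30°, z-continuous partial → 90°,
otherwise 180°) is deliberately coarse and documented as arbitrary; only
its ordering is meaningful.

The thermodynamic forms are 2D CNT stand-ins chosen for planar lattice
growth: a disc nucleus with edge free energy Γ gives
`ΔG* = πΓ²/Δg(T)` with supersaturation `Δg = Δh·(T_m − T)/T_m`
(temperatures absolute), heterogeneous nucleation scales the barrier by the
2D cap shape factor `f(ψ) = (ψ − sinψ cosψ)/π`, and rates are Arrhenius
with reduced units (k = 1). These are standard textbook CNT forms adopted
as the model of this system; they are constrained to the documented
qualitative behaviour — `R = N_hetero/N_homo`
equals 1 for f = 1 with matched prefactors, increases with temperature
under wetting (on any grid above T_m/2 in absolute terms, which any
experimentally sensible grid satisfies), grows without bound towards T_m
while both absolute rates vanish, and is elevated across the whole range
for strong wetting. Whether R truly peaks below T_m or rises monotonically
to the domain edge is not decidable from the available information; the
model is monotone up to T_m.

Reduced-unit defaults (T_m = 45 °C, Δh = 200, Γ = 50, prefactors 5·10⁴,
seed-site/bulk density ratio 10⁻³) place the model in the regime the
experiments describe: bulk nucleation effectively suppressed at 40 °C but
active at 34 °C, and strongly wetting seeds nucleating much faster than the
bulk. No kinetic constants are published; these are regime choices, not
fits, and the absolute experimental percentages are never asserted.

## Growth simulator

A well-mixed Gillespie SSA over three event classes: bulk nucleation
(∝ N_homo × free fraction), per-seed nucleation (∝ N_hetero per site ×
unused seeds × free fraction; each seed nucleates at most once), and
growth (∝ √size × free fraction — perimeter-limited attachment for a 2D
aggregate; an area-independent law is selectable). A tau-leaping variant is
available for large pools. Mass is conserved exactly on every trajectory;
`rng_seed` is mandatory and fully determines a run. Default study
conditions use a pool of 8 000–20 000 tiles, 0–100 seeds and a duration of
a few reduced time units — sizes chosen so a run takes well under a second
while leaving hundreds of structures for statistics. The simulator
reproduces directions, not magnitudes: more seeds → more, smaller, more
uniform lattices; cooling → more bulk nucleation → lower seeded fraction;
no wetting → statistically indistinguishable from unseeded assembly.

## Synthetic imaging

Scenes are rendered from exact lattice geometry: isotropic Gaussian spots
(σ = 0.6 nm) at every lattice point, 0.5 nm/px on a 1024² field by default
(256–512 px in fast unit tests), optional central seed disc, Gaussian read
noise (2% of dynamic range) and optional Poisson shot noise, 16-bit TIFF
output with a JSON truth sidecar. Spots are evaluated analytically per
pixel rather than splatted and blurred — a Gaussian has no spectral weight
near the sampling frequency, so the render is alias-free where it matters.

Contrast is the one deliberate nonlinearity: the default is Beer–Lambert
absorption `1 − exp(−D)` of the spot density D, emulating stain
mass–thickness contrast. This matters because a strictly linear
superposition of two lattices has **no** spectral weight at the moiré
difference frequencies — the visual beat pattern of a linear sum is not a
Fourier component. The nonlinear transfer puts the difference peaks into
the spectrum, as in real micrographs. Because a nonlinearity applied to
sampled data aliases lattice harmonics beyond the output Nyquist into the
low-frequency band, the transform is applied on an internally 2×
supersampled grid and anti-alias filtered before decimation. With
`contrast="linear"` the render is exactly additive (the linearity property
tests use it) but moiré-period estimation is then impossible by
construction.

Gradient scenes build the second layer from 72 azimuthal sectors, each
filled from a lattice generated at the sector-centre local twist; sector
joins are left unreconstructed (the real lattice relaxes them; at imaging
resolution the difference is negligible).

What the renderer does **not** emulate: TEM contrast physics (defocus,
CTF, stain granularity), 3D projection, lattice defects, twin boundaries,
finite lattice outlines, or drying deformation beyond the global constant
presets. Passing recovery tests therefore demonstrate the correctness of
the measurement chain on ideal-geometry images, not robustness to the full
pathology of real micrographs.

## FFT recovery

Measurement chain: mean subtraction → Hann window → 2D FFT power spectrum
with nm⁻¹ axes → local maxima above `min_snr ×` the annulus median, refined
by 3×3 centre of mass (ties: larger magnitude, then smaller |g|), conjugate
pairs merged to azimuths in [0°, 180°). Sublattice peaks are sought in the
±30% annulus around the expected first-order |g| when a constant is
supplied, else full band.

Twist estimation folds peak azimuths into the symmetry's fundamental zone
(90° square, 60° hexagonal — acute twists only), keeps peaks within a
relative-magnitude factor (2%) of the strongest (first-order families
dominate their moiré satellites by orders of magnitude), splits the folded
azimuths at the two largest circular gaps into two families, and reports
magnitude-weighted circular means; families closer than 0.75° are a single
family (monolayer flag, twist undefined). Angular statistics use circular
means throughout.

Moiré periodicity is read from the band between 4 frequency bins above DC
(skipping the window main lobe) and 60% of the sublattice |g|. Two
safeguards are principled rather than cosmetic: the detection threshold
grows as `3·ln(number of band bins)` because the maximum of n exponential
noise bins is ~ln(n) times the mean (otherwise pure noise yields a "moiré
peak" for untwisted stacks, which must instead return the not-detected
sentinel); and the **smallest-|g|** peak within 5% of the strongest is
taken as the fundamental, because for kagome/honeycomb the brightest moiré
difference peak can be a harmonic inherited from the brighter higher-order
sublattice shell.

Windowed orientation maps run the same chain per window on a regular grid
(window 128–256 px, stride 64). Resolution limit: two families merge when
their peak separation `|g|·sin(θ)` falls below ~2 frequency bins, so
measuring twists down to ~2.8° locally requires 256 px windows at
0.5 nm/px. Local p_M comes from local twist via the closed form using the
locally measured constant. Ring profiles around the seed support an
optional circular running median (window 3) to suppress isolated
mis-estimated windows before gradient analysis — with it, the recovered
local period around a gradient fixture spans ≈9.4–39 nm against the
designed 9.2–45 nm endpoints, with exactly one azimuthal discontinuity
(window averaging near the sharp boundary accounts for the compression of
the upper endpoint). Window placement is a regular grid; selecting analysis
areas by eye, as a human analyst would, is deliberately not reproduced.

## Numerical choices and conventions

- Angles in degrees at every interface, right-handed about +z; radians
  internally where convenient. Lengths in nm, reciprocal space in nm⁻¹
  (`|g| = 1/d`, no 2π).
- Region clipping in lattice generation uses closed boundaries with a
  relative tolerance of 10⁻⁹·a, so points on an edge are included.
- Infinite moiré period (θ = 0) is an explicit `inf` sentinel; undetected
  moiré peaks and unresolvable windows are `None`/`NaN` sentinels;
  degenerate cross-sections (rim = pore) carry a flag instead of an error.
- All stochastic components (renderer noise, growth simulator) require an
  explicit RNG seed and are exactly reproducible given it.

## Test problem sizes

Unit tests render 256–512 px images; the recovery sweep in the acceptance
suite uses the full 1024² default across {square, kagome, honeycomb} ×
{2°, 5°, 10°} × 3 noise seeds, and growth-trend checks use 20 paired
replicates at an 8 000-tile pool — sizes at which the whole suite completes
in a few minutes on one CPU while every statistical claim retains a clear
margin.
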