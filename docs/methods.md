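# Methods

This note records the scientific and numerical choices behind `dissolvox`:
what each component computes, the assumptions it makes, and where the
design was genuinely open.

## Voxel matrices and composition accounting

A virtual tablet is a 3D array of 8-bit labels indexed `(slice, row, col)`,
axis 0 along the tablet height, all indices 0-based with half-open ranges.
The default label convention is air = 0, drug = 1, matrix former = 31,
dissolution medium = 200; every operation takes an explicit `label_map`, so
any convention can be used.  The physical scale enters solely through the
voxel edge length (default 0.028 mm, a typical upload resolution for
voxel-based dissolution engines; fixtures use a coarser 0.2 mm so test
volumes stay small).

Masses follow from counting: `mass = count × edge³ × ρ`, with edges in mm
and helium densities in kg/m³ resolved to mg (1 kg/m³ = 10⁻³ mg/mm³).
Recovery rates are `100 × m_virtual / m_real` per compound, for the total,
and for the three composition ratios; reported recoveries are rounded
half-up to one decimal, matching how such rates are conventionally printed.

**Image porosity region.** The air fraction of a voxel image depends on the
evaluation region, and no single convention is canonical: an uploaded
segmented tomography stack is already cropped to the tablet, whereas a
generated tablet sits in an air bounding box.  Both conventions are
exposed — the default is the full stack; an analytic cylindrical mask
(voxel centres inside the cylinder) can be passed for generated tablets.

**Desirability.** The tablet desirability is the geometric mean of six
per-parameter scores, one per recovery quantity, each mapping a recovery
percentage into [0, 1].  The geometric mean makes any completely failed
parameter annihilate the score, which is the intended behaviour for a
quality gate.  The per-parameter mapping is pluggable; the default is a
two-sided linear ramp `d = max(0, 1 − |recovery − 100|/w)` with width
w = 25 percentage points — a transparent stand-in chosen so that a 25-point
recovery error zeroes that component.  Batch-level aggregation with a
precision factor is out of scope.

## Tablet generation

Both construction modes fill an analytic cylinder rasterised by
voxel-centre membership.  Target masses are converted to voxel counts by
nearest rounding, which bounds the mass error by half a voxel-mass per
compound (the contract asserts one voxel-mass).

*Distributed*: in-cylinder voxels are assigned uniformly at random.
*Seed-and-grow*: `n_seeds` voxels per compound are placed uniformly at
random; growth proceeds in rounds, each surviving cluster accreting one
uniformly chosen empty 6-neighbour per round until the compound's voxel
count is reached.  The user controls particle number (seed count) and
particle size (growth extent); the accretion rule itself — single-voxel,
6-connected, uniform over the cluster frontier — is the simplest isotropic
choice and is asserted to produce 6-connected clusters.  A compound whose
clusters are fully enclosed before reaching target raises a named error.

*Densify* converts in-region air to compound voxels, holding the
**voxel-count ratio** (not the mass ratio) of the existing compounds to
within one voxel via largest-remainder quotas.  A voxel engine can hold a
count ratio exactly, whereas a mass ratio is generally unattainable when
densities differ; the achieved masses are reported alongside.  Existing
compound voxels are never modified.  In `seed_grow` mode air is converted
preferentially adjacent to existing particles so the result stays compact;
isolated air pockets are assigned directly once no adjacent growth remains.

All generators draw from one `numpy.random.default_rng(seed)`; identical
parameters and seed reproduce matrices bit-identically.

## Porosity arithmetic

The measured tablet porosity is one minus true volume over apparent
volume: `φ_tablet = (1 − (m_API/ρ_API + m_ex/ρ_ex)/(π(D/2)²h)) × 100 %`.
This true-volume/apparent-volume form is the only dimensionally consistent
reading of the quantity; the implementation rejects results outside
[−5, 100] % as a signal of inconsistent inputs (slightly negative values
are tolerated for rounding of printed masses).

The virtual excipient porosity redistributes the porosity deficit of the
image onto the matrix former:

    φ_ex = S (φ_tablet − φ_image) Vx_size (Vx_API + Vx_ex)
           (1 + 0.01 φ_tablet) / (h Vx_ex)

implemented literally, with percent values carried on the 0–100 scale
(hence the `0.01 φ_tablet` term).  A negative result — the image showing
*more* porosity than measured, i.e. over-segmented voids — is physically
meaningful and is returned with a warning rather than raised.  The module
is binary-mixture-only; how such a correction should distribute across
three or more compounds is not defined here.

## Profile similarity

f1 and f2 are computed on the strict common time grid of reference and
test profile: both experiment and prediction are sampled on the same
interval in this workflow (600 s), so grid mismatches indicate user error
and are rejected rather than interpolated.  The selection window runs to
12 h or to the first reference sample at ≥ 99.5 % release (configurable),
that point included.  The t = 0 sample is excluded by default: it carries
no information and inflates n, which biases f2 upward; a toggle restores
it.  The verdict uses strict inequalities (f1 < 15, f2 > 50), both limits
configurable.

## Kinetics

Both plots use time in **minutes** and release in **percent**.  This
convention is pinned by an internal consistency check: an
experimental-like Higuchi line with slope ≈ 1.79 and intercept ≈ 1.09
evaluates to ≈ 49 % release at t = 720 min, i.e. roughly half release at
12 h, which is the physically sensible reading.  The Korsmeyer–Peppas plot
is base-10; the time base affects only the intercept (asserted
numerically), and the exponent n is invariant.

The regression window is the closed interval 20–60 % release; fewer than
four window points raise an *exclusion* signal distinct from an error.
Fits are ordinary least squares (`scipy.stats.linregress`); both plain and
adjusted R² (`1 − (1 − R²)(n−1)/(n−2)`) are retained.

Mechanism classification for cylinders: n ≤ 0.45 + tol Fickian diffusion,
up to 0.89 − tol anomalous transport, above that case-II; tol defaults to
0.02 and is configurable because the literature bands are guidelines, not
sharp thresholds.

**Regression comparison.** Slopes are compared with the pooled
(ANCOVA-style) t-test: `t = (b₁ − b₂)/SE`, pooled residual variance,
df = n₁ + n₂ − 4.  Only when the slope test does not reject is the
elevation (intercept) compared under a common-slope model with
df = n₁ + n₂ − 3; otherwise the intercept comparison is meaningless and is
reported as the literal string `NA`.  Tests are two-sided at α = 0.05 with
no multiple-testing correction (per-matrix raw p-values are the reporting
convention).  The pooled variant was chosen over Welch because the two
windowed fits have similar design and residual scale by construction; the
choice is isolated in `compare_regressions`.  A tiny negative common-slope
residual sum (floating-point cancellation on perfect fits) is clamped to
zero.

## Reference dissolution fixture

The simulator exists to exercise the validation chain, with every rule
open and every constant in `SimulationConfig`.  It is not a reproduction
of any production dissolution engine and none of its outputs are
reference values.  Assumptions: one-second steps (43,200 for 12 h),
medium advances one voxel per step through 6-connected open space from the
bounding-box faces; a compound is wettable iff its contact angle is
strictly below 90°; wettable matrix former with intraparticular porosity
φ becomes conductive with per-step probability
`1 − (1 − r·φ/100)^(wet faces)` (r = `percolation_rate`, default 0.05);
soluble voxels lose `rate × solubility × wet_faces × (1 + mixing)` mg per
step (`dissolution_rate` default 3 × 10⁻⁵ mg·mL/mg per face per step,
chosen so a surface drug voxel at 10 mg/mL solubility dissolves over
~minutes of simulated time at the default resolution).  Molar mass,
medium viscosity/tension and pore size are configuration passthroughs the
update rule does not consume.

Mass is conserved by construction (dissolved mass is debited exactly from
voxel masses), profiles are nondecreasing and capped at 100 %, insoluble
compounds are never released, and a drug cluster sealed by unwettable
zero-porosity excipient plateaus at its exposed fraction — the
non-percolation signature that distinguishes a structurally wrong virtual
tablet from a sound one.

## Synthetic data

Profile generators produce power-law (`k·tⁿ`), square-root (`k·√t`) and
logistic (`cap/(1 + e^(−k(t−n)))`, n = midpoint time in minutes) curves on
a 10-minute grid to 12 h, with optional Gaussian noise (clipped to
[0, cap] and made nondecreasing by running maximum — the monotonisation
mildly biases noisy values upward near the plateau but leaves the 20–60 %
fitting window essentially untouched at the default 0.5-point noise).

Composition fixtures embed the worked records of a 25/75
theophylline/ethyl-cellulose compact (real 86.9/329.5 mg; e.g. virtual
73.3/329.2 mg for the low-desirability matrix T7 and 96.1/323.8 mg for
T4) and realise each record as a generated matrix at 0.2 mm voxels inside
an 11.28 mm die, so the recovery arithmetic reproduces the published
rates (84.3 %/99.9 % and 98.3 %) from an actual voxel volume rather than
from a division.  What these fixtures do **not** emulate: tomographic
noise, beam hardening, segmentation artefacts, or realistic particle-size
distributions — passing tests demonstrate correct accounting and
statistics, not image-processing fidelity.

## Problem sizes

Test and acceptance runs use grids up to 20 × 59 × 59 voxels
(~70,000), 10⁴-replicate oracle sweeps, 1000-replicate calibration runs
and simulator horizons of 30,000–40,000 steps on ≤ 9³ grids; these sizes
give stable statistics (binomial SE ≈ 0.007 on the calibration rate) while
the full suite completes in well under a minute of compute.

## Known limitations

- Binary mixtures only, matching the validation design the package serves.
- The desirability components and the similarity limits are conventions,
  not science; both are parameters.
- The seed-and-grow accretion rule is one defensible choice among many;
  matrices generated by other engines will differ in microstructure even
  at equal seed counts and masses.
- The reference simulator's kinetics are qualitative.  It shares state
  variables (wetting, exposure, solubility) with production engines but no
  calibration; conclusions about a real engine require that engine's own
  profiles.
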