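# Methods

`mcdose` is a fast Monte Carlo engine for absorbed-dose calculation from
megavoltage photon beams, in the tradition of the Dose Planning Method class
of codes: simplified interaction physics valid for low-Z media and
radiotherapy energies, Woodcock (delta) tracking for photons in voxelized
geometry, condensed-history transport for charged particles, and a mixed
geometry model that couples a quadric-surface machine head (MLC leaves,
jaws) to the voxelized phantom so dynamic deliveries can be simulated in a
single transport step.  A comparison toolkit (local 3-D gamma analysis and
a statistical/systematic difference decomposition) evaluates agreement
between dose distributions.

## Photon physics

Interactions are Compton scattering, photoelectric absorption and pair
production; Rayleigh scattering, bound-Compton corrections, Doppler
broadening and photonuclear reactions are neglected, which is accurate for
low-Z media above ~100 keV and degrades gracefully in the tungsten
collimator (documented limitation; the collimator mainly attenuates).

* **Compton.**  Klein–Nishina differential cross section for a free
  electron at rest, sampled in `eps = E'/E` by the standard two-branch
  composition–rejection scheme; the polar angle follows from the Compton
  relation `E' = E / (1 + (E/m_e c^2)(1 - cos theta))`, the recoil electron
  from two-body kinematics.  Energy is conserved exactly per interaction.
* **Photoelectric.**  The photon is absorbed and a photoelectron carries
  the *full* photon energy along the photon direction; binding energy,
  fluorescence and Auger relaxation are neglected.  Adequate for low-Z
  tissue at megavoltage energies; a known simplification inside tungsten.
* **Pair production.**  Above 1.022 MeV the available kinetic energy is
  split uniformly at random between the electron and positron, both emitted
  forward.  The positron is transported with the electron model and, at
  local absorption, emits two back-to-back 0.511 MeV photons with an
  isotropic axis.  Pair is a minor channel at 6 MV, so the crude angular
  model has negligible dose impact; it is isolated and testable.

Per-material linear attenuation coefficients live on a shared logarithmic
energy grid (default 100 nodes, 1 keV – 7 MeV, covering a 6 MV spectrum
with headroom).  The Compton channel is `n_e * sigma_KN(E)` analytically;
photoelectric and pair channels come from per-element tables shipped with
the package and mixed by mass fraction.  Those element tables are
*synthetic*: generated by `scripts/make_element_tables.py` from standard
analytic approximations (Born-approximation Z^5 photoelectric scaling,
Bethe–Heitler complete-screening pair asymptote with a cubic threshold
factor, Bethe collision stopping power with ICRU mean excitation energies
and no density-effect correction, radiative term `(T + m_e c^2)/X_0` with
the PDG radiation length).  They are physically plausible rather than
evaluated-library accurate; since Compton dominates tissue attenuation
above ~100 keV, megavoltage attenuation and dose in tissue are controlled
by the analytic Klein–Nishina term.  All engine-level verification is
against the package's own tables, so no test depends on library-grade
element data.

Interpolation between grid nodes is log-log linear, exact at nodes, with a
linear fallback where a bracketing value is zero (the pair channel at
threshold), and *no extrapolation*: out-of-range queries raise.  The
interpolation contract is explicitly tested (including a dense-grid
consistency check for air) because interpolation artifacts in low-density
media are a classic failure mode of this class of engine.

## Photon tracking

Inside the voxel grid photons use Woodcock tracking: path lengths are drawn
from the majorant coefficient `mu_max(E) = max_voxels mu(material, rho, E)`
and tentative sites are accepted as real interactions with probability
`mu_local/mu_max`, so voxel-wall intersections are never computed.  The
majorant is evaluated per photon energy as the maximum over the materials
present (scaled by each material's maximum density ratio in the grid),
which guarantees `mu_max >= mu` everywhere for the same interpolant —
the dominance is structural, not numerical.  In the machine region photons
are ray-traced body-to-boundary with the local body's coefficient
(surface-to-surface distances from the quadric roots), matching the split
geometry model.

## Electron physics

Charged particles use class II condensed history:

* **Soft losses.**  Restricted collision stopping power (Bethe minus the
  hard-Moller energy-loss rate above `W_c`) plus the radiative term,
  deposited continuously along the step with a midpoint rule.
* **Hard collisions.**  Moller scattering on free electrons, restricted to
  `W in [W_c, E/2]` (identical-particle convention), sampled by rejection
  with a 1/W^2 envelope; delta rays are tracked.  Distances to hard
  collisions are exponential in the restricted inverse mean free path.
* **Multiple scattering.**  One polar deflection per step from a single
  small-angle distribution scaled by `theta_0^2 = T(E) * s`, where the
  scattering power `T` derives from a Highland-type formula
  `T = (13.6 MeV / (beta p c))^2 / X_0`.  The shape is the plane-projected
  2-D Gaussian (Rayleigh-distributed polar angle) truncated at pi, which
  preserves `<theta^2> = T s` exactly.  This is a deliberately simple
  stand-in for Lewis-theory samplers; it keeps the small-angle,
  single-distribution structure and exact moment scaling, and is isolated
  behind the scattering-model interface so a higher-fidelity sampler can
  replace it without touching the stepper.
* **Positrons** reuse the electron model (Moller in place of Bhabha) and
  annihilate at rest; the 2 x 0.511 MeV rest energy is carried explicitly
  through the energy audit.
* **Radiative losses** are included in the stopping power and deposited
  along the track rather than radiated as explicit bremsstrahlung photons.
  This overestimates local deposit and underestimates long-range photon
  leakage from thick collimators; at 6 MV in tissue the radiative fraction
  is a few percent.  (The spec's alternative — emitting a forward photon
  per step — was considered; the simpler local model was chosen to keep
  per-history energy conservation exact and the step cheap, and because
  MLC leakage in the scenes studied is photon-transmission dominated.)

Steps are limited by the fractional energy loss `f_step * E / S(E)`, a
geometric cap, voxel walls (each sub-step deposits in one voxel; the scalar
`condensed_step` contract implements the equivalent chord-proportional
split), body boundaries in the machine region, and the sampled
hard-collision distance.

Defaults (all configurable, none pinned by the underlying physics): photon
cutoff 0.05 MeV, electron cutoff 0.2 MeV, `W_c` 0.2 MeV, `f_step` 0.04,
maximum step 0.5 cm in the grid.  Below cutoff, energy is deposited on the
spot.

## Geometry

Beam axis is -z toward the phantom, isocenter at the origin, voxel indices
zero-based with half-open `[low, high)` intervals (a point on a shared face
belongs to the higher-index voxel).  Machine bodies are intersections of
signed quadric surfaces with rigid transforms; crossing roots within
1e-8 cm are skipped to avoid re-detecting the surface just crossed.  Gantry
and collimator rotations compose as rigid rotations about the isocenter
(IEC sense: gantry about +y, collimator about +z); the couch rotation is
stored inversely on the grid orientation metadata.

The MLC is parametric: two opposed banks of rectangular leaves with
cylindrical tip surfaces and an optional tongue-and-groove step (a
half-thickness strip on one leaf side), with configurable count, width,
thickness, tip radius and tongue width.  It reproduces the physics of the
classic verification pattern — rounded-tip leakage between closed opposed
tips, tongue-and-groove underdose, interleaf transmission — without
claiming any vendor's dimensions.

Coarse-voxel support: `coarsen_grid` rebins density by exact volume-overlap
weighting (total mass conserved to floating-point accuracy; the dominant
material by overlap volume is assigned), and `refine_dose` maps a coarse
dose back to the original grid by trilinear interpolation of voxel-center
values with clamped edges — exact on uniform and linear fields, which is
the tested contract.

## Sources, plans, parallel contract

The analytic source is a Gaussian focal spot (FWHM 0.15 cm) with Gaussian
energy spectrum (6.2 MeV mean, 0.186 MeV FWHM) and a uniform cone of
half-angle 2.5 degrees aimed down -z from z = +100 cm — the nominal 6 MV
upstream beam parameterization.  Phase-space files use a versioned 128-byte
text header plus fixed-width binary records (species, E, x, y, u, v, sign
of w, weight); readers partition a file by stride without copying, so
parallel streams need no pre-partitioning step.

Plans are ordered control points (leaf/jaw positions, angles, cumulative
meterset weight) in a YAML schema, with optional DICOM-RTPLAN import and a
structural export used for round-trip testing.  Histories are apportioned
to control points proportionally to meterset increments by the
largest-remainder method (exact, deterministic, ties broken by control
point order — the rounding rule is a package choice, stated here because
no standard fixes it).  Each control point is simulated against its frozen
machine configuration; leaf motion is not interpolated within a control
point.

Parallelism is a contract, not a mechanism: work is partitioned by history
over counter-based Philox streams keyed by (seed, stream, control point),
tallies merge exactly, and the result is bitwise reproducible for a fixed
(seed, number of streams).

## Tally statistics

The tally uses the grouped history-by-history estimator: all deposits of
one primary history and its progeny (split copies, delta rays, annihilation
photons) are summed per voxel before squaring.  A per-deposit estimator
would be biased low because in-history deposits are correlated; the grouped
contract is tested directly.  Dose is reported per source particle in
MeV/g (1 MeV/g = 1.602e-10 Gy).  The uncertainty report follows the
convention of averaging the relative standard uncertainty over voxels
scoring more than 50% of the maximum dose; both 1-sigma (reports) and
2-sigma (gamma exclusions) conventions appear explicitly where used.

## Variance reduction

Two techniques, both unbiased and tested for unbiasedness against plain
runs: simple particle splitting (factor n, weight w/n) applied when a
particle crosses the interface into the voxel region, and movable-skins
range rejection for electrons in flagged machine bodies — an electron whose
residual CSDA range is smaller than its distance to the body's skin (an
inner margin, default 0.1 cm, from any surface) cannot reach an open region
and is absorbed on the spot.  The distance to the nearest surface is exact
for planes and first-order (`|Q|/|grad Q|`) for curved quadrics.

## Dose comparison

**Gamma.**  Local 3-D gamma: for each non-excluded reference voxel center,
`gamma^2 = min [ (dD / (d * D_ref/100))^2 + (r / DTA)^2 ]` over a lattice
filling a sphere of radius `1.2 * DTA` around the point — points outside
that volume cannot pass the DTA criterion, so the bound is structural.  The
lattice step satisfies both protocol constraints: at least 5 samples per
axis across the search span and no larger than half the finer grid
resolution; the evaluated distribution (only) is sampled by trilinear
interpolation.  Exclusions: reference dose below 1% of the maximum, or
reference 2-sigma uncertainty above 10%.  Ties at gamma = 1 pass.

**Systematic-difference decomposition.**  Per-voxel normalized differences
`t_v = (D1 - D2)/sqrt(s1^2 + s2^2)` are modeled as a three-component
mixture: pure statistical (unit normal) with probability `1 - a+ - a-`, and
systematic components offset by `+Delta` or `-Delta` (expressed in % of the
maximum dose, converted to t-units per voxel) with weights `a+`, `a-`.
The single shared magnitude with per-sign weights is the estimator's model;
components are reported as (alpha+, +Delta) / (alpha-, -Delta) pairs.
Estimation is maximum likelihood (coarse grid scan, Nelder–Mead
refinement).  Because alpha is unidentifiable on the `Delta -> 0` ridge, a
likelihood-ratio guard (threshold 10 on `2 dLL`, a deliberately
conservative heuristic) returns the pure-noise solution unless the mixture
fits significantly better.  Identifiability limit: when `Delta` is below
about one combined noise sigma, alpha and Delta are not separately
identifiable at 10^4 voxels (only `alpha * Delta^2` is); recovery tests
therefore cover the resolvable regime and the null.

## Synthetic data and what the tests show

No external data is used anywhere.  The synthetic generators emulate: the
analytic 6 MV beam (not a full linac head simulation — no contaminant
electrons, no off-focal radiation), the water and seven-layer slab phantoms
(muscle 1.04 / air / lung 0.3 / muscle / compact bone 1.85 / lung / muscle,
40x40x35 cm^3 at 0.5x0.5x0.25 cm^3), and mixture-model dose-difference
fields with known (alpha, Delta).  Passing tests therefore demonstrate
internal physical consistency (attenuation laws, spectra against
quadrature, CSDA and moment limits, conservation, unbiasedness,
reproducibility) and correct implementations of the comparison protocols —
they do not certify agreement with a general-purpose reference code on
clinical CT data, which requires that code and those data.

## Numerical choices and degenerate inputs

Energy conservation is audited per history to 1e-9 relative and asserted on
every run, including delta rays, annihilation (rest mass carried
explicitly), machine-body deposits and escapes.  Zero-majorant (vacuum)
grids transport photons straight through; electrons leaving the voxel grid
are scored as escaped (vacuum surround, as in voxel-only engines), which
slightly underestimates backscatter at the outermost voxel shell.
Particles exactly on the interface plane cross immediately; surface roots
closer than the 1e-8 cm boundary tolerance are ignored.  Problem sizes in
the shipped tests and the acceptance script (10^5-history transport checks,
10^4-voxel comparison fields, 6-pair MLC scenes over coarse water grids)
were chosen so the full verification runs comfortably on one CPU; they are
package defaults, and every size is a parameter.

## Known limitations

No Rayleigh scattering, atomic relaxation or explicit bremsstrahlung
photons; tungsten photoelectric treatment is crude (affects collimator
spectra more than phantom dose); the multiple-scattering shape is Gaussian
rather than a Lewis-moment sampler (slightly too few large-angle
deflections — depth-dose tails in low-density media are the sensitive
case); element data are analytic approximations, not an evaluated library;
couch rotation is metadata applied at the region hand-off rather than a
re-oriented voxel traversal; absolute calibration (Gy/MU) is out of scope.
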