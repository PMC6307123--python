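# mcdose

Fast Monte Carlo dose calculation for megavoltage photon beams, with a
mixed quadric/voxel geometry for simulating the patient-dependent linac
head (MLC, jaws) and the patient in one transport step, dynamic
control-point plans, variance reduction, and a dose-comparison toolkit.

**Who it is for.** Medical-physics researchers and developers of dose
verification tools who need a transparent, fully tested engine of the
"fast MC" class (simplified cross sections, Woodcock tracking, condensed
history) to compute, perturb and compare 3-D dose distributions — not a
clinical treatment-planning system.

## The model

Photons undergo Compton scattering (Klein–Nishina, free electron at rest),
photoelectric absorption (full energy to a forward photoelectron) and pair
production. Inside the voxel grid they are tracked by the Woodcock (delta)
technique: with a majorant attenuation coefficient
`mu_max(E) >= mu(r, E)` everywhere, free paths are sampled as
`s = -ln(xi)/mu_max` and a tentative site is a real interaction with
probability `mu(r, E)/mu_max` — no voxel-wall intersections are ever
computed. In the quadric machine region photons are ray-traced from
surface to surface.

Electrons and positrons use mixed (class II) condensed-history transport:
restricted continuous energy loss `dE = S(E) ds` below the hard threshold
`W_c`, discrete Moller collisions with transfers `W in [W_c, E/2]`
(delta rays tracked), and one small-angle multiple-scattering deflection
per step with `<theta^2> = T(E) s` from a Highland-type scattering power.
Positrons annihilate at rest into two 0.511 MeV photons.

Two unbiased variance-reduction techniques are built in: particle
splitting on entry into the voxel region, and movable-skins range
rejection — an electron deep inside an MLC leaf or jaw whose residual CSDA
range cannot reach the body's skin is absorbed on the spot.

Dose comparison follows the standard protocols: local 3-D gamma analysis
`gamma^2 = min[(dD/(d D_ref/100))^2 + (r/DTA)^2]` over a search sphere of
radius `1.2 DTA` (trilinear sampling, >= 5 points per axis, step at most
half the finer resolution, low-dose and high-uncertainty exclusions), and
a maximum-likelihood decomposition of per-voxel normalized differences
into statistical noise and a systematic component (fraction `alpha`,
magnitude `Delta` in % of the maximum dose).

Full model details, defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from mcdose import (AnalyticBeam, GammaSettings, KFSettings, RunConfig,
                    build_water_phantom, gamma_pass_rate, kf_decomposition,
                    report_uncertainty, run_simulation, stream_generator)

phantom = build_water_phantom(size=(20, 20, 20), spacing=(0.5, 0.5, 0.5))
beam = AnalyticBeam()   # nominal 6 MV: 6.2 MeV, FWHM 0.186 MeV, spot 0.15 cm, 2.5 deg
tally, audit = run_simulation(RunConfig(phantom, beam, histories=40000,
                                        seed=1, streams=4))
dose = tally.dose()     # MeV/g per history
```

Continuing with gamma comparisons of the computed dose against rescaled
copies and a decomposition of a synthetic difference field with known
truth (30% of voxels carrying a ±1%-of-Dmax systematic offset under 0.5%
noise) prints:

```
energy audit max violation : 1.5e-15
max central-axis dose      : 3.792e-03 MeV/g per history at depth 2.50 cm
avg rel. sigma (>50% Dmax) : 27.3 %
gamma(1%,1mm) vs +0.5% scale : 100.0 % of 18176 points
gamma(1%,1mm) vs +2.0% scale : 50.4 %  (DTA rescues gradients)
mixture decomposition      : alpha = 34.3 % (truth 30), Delta = 0.94 % of Dmax (truth 1.0)
```

Reading the numbers: every history's energy balances to machine precision;
the depth of maximum dose for a ~6 MeV photon beam in water lands at
2.5 cm; at 40 000 histories the mean statistical uncertainty in the
high-dose region is 27% (it falls as `1/sqrt(N)`); a flat +0.5% rescale
passes a 1%/1 mm gamma everywhere while +2% fails except where steep
gradients let the distance-to-agreement term rescue points; and the
mixture estimator recovers the planted systematic fraction and magnitude
within its statistical precision.

The same engine drives the command line:

```sh
mcdose simulate --scene water --histories 20000 --seed 7 --streams 4 \
    --out dose.mvox.npz
mcdose compare gamma ref.mvox.npz eval.mvox.npz --dose-crit 1 --dta 1
mcdose compare kf ref.mvox.npz eval.mvox.npz --threshold 0.5
mcdose phantom multilayer --out slabs.mvox.npz
```

Scenes include the homogeneous water phantom (40x40x30 cm^3,
0.2x0.2x0.5 cm^3 bins), a seven-layer slab phantom
(muscle/air/lung/muscle/bone/lung/muscle, 40x40x35 cm^3,
0.5x0.5x0.25 cm^3 bins) and a parametric MLC scene with a closed central
leaf pair, tongue-and-groove stretch and open segment. Dynamic plans are
YAML control-point lists (optional DICOM-RTPLAN import); histories are
allocated to control points by cumulative meterset weight.

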