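# Methods

## The correction problem

Steady-state fluorescence intensity (FI) measured at a tissue surface
confounds fluorophore concentration with the medium's absorption
(mu_a) and reduced scattering (mu_s') at the excitation wavelength: the
same concentration can read out over more than an order of magnitude
across physiological optical properties.  `fluolut` implements a
model-independent correction: two reflectometry quantities measured at
the excitation wavelength — the total diffuse reflectance `R_T` under a
large (4.16 mm) projected disk, and the slope of log10 of the spatially
resolved reflectance (SRR) under a small (0.70 mm) disk, fitted between
1.1 and 2.1 mm from the beam center — index a look-up table (LUT) built
from training phantoms that share one calibration concentration
`c_cal`.  Because (`R_T`, mu_eff) maps one-to-one onto (mu_a, mu_s')
for diffuse media, and the logSRR slope is a proxy for the effective
attenuation mu_eff = sqrt(3 mu_a (mu_a + mu_s')), the pair
(`R_T`, slope) indexes the optical-property dependence of FI without
ever estimating mu_a or mu_s'.

Each training phantom i contributes the correcting value

    cvF_i = log10(1 / F_i),

and a scattered-data interpolant cvF(R_T, slope) corrects any query:

    F_corrected = F * 10^cvF(R_T, slope),      c = c_cal * F_corrected.

At every training phantom the correction returns exactly 1 by
construction; the log/power pair keeps the interpolated surface mild
where F is strongly attenuated.  The linear relation between
F_corrected and concentration assumes no quenching.

## Monte-Carlo transport engine

A weighted-photon random walk in a homogeneous slab (semi-infinite or
finite depth with a totally absorbing backing), MCML-style: exponential
step lengths with mu_t = mu_a + mu_s, isotropic or Henyey-Greenstein
scattering, partial Fresnel transmission at the refractive-index
mismatched top surface (total internal reflection included), Russian
roulette (threshold 1e-4, survival 0.1) for weights reduced by boundary
splitting.  The specular entry reflection ((n-1)/(n+1))^2 is excluded:
all outputs are per unit energy *entering* the medium, matching
measurements taken through crossed polarizers.  Runs are bit-exact for
a fixed seed (a splitmix64 stream drives every decision).

Absorption bookkeeping switches per medium, both variants unbiased:

- **continuous deposition** (fraction mu_a/mu_t of the weight deposited
  at every interaction) whenever mu_a/mu_t >= 8e-3.  It keeps photons
  alive, which is what gives usable statistics in the 1.1-2.1 mm fit
  window at high absorption, where escaping photons are rare.
- **analog survival sampling** (terminate with probability mu_a/mu_t,
  depositing the full weight) below that, i.e. for extreme albedos
  where continuous deposition would grind for ln(1/W_th) * mu_t/mu_a >
  1000 steps per absorbed photon while virtually all photons escape
  anyway, making the two schemes statistically equivalent.

Pencil-beam (impulse) responses are binned into 25 um annuli out to
10 mm at the surface and into a 50 um x 100 um (r, z) absorbed-weight
map (10 x 20 mm).  Extended beams are never simulated directly:
transport is linear, so any disk or Gaussian beam is synthesized by 2D
FFT convolution of the impulse response with the beam irradiance
profile on a 25 um Cartesian grid, and one Monte-Carlo run serves all
three observables.  The synthesis declares a validity radius and raises
instead of silently truncating when the impulse does not extend far
enough.

Fluorescence is modeled perturbatively in two stages: the excitation
run's absorbed-weight map defines isotropic emission sources with total
strength `quantum_yield * (mu_a_fluo / mu_a_ex) * absorbed_weight`;
source positions are sampled from the map (jittered uniformly within
cells) and propagated at the emission-wavelength properties.  Escaping
fluorescence is therefore exactly linear in fluorophore absorption and
quantum yield — the premise of the concentration equation.  Absorption
outside the recorded (r, z) grid cannot seed emission; for the most
transparent grid media this truncates a few percent of the source
strength, a smooth function of the optical properties that the LUT
absorbs (training and query share it).  A single-pass re-emission
random walk serves as the independent oracle for this factorization in
the test suite.

## Measured quantities

- `R_T`: mean of the large-disk surface map over a central 1.40 mm
  diameter ROI (pixel-center-in-circle rule), divided by the equivalent
  ROI mean of an ideal reflectance standard (reflectance 0.99) under
  the same beam.  The standard's exact reflectance cancels out of the
  corrected FI because training and query share it (tested).
- SRR: radial profile of the small-disk map — read along the grid axes,
  exact for radially symmetric synthesis — normalized to the total
  intensity and area within 5 mm (simulation convention; the camera
  pipeline uses 3.7 mm, matching its acquisition geometry).  The slope
  of log10(SRR) is fitted by OLS over bins whose centers lie in the
  closed interval [1.1, 2.1] mm (40 bins at the default pitch); any
  non-positive value in the window is an error, not a silent drop.
- `F`: like `R_T` but on the fluorescence map, same reference
  normalization (the reflectance-referenced convention applied
  consistently on both channels).

## LUT interpolants

Inputs (R_T, slope) are standardized to the training set's zero mean
and unit variance before fitting — the thin-plate spline kernel is not
scale-invariant and the two inputs carry different units; the scaling
is stored with the LUT.  Both interpolants reproduce the nodes exactly:

- **linear**: barycentric interpolation on the Delaunay triangulation,
  with per-simplex affine coefficients solved directly.  Outside the
  convex hull the affine function of the boundary simplex nearest to
  the query is evaluated at the query's projection onto the hull:
  boundary simplices of the curved training manifold can be slivers
  whose planes diverge within a fraction of a cell, so the value
  continues constant along the outward normal and stays bounded by the
  node range.
- **tps**: exact thin-plate spline (r^2 log r kernel plus affine part,
  solved by scipy's RBF machinery with zero smoothing; an optional
  ridge parameter relaxes exactness for noisy experimental tables).
  TPS extrapolates naturally.

Queries outside the hull are evaluated but flagged `extrapolated`.
The standard F/R baseline (fluorescence over excitation-wavelength
reflectance) is included for comparison, calibrated by its mean over
the same training phantoms so that its corrected value is also ~1.

## Synthetic phantoms and the camera model

The generator emulates liquid phantoms of Intralipid (scatterer),
India ink (absorber) and an Alexa-Fluor-680-like dye (87 nM calibration
concentration; absorption 4.24e-5 mm^-1 per nM from a molar extinction
of 1.84e5 M^-1 cm^-1; quantum yield 0.36) in black wells, at 670 nm
excitation / 716 nm emission.  Grids are log-spaced over mu_a in
[0.05, 3] cm^-1 and mu_s' in [2.5, 100] cm^-1 (training sets over
[0.08, 2.57] and [3.02, 96.8] cm^-1), endpoints inclusive; a
single-value axis takes the geometric mean of its range.  Emission
properties follow mu_s'(lambda) ~ lambda^-2.4 (an Intralipid-like
power law) and a flat ink spectrum by default; both exponents are
configurable since published spectra vary.  Test sets mirror the two
experimental series: a concentration series (log-uniform properties
inside the training ranges, varying concentration, 10 mm wells, plus
two phantoms 10% outside the ranges to exercise the extrapolation
flag) and a depth series (four media x well depths 1/3/5/10 mm at the
calibration concentration).

The frame renderer produces the five acquisition images (reflectance,
fluorescence, reflectance reference, background, spread dot) for a
16-bit camera at 0.046 mm/pixel (the 0.46 mm analysis strip is then 10
pixels), with a constant background offset, optional Poisson shot
noise and Gaussian read noise, and an optional peak shift emulating
the instrument's 20-degree oblique incidence.  What it does *not*
emulate: speckle, vignetting/flat-field structure beyond the reference
normalization, camera nonlinearity, and genuine oblique-incidence
transport (the shift is a geometric stand-in).  Pipeline tests passing
on these renders therefore validate the processing chain's algebra and
geometry, not robustness to those instrument effects.

The camera pipeline reproduces the acquisition processing: background
subtraction (clipping negatives), exposure normalization, reference
normalization for the two ROI channels; for the spread dot, peak
finding, intensity-and-area normalization within 3.7 mm, and radial
averaging within a 0.46 mm strip perpendicular to the incidence
direction.  The peak is the centroid of the maximal plateau of the 3x3
mean-smoothed frame: bright dot cores routinely clip at the camera's
full well, and a plain argmax would land on a corner of the saturated
plateau, displacing every radial bin; the centroid convention reduces
to the argmax pixel when the maximum is unique.

## Evaluation harness and problem sizes

The numerical experiment simulates every grid phantom once, then
builds LUTs from log-spaced training subsets chosen as the nearest
grid nodes to the ideal training values (no re-simulation), corrects
all phantoms, and reports the RMSE of corrected FI against 1, its
relative standard deviation, per-phantom relative errors, and the R^2
statistics of the slope fits.

Desk-scale defaults: a 10 x 10 evaluation grid, 2e5 excitation photons
and 1e5 emission photons per phantom (about five minutes per grid on
one core), versus ~900 combinations at 1e6 photons at full scale; a
full-scale run is a configuration change, not a code path.  All grid
phantoms share one RNG seed (common random numbers): the Monte-Carlo
error then varies smoothly across the grid, and since training
phantoms are grid nodes, the LUT absorbs part of the shared error —
mirroring real measurements, where training and test share one
instrument response.  Seed replicates (the acceptance protocol uses
three, reporting medians) expose the residual noise.

At this photon budget the corrected-FI spread is noise-limited in one
specific place: toward low mu_a and low mu_s' the (R_T, slope) pair
loses sensitivity to mu_a (the fit window is only a fraction of a
transport length from the source there, and the logSRR slope saturates
toward a mu_t-driven quasi-ballistic decay), so the map from
measurements to cvF becomes ill-conditioned and per-phantom noise of
~1% in slope is amplified several-fold into the corrected FI.  The
relative-SD statistic is therefore a few times larger at desk scale
than at full scale, while the mean and maximum LUT-fit errors — driven
by the smooth interpolation bias, not by noise — reproduce.  The same
ill-conditioning, not interpolation, dominates the error map's
low-absorption corner, consistent with where the method's error
concentrates at full scale.

## Numerical conventions and edge cases

- Lengths in mm, coefficients in mm^-1 internally; `per_cm` converts
  explicitly at I/O boundaries.
- Anisotropy defaults to g = 0 with mu_s = mu_s_prime (similarity
  relation); g is configurable and tested against g = 0.7 at equal
  mu_s'.
- Beam profiles: flat-top disks of the quoted diameters by default; a
  Gaussian option interprets the diameter as the 1/e^2 width and
  truncates at twice that radius.
- Delaunay degeneracy (collinear training inputs) and singular TPS
  systems raise with a conditioning diagnostic; ties in peak finding
  and simplex selection resolve to the lowest index, never by jitter.
- F = 0 corrects to 0 (concentration 0); F < 0 and quantum yields
  outside [0, 1] are rejected.
- The 1.1-2.1 mm window membership is decided by bin centers in the
  closed interval.

## Known limitations

- The logSRR-slope/mu_eff proportionality is a diffusive far-field
  statement; over the full property grid the 1.1-2.1 mm window is
  pre-asymptotic for weakly attenuating media and the rank correlation
  between |slope| ln10 and mu_eff is ~0.89-0.90 even for the
  closed-form dipole model (the Monte-Carlo engine agrees with the
  model; the discrepancy is physics of the window, not sampling).
- Polarization, layered media, time/frequency-domain transport and
  oblique-incidence transport are out of scope.
- The perturbative fluorescence model omits re-absorption/re-emission
  and quenching; it is exact only to first order in mu_a_fluo.
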