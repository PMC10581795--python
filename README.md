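# fluolut

Model-independent correction of fluorescence intensity (FI) for tissue
optical properties, driven by two excitation-wavelength reflectometry
measurements, with the Monte-Carlo photon-transport engine and the
evaluation harness needed to validate the method numerically.

## The problem and the method

Wide-field fluorescence imaging reads out fluorophore concentration
through tissue whose absorption mu_a and reduced scattering mu_s'
modulate the signal by more than an order of magnitude across
physiological ranges.  Estimating mu_a and mu_s' explicitly and
inverting a light-propagation model is accurate but slow and
ill-posed.  `fluolut` implements the look-up-table (LUT) alternative:
for diffuse media the pair (total diffuse reflectance R_T, effective
attenuation mu_eff) maps one-to-one onto (mu_a, mu_s'), and the slope
of log10 of the spatially resolved reflectance (SRR) over 1.1-2.1 mm
is a practical proxy for mu_eff.  Training phantoms sharing one
fluorophore concentration c_cal but spanning the optical-property
range contribute correcting values

    cvF(R_T, slopelogSRR) = log10(1 / F),                        (training)

interpolated by a thin-plate spline or Delaunay-linear scattered
interpolant.  Any sample measurement (F, R_T, slope) is then corrected
without ever estimating its optical properties:

    F_corrected = F * 10^cvF(R_T, slopelogSRR),   c = c_cal * F_corrected.

At a training phantom the correction returns exactly 1, so c = c_cal.

The package contains the full numerical chain: an MCML-style
Monte-Carlo engine (pencil-beam impulse responses, two-stage
perturbative fluorescence, slab or semi-infinite media), beam
synthesis by convolution (4.16 mm and 0.70 mm projected disks), the
three measured quantities, LUT construction/application, a camera
image-processing pipeline (background/exposure/reference
normalization, peak finding, strip-based radial profiles), synthetic
phantom and frame generators, and the grid evaluation harness with the
F/R baseline.  See `docs/methods.md` for the science and the numerical
conventions.

## Worked example

Build a LUT from four training records and correct a measurement (the
numbers are exact, no simulation involved):

```python
from fluolut import ReflectometryTriplet, TrainingSet, build_lut, correct

records = [
    ReflectometryTriplet(R_T=0.20, slope_log_srr=-1.0, F=0.004),
    ReflectometryTriplet(R_T=0.80, slope_log_srr=-1.0, F=0.040),
    ReflectometryTriplet(R_T=0.50, slope_log_srr=-0.4, F=0.020),
    ReflectometryTriplet(R_T=0.50, slope_log_srr=-1.7, F=0.010),
]
lut = build_lut(TrainingSet(records, c_cal=87.0), method="tps")

res = correct(0.004, 0.20, -1.0, lut)   # a training phantom's own triplet
print(res.F_corrected, res.c_estimate)  # 1.0000000000 87.0  (node exactness)

res = correct(0.012, 0.55, -1.2, lut)   # an interior query
print(round(res.F_corrected, 4), round(res.c_estimate, 2), res.extrapolated)
```

prints

```
0.9999999999999998 86.99999999999999
0.8102 70.48 False
```

i.e. the query's raw FI of 0.012 corresponds to 0.81 of the
calibration intensity once its optical-property attenuation is removed,
hence 70.5 nM, and the query lies inside the training convex hull.

Simulate one phantom end-to-end and measure its triplet:

```python
from fluolut import OpticalMedium, SimulationConfig
from fluolut.phantoms import phantom_from_properties, simulate_phantom

spec = phantom_from_properties(mu_a=0.03, mu_s_prime=2.0)  # mm^-1, 670 nm
cfg = SimulationConfig(n_photons=200_000, seed=5)
triplet, fit = simulate_phantom(spec, cfg)
print(triplet)
# ReflectometryTriplet(R_T=0.4237520571215054,
#                      slope_log_srr=-0.550890112765028,
#                      F=0.0025241509856951568)
```

The same operations are exposed on the command line:

```sh
fluolut simulate --mu-a 0.03 --mu-sp 2.0 --photons 2e5 --seed 5 --out imp.h5
fluolut build-lut train.csv --method tps --ccal-nm 87 --out lut.json
fluolut correct meas.csv --lut lut.json --out corrected.csv
fluolut process-frames acq_dir/ --out triplet.csv
fluolut evaluate --na 10 --ns 10 --seed 1 --out results/
```

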