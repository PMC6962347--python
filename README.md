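# plaqueswe

Combined spatiotemporal (group-velocity) and frequency-dependent
(phase-velocity) shear wave elastography analysis for carotid plaques,
together with synthetic wave-field and cohort generators that make every
stage verifiable without patient data.

## The problem

Rupture-prone ("vulnerable") carotid plaques are identified by their
internal composition — lipid-rich necrotic core (LRNC), thin fibrous
cap, intraplaque hemorrhage — rather than by how much they narrow the
lumen, so stenosis-based screening can miss them. Ultrasound shear wave
elastography (SWE) probes plaque stiffness mechanically: an acoustic
radiation force push launches shear waves through the plaque, and their
propagation speed reflects the tissue's shear modulus. In a spatially
confined plaque the waves are guided and dispersive, so two velocity
metrics carry complementary information:

* **Group velocity** `v_g` — the speed of the wave-packet envelope in
  the space–time domain, estimated by a linear fit of time-to-peak (TTP)
  arrival times `t(x) = x / v_g + b` with a random-sample-consensus
  (RANSAC) filter and an inlier-ratio quality gate.
* **Phase velocity** `c_p(f)` — the frequency-resolved speed, read from
  the 2-D Fourier (f–k) transform of the space–time map as
  `c_p(f) = f / |k*(f)|` at the wavenumber of maximum spectral
  intensity, then averaged within 200–300, 300–400 and 400–500 Hz bands.

Upstream of both metrics, axial particle velocities are estimated from
complex baseband (IQ) ultrasound ensembles by a 2-D autocorrelation
(Doppler) estimator, the counter-propagating waves of the dual-sided
push are separated by directional filtering in the f–k plane, and the
plaque-masked movie is depth-averaged to a space–time map `v(x, t)`.
Downstream, per-plaque summaries feed a cohort evaluation: two-sided
Wilcoxon rank-sum comparisons of modified AHA plaque types (the complex
type VI against each other type) and Pearson/Spearman correlation
screens against MRI-derived plaque components and blood lipids, with a
correlation flagged at |R| ≥ 0.5 and p < 0.05.

The package is aimed at researchers developing or validating SWE
processing chains for confined vascular tissue; all inputs can be
synthetic (dispersive wave fields with known ground truth, cohorts with
known group structure), so every stage has a recovery target.

## Worked example

Simulate a dual-push acquisition through a 3 mm plate with bulk shear
speed 4 m/s (flexural-mode dispersion, `c_p(f) = sqrt(2π f h c_T / √3)`),
then run the full analysis on the rightward-travelling wave:

```python
import plaqueswe as ps

cfg = ps.WaveSimConfig(
    dispersion=ps.DispersionLaw.plate_a0(h=3e-3, c_T=4.0), snr_db=None, seed=0
)
field = ps.simulate_wavefield(cfg)
left, right = ps.directional_filter(field)
m = ps.depth_average(right, cfg.roi, "rightward")
est = ps.estimate_group_velocity(m)
bands = ps.band_average(ps.extract_curve(ps.compute_dispersion(m)))
print(f"group velocity: {est.velocity:.2f} m/s (inlier ratio {est.inlier_ratio:.2f})")
for (lo, hi), mean, ok in zip(bands.band_edges, bands.band_means, bands.band_valid):
    print(f"phase velocity {lo:.0f}-{hi:.0f} Hz: {mean:.2f} m/s (valid={ok})")
```

prints

```
group velocity: 4.60 m/s (inlier ratio 0.62)
phase velocity 200-300 Hz: 3.32 m/s (valid=True)
phase velocity 300-400 Hz: 3.89 m/s (valid=True)
phase velocity 400-500 Hz: 4.43 m/s (valid=True)
```

The band means track the analytic within-band averages of the law
(3.29 / 3.90 / 4.42 m/s) to better than 1%, rising with frequency as
√f — the dispersive signature of a guided wave. The group velocity is a
broadband envelope speed and, in a dispersive medium, is not expected to
equal any single-band phase velocity; for a non-dispersive (constant
law) simulation the two metrics agree within a few percent.

The same chain is available from the shell:

```bash
swe simulate-wave --speed 5 --iq --out acq.h5
swe estimate-motion acq.h5 --out vel.h5
swe make-maps vel.h5 --out maps.h5
swe group-velocity maps.h5 --out gv.csv
swe phase-velocity maps.h5 --out pv.csv
swe simulate-cohort --out cohort.csv && swe evaluate cohort.csv --out report/
swe run --out rundir/          # full pipeline with manifest and report
```

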