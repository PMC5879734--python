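# Methods

## Displacement model

Each liver is reduced to nine representative points, one per Couinaud
segment (1, 2, 3, 4a, 4b, 5, 6, 7, 8), observed in three imaging states: a
free-breathing helical CT snapshot, the end-inspiration bin ("phase 0") and
the end-expiration bin ("phase 50") of a 10-phase gated 4DCT. All positions
live in a signed LR/AP/SI patient frame with positive = left, posterior,
superior (an LPS-style convention); every displacement is destination minus
origin, so the identity

    (helical -> phase50) - (helical -> phase0) = (phase0 -> phase50)

holds exactly per observation, and all cohort statistics are invariant under
rigid translation of a patient's positions.

Cohort summaries use the sample SD with the n-1 denominator, matching the
downstream Student-t construction. The overall row of an amplitude table
pools all 9 x n per-patient values per axis; its mean therefore equals the
unweighted mean of segment means (all segments share n). The published
summary this package emulates does not state how its overall +/-SD was
pooled, so the pooled-SD rule is the default and a mean-of-segment-SDs
alternative is available (`amplitude_table(..., overall="mean_of_sds")`).

## Margin derivation

For one segment/axis, each helical->phase displacement summary (mean, sd, n)
yields a t-interval for the cohort mean, `mean ± t · sd/√n`, with `t` the
two-sided 95% Student-t quantile at n-1 degrees of freedom. At n = 20 the
conventional printed value 2.093 is used verbatim rather than the
eight-decimal quantile, so derived tables match hand calculations at 0.1 mm.
The margin is the envelope of the phase-0 and phase-50 intervals, clamped to
contain zero — the clamp is forced by the meaning of an expansion margin (an
ITV can never be smaller than the delineated volume) and is visible in
published tables as 0.0 bounds where both intervals sit on one side of zero.
The construct is deliberately a confidence interval for the cohort mean
displacement, not a tolerance interval for individual lesions; see
"Coverage" below. The overall margin row averages the nine per-segment
margins per axis and direction. (Applying the formula to the pooled overall
statistics instead gives values up to ~0.15 mm different; the published
overall row matches neither convention exactly at 0.1 mm, and the
mean-of-margins convention is adopted.)

Reported distances are rounded to 0.1 mm, half away from zero; machine
outputs (CSV/JSON) keep full precision.

## Synthetic cohort generator

No patient-level data accompany the reference analysis, so the generator
emulates the study population from its printed per-segment statistics:

* Total expiration displacement `d ~ Normal(mu, sd)` per segment/axis, with
  (mu, sd) defaulting to the published 20-patient per-segment amplitudes
  (e.g. S7 SI: 8.6 ± 3.4 mm). Segments and axes are independent — no
  covariances are published — with an optional per-patient shared scaling
  factor (`shared_scaling`, default off) to mimic breathing-depth
  correlation.
* Helical sampling fraction `u ~ Normal(0.42, 0.15)` truncated to [0, 1],
  one draw per patient (one helical scan per patient):
  `helical = phase0 + u·d`. The snapshot is assumed to catch the breath at a
  normally distributed point of the excursion; the mean 0.42 is calibrated
  so that the implied helical->phase0 and helical->phase50 mean splits
  (-0.42·mu and 0.58·mu) reproduce the published splits for the
  large-motion segments (S7 SI: -3.6 and 5.0 mm).
* Segment reference positions are a fixed, documented 9-point layout laid
  out like the Couinaud arrangement; only displacements enter any statistic,
  so these coordinates are arbitrary.
* Lung volumes scale a published per-state mean table by a per-patient size
  factor `~ TruncNormal(1, 0.15)` (plus 2% per-side jitter shared across
  states); the helical-state volume interpolates between the phase volumes
  at the same fraction `u`, so the physiological bracket
  `phase50 <= helical <= phase0` holds by construction.
* The breathing surrogate is a raised-cosine cycle peaking at the cycle
  start (end-inspiration), period 4 s, amplitude 10 a.u., with independent
  truncated-normal cycle-to-cycle amplitude (10%) and period (5%) jitter,
  sampled at 20 Hz for 20 cycles. The maximum phase error at gated phase p
  is the range over cycles of the surrogate value at fraction p/n_phases of
  each cycle, normalised by the mean peak-to-peak cycle amplitude — a
  documented emulation of a gating system's cycle-variability report, not a
  reproduction of any vendor's internals.

What the generator does **not** emulate: deformable-registration error
(printed SDs absorb it, so simulated helical->phase SDs come out smaller
than published ones), hysteresis between inhale and exhale trajectories,
intra-/inter-fraction drift, non-normal displacement tails, and any
image content (no voxels, no DICOM). Passing tests therefore demonstrate the
statistical machinery on a faithful distributional stand-in, not performance
on real CT registrations; the published whole-liver overlap indices
(0.94/0.96) and patient lung volumes depend on the unavailable images and
are not reproduction targets.

## Coverage simulation

Each replicate generates a fresh cohort, derives the full margin table, and
scores each segment/axis cell a success if the model's *true mean*
helical->phase0 and helical->phase50 displacements (-E[u]·mu and
(1-E[u])·mu, with E[u] the exact truncated-normal mean) both lie in
[neg, pos]; containment uses a 1e-9 mm tolerance so zero-variance point
margins are not failed by rounding noise. The per-lesion reading —
individual simulated displacements inside the margins — is reported as a
separate column (`per_tumor_pct`), since a t-interval for a mean makes no
promise about individual excursions (it lands near 50% at the default
noise).

A structural caveat the simulation exposes: the product form `u·d` couples
the mean and the spread of the per-pair displacement (a patient sampled
near phase 0 has both a small helical->phase50 mean and a small SD), so the
per-pair displacements are not normal and the one-sided t-interval miss
rate exceeds the nominal 2.5% at n = 20. Pooled over all segments, axes and
replicates the success rate stays at or above 95% (the LR cells, whose true
means sit near zero, gain slack from the clamp), but individual
large-motion SI/AP cells can dip a few points below the nominal rate. With
the helical fraction held fixed (`helical_fraction_sd=0`) the displacements
are exactly normal and every cell meets or exceeds 95%, which is the
closed-form t-interval check in the test suite (clamp off, single phase,
coverage = 95% within Monte-Carlo error).

Problem sizes: the default validation run uses 200 replicates of 20
patients; the headline coverage number and tests use 1000 replicates, and
parameter-recovery checks use a 2000-patient cohort (sample means within
3·sd/√n, SDs within 10%).

## Numerical and interface choices

* Reproducibility: all randomness flows through one `numpy` Generator;
  a fixed integer seed gives bit-identical cohorts, traces and reports.
  Truncated-normal draws use the inverse-CDF transform of uniforms so
  vectorised and scalar paths agree.
* Degenerate inputs: sd = 0 is allowed everywhere (point intervals, zero
  half-widths); n < 2 is rejected wherever an SD is needed; traces need at
  least 2 complete cycles for a phase error and at least 3 when generated.
* Serialisation: cohort CSV has a fixed header
  (`patient_id,segment,helical_lr,...,phase50_si`), floats at 17
  significant digits for bit-exact round trips; UTF-8 BOM and CRLF inputs
  are accepted. A JSON mirror bundles points, lung volumes and the drawn
  helical fraction. Run reports embed the seed and a hash of the
  scientific configuration (the output directory is excluded from the
  hash), so a report can be reproduced from its own metadata.
* The CLI (`livermotion simulate|amplitudes|margins|validate|run-all`) is a
  thin layer over the library; logs go to stderr, reports to files/stdout.

## Known limitations

* Margins guarantee (approximate) coverage of the cohort-mean motion only;
  clinical use would add setup-error (PTV) margins, which are out of scope.
* The helical-fraction law is a calibrated guess (the acquisition is only
  known to sample the cycle "randomly"); its mean/SD are configurable.
* Breathing traces are uncorrelated with the drawn displacement magnitudes;
  no such correlation is published.
* With 20 patients the t multiplier is fixed at 2.093; other cohort sizes
  use the exact quantile, which changes margins in the 0.01 mm range at
  n = 20 if overridden.
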