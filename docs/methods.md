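# Methods

This note documents the models implemented in `loudmatch`, the default
parameters and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## The quantity of interest

The *mismatch* is the headphone-minus-loudspeaker difference in sound
pressure level at the eardrum when both presentations are judged equally
loud. One mismatch value exists per subject and condition, where a
condition is a cell of the factorial design room × stimulus × headphone
presentation mode (4 × 4 × 4 = 64 conditions). All levels are dB SPL
re 20 µPa.

## Stimuli

Four signals, 1 s long with 20 ms raised-cosine (Hann) rise/fall ramps:

- `tbn250`, `tbn1000`, `tbn4000` — one-third-octave band noises with
  edges `fc·2^(∓1/6)`;
- `uen17` — broadband noise with equal energy in 17 Zwicker critical
  (Bark) bands.

Noise is synthesised in the frequency domain: independent complex-Gaussian
coefficients inside the band(s), zero outside. This gives exact band
confinement (out-of-band/in-band energy ratio is numerically zero before
ramping) and the naturally fluctuating temporal envelope the matching task
requires — narrowband envelopes are deliberately *not* flattened. Each
band's realised energy is normalised exactly, so the 17 `uen17` band
energies are equal by construction (the 0.1 dB check in the tests verifies
the FFT bookkeeping, not a stochastic property). Identical seeds produce
bit-identical waveforms; the experiment uses frozen per-stimulus seeds so
that level changes are pure rescaling.

**Band edges of `uen17`.** The critical-band definition is ambiguous in
the source material (a 20 Hz vs. a ≈250 Hz lower boundary appear in
different places). The default is Bark bands 2–18, edges 100–4400 Hz:
this yields exactly 17 bands and an upper edge matching the 4 kHz
third-octave band's upper edge. The edge list is a plain argument and can
be replaced.

**Calibration.** The loudspeaker presentation level is the SPL of a
65-phon pure tone at the stimulus centre frequency (1 kHz for `uen17`),
via the ISO 226:2003 contour equation with the standard's tabulated
parameters, linearly interpolated on a log-frequency axis. At exactly
1 kHz the identity `SPL = phon` is returned by definition of the phon
scale; the analytic contour with tabulated parameters deviates from the
identity there by up to ≈0.1 dB at moderate levels (it is exact only at
94 dB), and the definition takes precedence. All level computations use an
analysis window that excludes the ramps; a configurable `tail_exclusion`
exists for room-convolved signals (default 0, since headphone paths have
no reverberant tail).

Default sample rate 44.1 kHz (configurable; the test suite uses 16 kHz,
which comfortably contains the 4.4 kHz upper band edge and keeps FFTs
small).

## Binaural synthesis and coherence

Presentation modes: monaural (left ear only), diotic (identical channels,
IC = 1), uncorrelated (independent channels, IC = 0), IC-matched
(coherence equal to that of the loudspeaker presentation in the room).

Two generators produce a prescribed coherence c from independent noises:

- symmetric: `L = a·n1 + b·n2`, `R = a·n1 − b·n2`, `a = sqrt((1+c)/2)`,
  `b = sqrt((1−c)/2)`;
- left-preserving: `L = s`, `R = c·s + sqrt(1−c²)·n2`.

Both keep each channel's variance equal to the input variance and have
expected zero-lag correlation c. They are *not* equivalent signal-wise:
only the left-preserving variant keeps the left headphone channel
identical to the loudspeaker signal, which is the convention of the
experimental design; it is therefore the default in experiment
simulation, with the symmetric generator selectable. The independent
right-channel noise is seeded deterministically (stimulus seed + 1000)
for reproducibility.

Coherence estimation conventions: for generator validation, the signed
zero-lag Pearson correlation over the analysis window; for measured or
room-like signal pairs, the IACC (maximum absolute normalised
cross-correlation over ±1 ms). For the broadband stimulus the IC-matched
scalar is the mean of the room profile across the 17 bands (the bands
carry equal energy, so the energy-weighted mean reduces to the plain
mean).

## Eardrum levels

**Headphone path.** The stimulus waveform is filtered with each of the
eight HpTF instances (re-seatings) separately, the windowed RMS computed
per instance, the RMS values averaged arithmetically, and the result
converted to dB. This propagates repositioning variability into the level
estimate the same way it enters the listening test. For monaural
presentation only the presented (left) ear is evaluated.

**Loudspeaker path.** In anechoic rooms the calibrated free-field
waveform is filtered with the frontal free-field HRTF. In reverberant
rooms the sound field mixes direct sound and reverberation, modelled by
the room-matched HRTF

    |H_room(f)|² = (1 − w)·|H_ff(f)|² + w·|H_df(f)|²,

optionally multiplied by a per-band heuristic correction. Choices made
here:

- "weighted average of the magnitudes" is ambiguous between the amplitude
  and power domain; the power domain was chosen for consistency with
  every other average in this module (HpTF power average, diffuse-field
  power average).
- `w` is a single broadband scalar per room, fitted by least squares in
  dB over the four stimuli's levels at a reference head, using a 10⁻³
  grid search over [0, 1] plus bounded local refinement (the objective is
  smooth and 1-D; the grid step guards against the optimiser settling on
  a shoulder). Residual spectral structure is the job of the optional
  band correction, defined as measured-minus-modelled dB per band — by
  construction it zeroes the reference-head error.
- Magnitude-only responses (anything power-averaged) are applied in the
  spectral-energy domain with zero phase; phase-bearing single instances
  are applied as complex filters. Both paths agree within 0.1 dB on
  band-limited noise (asserted in the tests); complex responses are
  interpolated in magnitude and unwrapped phase so that |H| is preserved
  between grid points.
- The diffuse-field HRTF is the power average over directions, weighted
  by cos(elevation) (the solid-angle density of a regular
  azimuth/elevation grid) when incidence angles are available, unweighted
  with a logged warning otherwise.

The model's declared range of validity is 0.25–4 kHz, the band of the
stimuli; the transfer-function grid must cover at least 100 Hz–8 kHz.

## The adaptive procedure

1-up-1-down alternative forced choice: the headphone level rises after
"loudspeaker louder" and falls after "headphone louder", converging on
the 50% point of the listener's psychometric function. Steps shrink
10 → 5 → 1 dB after the first and second *upper* reversals. The start
level lies 15–30 dB (uniform) below the expected match, guaranteeing
"loudspeaker louder" initially — together with the large first step this
brackets the match and removes start-level bias (verified: mean recovered
match varies < 0.5 dB across start offsets of 15–40 dB).

Bookkeeping conventions where the procedure description is silent:

- The measurement phase begins when the 1 dB step takes effect (at the
  second upper reversal); that triggering reversal itself still belongs to
  the bracketing phase and is discarded.
- The equal-loudness level is the median of the six pooled measurement
  reversal levels (three upper + three lower). The alternative reading —
  the mean of the two per-direction medians — differs by < 0.5 dB in
  simulation.
- Presentation-order alternation has no effect on a memoryless simulated
  listener and is therefore not modelled.
- Levels clip at a 0/110 dB floor/ceiling (logged); non-convergence
  within 100 trials returns a flagged, not raised, result.

With 1 dB decision noise the procedure converges in typically 10–20
comparisons and recovers the true 50% point with < 0.3 dB mean error over
200 runs; a small positive bias of ≈0.1 dB remains because the first
measurement reversal always arrives from below.

## The synthetic scenario

The virtual listener is an *inverse* model of the observed mismatch
structure — a scenario device for exercising the pipeline, not a loudness
model. Its internal equal-loudness headphone playback level in a
condition is

    L_int = L_eq0 + base(room, stimulus) − slope·(IC_room − IC_hp)
            + gain·[monaural],

where `L_eq0` is the playback level that would exactly equalise left-ear
eardrum levels (computed through the subject's own transfer functions),
and each trial's verdict adds Gaussian decision noise (SD 1 dB).
Monaural trials carry no coherence term. Defaults (dB):

| parameter | mean | between-subject SD | rationale |
|---|---|---|---|
| base, tbn250 | 6.0 | 2.0 (shared shift) | low-frequency mismatch of several dB |
| base, tbn1000 | 5.0 | — | similar to 250 Hz |
| base, tbn4000 | 1.0 | — | mismatch largely vanishes at 4 kHz |
| base, uen17 | 0.0 | — | no broadband mismatch |
| room offset, AC_anechoic | +2.6 | — | between-anechoic-chamber site effect |
| coherence slope | 4.0 | 1.0 | diotic vs. matched differs by a few dB in reverberant rooms |
| monaural gain | 7.0 | 1.0 | binaural-summation analog, 5–9 dB |
| decision noise SD | 1.0 | — | yields 10–20 trials to convergence |

The subject-level shift is a single scalar added to all conditions of a
subject, which produces the strong across-condition correlation of
individual mismatches (diotic vs. room-matched r near 1). There is no
quantitative model linking interaural coherence to loudness; the linear
slope is an assumption of the scenario.

Synthetic ears: smooth log-magnitude curves (random-phase cosine series,
which have exactly the target pointwise SD and are stationary in log
frequency) riding on a 12 dB ear-canal-resonance peak near 2.5 kHz.
Targets: 3 dB between-subject and 1 dB within-subject SD in 0.25–4 kHz
(re-seating jitter grows to 3 dB above 4 kHz). HRTFs are ~0 dB at low
frequency with a pinna/concha gain near 3 kHz.

Rooms: the coherence profile mixes coherent direct sound with the ideal
diffuse field of two points spaced 0.17 m apart (speed of sound 343 m/s):
`IC(f) = (DRR + |sin x / x|)/(DRR + 1)`, `x = 2πfd/c`, clipped to [0, 1].
The free/diffuse mix weight of the room-matched model is the diffuse
energy fraction `1/(1 + DRR)`. The four default rooms are two anechoic
chambers (DRR → ∞, IC = 1) and two reverberant rooms (T30 0.395 s and
0.574 s, DRR 0.25 and 0.15 — the listening position sits beyond the
reverberation radius, so the reverberant field dominates).

Design: 27 subjects per site, 14 of them cross-site (sharing identity,
ears and traits across sites), so 40 distinct subjects and
14×64 + 26×32 = 1728 rows. Cross-site site effects enter through the
per-room offset of the trait configuration.

**What the generator does *not* emulate** — and hence what passing tests
do not show about real data: no real loudness model (no spectral
summation, no binaural loudness-summation mechanism; the monaural gain is
an implanted constant); no visual or cognitive room effects beyond the
scalar room offset; no headphone leakage, placement-dependent coloration
beyond smooth log-magnitude jitter, or transducer distortion; transfer
functions are smooth by construction and lack real notch structure; no
trial-to-trial learning or lapses (the decision noise is iid Gaussian).
Parameter recovery on this scenario demonstrates that the pipeline is
internally consistent, not that the scenario's numbers describe any
particular population.

## Statistical analysis

- Mismatch uses left-ear levels for both sources by default (the stimuli
  are referenced to the left ear); a per-ear-mean convention is available
  and differs only when the ears are asymmetric.
- Per-condition one-sample t-tests against zero, two-sided, Bonferroni
  ×64, α = 0.05.
- Three-way fixed-effects ANOVA (statsmodels OLS, Type II sums of
  squares) with all interactions; repeated measures are pooled as
  replicates, matching the denominator degrees of freedom of the original
  analysis style (a mixed model is out of scope). Under the all-null
  scenario the per-term type-I error is ≈5% (verified over 200 replicate
  simulations).
- Room marginal contrasts: per-subject room-marginal means compared
  between rooms with Welch two-sample t-tests, Bonferroni ×6. Two-sample
  rather than paired because site-exclusive subjects visit only their own
  site's rooms.
- Mode pairwise tests: paired t-tests within each room × stimulus cell;
  the Bonferroni family is the six mode pairs of one cell (per-cell
  family), with the total comparison count reported for transparency.
- Correlations are Pearson; apparent-source-width ratings live on the
  −50..50 scale and out-of-scale rows are rejected.

Parameter-recovery checks compare recovered quantities against the
*realised* implanted values of the simulated population (the mean of the
sampled subject traits), not the configured population means — with 27
subjects and a 2 dB between-subject SD the two differ by sampling error
of ≈0.4 dB, which is a property of sampling, not of the pipeline.

## Numerical conventions and edge cases

- dB reference 20 µPa throughout; calibration is exact scalar scaling
  (idempotent to < 0.01 dB).
- Filtering is spectral multiplication (circular); signals are ramped to
  zero at the edges, so wrap-around is negligible.
- Degenerate inputs fail loudly and specifically: bands beyond Nyquist,
  non-ascending edges, silent analysis windows, coherence outside [0, 1],
  mismatched transfer-function grids, empty ANOVA cells, singleton
  conditions. Exceptions: a non-converged staircase and an unidentifiable
  room weight (free-field ≡ diffuse-field prediction, returns w = 0) are
  flagged/logged instead, since both occur in legitimate runs.
- Problem sizes in the test suite are scaled for a desk run: 16 kHz
  sample rate, 6 subjects per site for integration fixtures, 27 per site
  for the end-to-end recovery check, 200 replicates × 4 subjects for the
  null-calibration check.

## Known limitations

- The room model (scalar w + band correction) underrepresents rooms with
  prominent early reflections; the heuristic correction absorbs the
  reference-head error but individual deviations remain unmodelled.
- The ANOVA pools repeated measures; subject-stratified inference would
  need a mixed model.
- SOFA reading covers the common HRIR/headphone-IR layouts
  (`SimpleFreeFieldHRIR`, `GeneralFIR`, `SimpleHeadphoneIR`) via the HDF5
  container; exotic conventions are rejected by name.
- Binaural room impulse responses, auralization, and loudness-model
  backends are out of scope.
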