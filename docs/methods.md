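# Methods

## The measurement problem

One large EV (0.2–1.3 μm) is positioned on a neuron by optical tweezers
and followed by phase-contrast imaging at 2 Hz for up to 20 minutes.
The quantities of interest are per-EV: how far and how fast it travels,
how intermittent the motion is, whether it moves at all beyond a
tethered jitter, and in which direction along the neurite it drifts.
Cohorts are then summarized as percentage ± SEM across independent
experiments. Everything downstream of the raw movie is implemented
here; the synthetic generator closes the loop so each stage can be
checked against a known truth.

## Motion model (synthetic generator)

A surfing EV is modelled as a two-state renewal process:

- **GO**: displacement along the neurite axis at a constant per-EV run
  speed `v ~ U(0.011, 0.412) μm/s` (the observed speed range), for an
  exponential dwell (mean `go_dwell_mean_s = 20 s`).
- **STOP**: no directed displacement, for an exponential dwell (mean
  `stop_dwell_mean_s = 20 s`). The first state is drawn from the
  stationary renewal probability, so a 50/50 dwell ratio yields a
  moving-time fraction of 0.5 in expectation.

Run direction per GO interval: anterograde/retrograde EVs keep a fixed
sign but each run is a *short* reversal (mean dwell / 4) with
probability 0.1, so realized run-length ratios straddle the 2× decision
boundary realistically; bidirectional EVs resample the sign per run
with equal probability. No dwell-time statistics are published for this
system; the 20 s exponential dwells are a modelling choice that
reproduces intermittency at the observed ~45–55% moving-time scale.

Superimposed on the directed component (and the whole of a static EV's
motion) is **tether-confined Brownian jitter**: a per-axis reflected
random walk with diffusion coefficient `D = 1e-3 μm²/s`, folded into a
square of half-width `R/√2` so the radial bound `R` holds strictly.
`D` is anchored on the observed static-EV behaviour — a mean radial
displacement of ~1.8 μm over 20 min implies `√(4·D·1200) ≈ 2 μm`, i.e.
`D ≈ 1e-3`, while per-2.5-s displacements stay below the stop/go
threshold (stops genuinely read as "0 displacement" at the analysis
sampling). Static EVs use `tether_radius_um = 2.0`; mobile EVs in STOP
intervals use a tighter `stop_confinement_um = 0.3` (pauses show
radial motion, but at a smaller scale than a free tether). Localization
noise is additive Gaussian, `jitter_sigma_um = 0.05` per frame per
axis.

Ground truth bookkeeping: `true_path_length_um = v × total GO time`
(directed transport only — tether jitter is real motion but is excluded
so the identity is exact); the static sub-label (virtually immobile vs
tethered Brownian) is assigned from the realized noise-free excursion
vs the EV diameter, i.e. by the same rule the classifier targets.

**What the generator does not emulate:** phase-contrast optics (the
camera model is a Poisson spot on flat background), EV jumps between
neurites (rare, unquantified), multi-EV fields, axis curvature changes
during a recording, stage drift, and photobleaching. Passing recovery
tests therefore validates the *analysis chain*, not the imaging
physics of real recordings.

## Tracking

Per-frame localization: matched-filter candidate test (peak of a
PSF-scale-smoothed window against the border-ring background plus 3×
the photon noise surviving the smoothing), then intensity centroid,
then least-squares fit of a symmetric 2D Gaussian + constant. A
post-fit amplitude filter (amp ≥ 3× raw robust SD) rejects shot-noise
artefacts; the residual false-positive rate on empty windows is a few
per cent, which the linking distance gate absorbs. Linking is greedy
nearest-neighbour (one spot per movie), with the gate widened
proportionally while bridging up to `max_gap_frames` missing frames;
persistent loss terminates the track and returns the prefix. Pixel
coordinates are continuous with the origin at the centre of pixel
(0,0). The apparent diameter is the fitted FWHM (2.3548 σ · pixel
size) floored at 0.2 μm — below that the image is diffraction-limited.

## Metrics

All headline metrics are computed after resampling to the 2.5 s
analysis interval (the sample nearest each multiple of 2.5 s; first and
last frames always kept). Native-rate metrics are available by passing
`interval_s=None`.

- **Path length**: Σ of consecutive Euclidean distances.
- **Signed excursions**: positions are projected to arc length on the
  neurite polyline (nearest point; `shapely`), re-zeroed at the contact
  point's projection, signed positive away from the soma. Points
  farther than 3 μm from the axis are rejected as projection failures.
  Run lengths split Σ|Δs| by the sign of Δs.
- **Mean speed** = path length / *total* recording time (pauses
  included). This is the reading under which a mean run length of
  143 μm per 20 min (0.119 μm/s) coexists with a mean speed of
  0.126 μm/s; dividing by moving time only would roughly double it.
- **Stop/go**: an interval is "go" iff its 2D displacement exceeds
  `motion_eps_um`. Default ε = 0.2 μm = 2× the RMS 2D displacement
  noise at the default localization σ (each coordinate difference has
  noise σ√2; the RMS 2D step noise is 2σ = 0.1 μm). A smaller ε equal
  to 2σ itself would flag e⁻¹ ≈ 37% of true stop intervals as motion;
  at 2× the RMS the false-go rate is e⁻⁴ ≈ 2%. The flip side: run
  segments slower than ε/2.5 s ≈ 0.08 μm/s are partly missed, a real
  resolution limit at this sampling and noise level.
- **Radial displacement**: mean over samples of the distance from the
  contact point (a time-average at uniform sampling). The maximal
  version is available as `max_dist_contact_um`.

## Classification

- **MSD exponent**: time-averaged MSD for lags up to 25% of the record;
  α is the least-squares slope of log MSD vs log lag **on ~25
  log-spaced lags**. Linear lag spacing would concentrate the fit at
  the longest lags, where a bidirectional EV's run directions have
  decorrelated and its MSD grows diffusively — log spacing weights
  every decade equally and preserves the run-scale ballistic signature
  that separates mobile EVs from tethered Brownian ones. Degenerate
  (zero-variance) records return α = 0.
- **Mobility rule**: static_immobile if max distance from contact ≤ EV
  diameter (a *moving* EV is one displaced by more than its diameter,
  so ties go static); else static_brownian if α ≤ α* = 1.3; else
  mobile. α* is a calibration of this package, not a published value:
  pure diffusion gives α ≤ 1 regardless of confinement, stop-and-go
  runs push α toward 2, and 1.3 splits the two with margin.
- **Direction rule**: anterograde if run_pos > 2 × run_neg, retrograde
  symmetrically, else bidirectional (equality at exactly 2× is
  bidirectional). Run lengths, not maximal excursions, feed this rule.

## Cohort aggregation

Percentages are computed per experiment first; mean and SEM
(SD/√N, ddof = 1) are taken across experiments, matching the
"n EVs, N experiments" reporting convention. A single-experiment group
reports SEM 0 with a flag. Contingency percentages are rounded half-up
to integers only in the recapture table output; full precision is kept
everywhere else.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use 10 experiments × 20 EVs
(full 20-min, 2 Hz trajectories) for parameter recovery, 100 seeded
random trajectories for oracle equivalence, and 20 rendered stacks of
100 frames at SNR ≈ 10 for tracking accuracy — sizes at which the
binomial/Monte-Carlo error bands in the tests are meaningful for the
cohort rates being recovered.

## Known limitations

- Run speeds below ~0.08 μm/s are at the noise floor of the 2.5 s
  stop/go segmentation; their moving-time fraction is underestimated
  and a few of the slowest mobile EVs are classified static_brownian.
- The direction rule inherits stop-interval jitter in both run-length
  sums, biasing very slow anterograde/retrograde EVs toward
  bidirectional.
- The measured mean speed includes a localization-noise contribution to
  path length (quadrature inflation of each 2.5 s step), a small
  positive bias relative to the noise-free speed.
- One EV per recording is assumed throughout; there is no multi-particle
  association, drift correction, or 3D localization.
- Between-group hypothesis tests are not re-implemented; standard
  routines (e.g. `scipy.stats.mannwhitneyu`) apply directly to the
  per-EV metric tables this package writes.
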