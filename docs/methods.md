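# Methods

`graspspace` simulates and analyses a delayed grasp-to-hold experiment in
which three cortical populations — parietal AIP, premotor F5 and primary
motor M1 — are recorded while a primate grasps 50 object conditions, and the
hand's 27 joint angles (J-space) are tracked at 50 Hz.  The scientific
question the analysis chain addresses is whether a population codes objects
in *visual* terms (shape, size) or in *motor* terms (the hand configuration
used to grasp), two descriptions that are normally confounded because shape
largely determines grip.

## Task and condition catalog

The catalog holds 50 conditions identified by two-digit codes: six parametric
shape families (rings, cubes, spheres, horizontal/vertical cylinders, bars)
at six sizes (15–40 mm), a mixed turntable of average-sized objects, six
abstract forms, and precision/power grips on a single handle (codes 00/01).
Two dissociations are built in by construction:

* **Same grip, different vision.**  The six abstract objects look different
  (each has its own visual identity slot) but share one identical grasp
  prototype.
* **Same vision, different grip.**  Handle conditions 00 and 01 share the
  visual stimulus but sit at opposite ends of one posture direction in
  J-space — the most distant condition pair by construction.

Trial timing follows the task: fixation 500–800 ms, cue 700 ms (object
illuminated), planning 600–1000 ms in the dark, a go cue, reaction
(150–250 ms), movement (fixed at 300 ms; the duration is not otherwise
constrained by the task description), hold 500 ms.

## Generative model of spiking

Each unit fires as an inhomogeneous Poisson process with intensity

    rate(t) = max(0, baseline + env(epoch(t)) * [ v_gain * v(c) * gate(t)
                                                 + m_gain * m(theta) ])

where `v(c)` is a unit-specific linear readout of the condition's visual
features (one-hot shape identity weighted 4:1 over normalized size, so shape
dominates size), `m(theta)` is a unit-specific linear readout of the trial's
standardized 27-channel hold posture, `env` is a per-epoch envelope, and
`gate` switches the visual drive on `latency_s` after cue onset and
multiplies it by `dark_gain` after cue offset (lights off).  Gains are in Hz
and equal the between-condition standard deviation of the drive they scale.
Negative intensities are rectified at zero — the simplest link; an
exponential link would avoid rectification bias but complicates the
closed-form checks.

Area presets: AIP is visual (v_gain 6 Hz, m_gain 0.5 Hz, 50 ms latency,
dark gain 0.6 — coding maintained at reduced gain in the dark); F5 splits
into a ventral (F5a-like) subpopulation (40% of units, mixed visual/motor,
80 ms lag, transient visual sharing with dark gain 0.15, planning envelope
0.8) and a dorsal (F5p-like) subpopulation (motor only, envelope ramping
0.1/0.3/1.0 across cue/plan/move); M1 is execution-only (envelope exactly 0
before movement onset, m_gain 6 Hz).  Baselines are Gamma(4, 2.5) (mean
10 Hz); per-unit gains carry a lognormal (sigma 0.4) spread.  Default
populations are 70/80/90 units (240 total, inside the 200–350 range of the
recorded sessions) with 10 trials per condition.

Because the programmed intensity is piecewise constant within a trial,
spikes are drawn exactly: Poisson counts per constant-rate segment, uniform
times within the segment.  This is distributionally identical to thinning on
a 1 ms grid and roughly an order of magnitude faster.

Kinematics: each trial's trajectory moves from rest to the condition
prototype with a smooth cosine transport over the movement epoch and stays
there through the hold; the realized hold posture is the prototype plus
i.i.d. N(0, (2 deg)^2) per-channel noise, constant within the trial (so two
same-condition trials differ by ~N(0, 2 sigma^2) per channel in J-space).

### Calibration of the AIP visual gain

The visual-latency estimator (below) has two opposing structural biases: the
symmetric 50 ms smoothing kernel leaks the cue response backwards in time
(early bias), while units only cross the sliding-ANOVA significance
threshold once enough of the ramping effect has accumulated (late bias).
The two cancel when the typical asymptotic effect is about twice the
detection threshold.  A one-time calibration sweep (visual gain 4, 6, 8 and
12 Hz over three seeds) located this regime at 6 Hz between-condition rate
s.d. for the default population size; 4 Hz recovers the 50 ms programmed
latency ~20 ms late and 8 Hz ~12 ms early.  The AIP preset is fixed at 6 Hz
and not treated as a free parameter.

## Analysis chain

* **Rates and alignment.**  Spike trains are smoothed with a Gaussian kernel
  (sigma 50 ms for sliding statistics on a 1 ms grid; sigma 300 ms on 10 ms
  bins for the feature correlation), truncated at 5 sigma (<1e-6 mass).  No
  padding is applied at trial edges (documented small downward bias).
  Because the planning epoch has variable duration, trials are *doubly
  aligned*: a cue-onset-aligned segment (default −0.2 to 1.0 s) is
  concatenated with a go-aligned segment (default −0.2 to 0.9 s); trials
  whose span cannot cover the windows are dropped with a warning.
* **N-space and J-space.**  The N-space is the trials × units matrix of mean
  epoch rates minus each trial's mean fixation rate (fixation is the only
  epoch guaranteed stimulus-free, hence the baseline).  The J-space is the
  trials × 27 matrix of mean hold-epoch joint angles after a zero-phase
  Kaiser-window FIR low-pass (passband configurable within 5–20 Hz, default
  10 Hz).  Both share one trial ordering.
* **Modulation depth / ANOVA.**  MD(c1,c2) = |mean rate difference|; pair
  separation uses one-way fixed-effects ANOVA plus the Tukey–Kramer
  studentized-range criterion (p < 0.01, unbalanced group sizes allowed,
  critical values from numerically integrated studentized-range quantiles).
* **Sliding ANOVA and latency.**  A classic (non-Welch) one-way ANOVA per
  unit and 1 ms step, no multiple-comparison correction; the population
  curve is the fraction of units with p < 0.01.  Visual response latency is
  the time from cue onset until the curve's first crossing of 75% of its
  post-cue peak (peak searched in the cue epoch).  The "population peak
  activity" is read from the fraction-tuned curve; a flag switches the peak
  search window.
* **CDA.**  Canonical discriminant analysis solves the generalized
  eigenproblem of between- vs within-condition scatter; components are
  within-class-whitened, ordered by eigenvalue, each axis oriented so its
  largest loading is positive.  Separation percentages are eigenvalue shares
  (the variance-of-projected-data reading of "explained variance" is
  available by flag).  The within scatter is shrunk toward its diagonal when
  requested or ill-conditioned; the automatic intensity is the Ledoit–Wolf
  estimate computed on within-class residuals.  With trials >> units (the
  default sessions) the automatic intensity is near zero.
* **Mahalanobis + HCA.**  Condition geometry in the full N-space uses
  Mahalanobis distances between condition means under the pooled
  (optionally shrunk) within-condition covariance; agglomerative average
  linkage with deterministic lowest-leaf-id tie-breaking produces
  dendrograms (exported as Newick, leaves at depth height/2).  Cluster
  purity is the fraction of parametric-family objects sharing a cluster
  with another object of the same shape at a six-cluster cut.
* **Procrustes.**  The N-space is reduced to the highest common dimension
  with the J-space (CDA scores, 27 components when the population supports
  it; otherwise the J-space is PCA-reduced to match) and aligned to the
  J-space by translation + rotation, by default also with uniform scaling
  and reflection allowed.  The dissimilarity d = min SSD / total centred
  variance of the reference is 0 for a perfect similarity match.  Note a
  tension in the source method description: it names only translation and
  rotation yet reports d values that can approach or exceed 1, which the
  scaled fit cannot exceed — both modes are first-class here
  (``allow_scaling`` / ``allow_reflection`` flags).
* **Feature-code correlation.**  Per 10 ms bin, the Euclidean distances
  between all trial pairs form an m × m modulation pattern per area; the
  strict upper triangles of two areas' patterns are rank-correlated
  (Spearman) per bin.  Bins with constant distances yield missing values,
  never zero.  Rates here are not baseline-subtracted (flag available).
  Ordinal ranks are used (continuous distances make ties a null set).

## What the generator does and does not emulate

The synthetic sessions reproduce the *structure* the analyses rely on:
epoch-locked condition-dependent firing, visual/motor dissociations, an
M1 population that is a noisy linear image of J-space, transient visual
sharing in ventral F5, and Poisson trial-to-trial variability.  They do not
emulate real features such as heterogeneous single-unit latencies,
non-Poisson count dispersion, slow drifts, correlated noise across units,
eye-movement or reach variability, or the continuum of real grip strategies.
Passing tests therefore demonstrate that the analysis chain recovers known
ground truth under its own model assumptions, not that the biological
effect sizes would be reproduced on real recordings — the real-data headline
values are treated as qualitative orderings (e.g. M1 > F5 > AIP motor
similarity), and those orderings are what the acceptance checks assert.

## Numerical choices and problem sizes

Kernel truncation 5 sigma; FFT convolution for kernels wider than 10 bins
(negative ringing clipped at zero); half-up rounding of window offsets keeps
half-sample alignment consistent across trials; Tukey–Kramer critical values
are cached per (alpha, k, df); HCA ties break on the lowest leaf id;
CDA axes flip to a positive largest loading.  Degenerate inputs: zero
within-group variance flags the ANOVA result and separates unequal-mean
pairs; a constant reference matrix makes Procrustes dissimilarity undefined
(error), a constant target returns d = 1.

Replicated checks run 20 default sessions for parameter/ordering recovery
and 20 reduced null sessions (30 units) for the sliding-ANOVA calibration;
the acceptance script reports medians/means over 6 default sessions, 3 of
them carried through the feature correlation, and 8 null runs.  These sizes
give Monte-Carlo errors comfortably below the effects being asserted (e.g.
s.e.m. of the recovered latency ~1.5 ms against a ±10 ms band).

## Known limitations

Rectification at zero slightly compresses programmed rate differences for
units with strong negative drives; the latency estimator is only unbiased
in the calibrated SNR regime (that regime is part of the study design); the
Ledoit–Wolf intensity is derived for an identity target but applied toward
the diagonal; purity is computed at a fixed six-cluster cut; the CLI's
multi-session averaging treats sessions as exchangeable (no animal-level
hierarchy).
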