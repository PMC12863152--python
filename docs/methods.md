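# Methods

## The model

Resting-state EEG microstate analysis treats the multichannel signal as a
sequence of brief (~50–120 ms) periods during which the scalp topography is
quasi-stable, each period belonging to one of a small number of classes —
canonically four, labeled A–D.  This package implements the full analysis
chain and a generative counterpart of it, so that every stage can be tested
by recovering known ground truth.

### Analysis chain

1. **Preprocessing** (`signal`): each 2-s epoch is band-pass filtered 2–20 Hz
   with a 3rd-order Butterworth applied forward–backward (zero phase; the
   double pass squares the magnitude response, giving gain 1 ± 0.01 across
   the band and ≥20 dB attenuation one octave outside it), then
   re-referenced to the instantaneous whole-scalp mean.  The moderate order
   is deliberate: zero-phase ringing grows with order, and at 4th order it
   outlasts a typical 80-ms microstate dwell, measurably blending adjacent
   states into the GFP-peak topographies (template recovery degrades from
   |r| ≥ 0.995 to ~0.93 on noise-free synthetic data).  The order is
   configurable.  Acquisition-stage
   cleaning (broadband prefilter, notch, ICA, artifact rejection, bad-channel
   interpolation) is assumed to have happened upstream; the pipeline treats
   its input as clean epoched EEG.
2. **GFP peaks** (`signal`): global field power is the spatial standard
   deviation of the average-referenced map at each sample (population form,
   divisor C — the field-standard Lehmann–Skrandies definition; some texts
   loosely say "variance").  Only topographies at strict local maxima of GFP
   within an epoch enter clustering: plateaus count once at their first
   sample, epoch-boundary samples are excluded, and no minimum-distance or
   prominence constraint is applied by default (both are available).
3. **Clustering** (`cluster`): polarity-invariant AAHC at fixed K=4 per
   subject.  Every peak map starts as its own cluster; the cluster with the
   smallest global-explained-variance contribution is repeatedly dissolved
   and its members reassigned to the surviving cluster with the highest
   absolute spatial correlation.  Cluster centroids are the first principal
   direction of the member maps — the correct polarity-invariant average,
   since plain averaging would cancel sign-reversed members.  Ties (equal
   contributions, equal correlations) go to the lowest cluster index, and
   input order is fixed, so runs are deterministic.
4. **GEV** (`cluster`): with GFP weight g_t and correlation r_t between peak
   map t and its assigned template, GEV = Σ(g_t·r_t)² / Σg_t².  Per-class
   terms partition the numerator.
5. **Two-level templates** (`cluster`, `labeling`): individual template maps
   are pooled within each group and re-clustered by the same AAHC at K=4
   (uniform weights) to give group templates — the standard formalization of
   "group average template maps" (plain label-wise averaging after sorting is
   available as an alternative through the library).  Group templates are
   sorted against a canonical A–D atlas by optimal one-to-one assignment
   (Hungarian; for K=4 this equals exhaustive search over the 24
   permutations, which the tests verify), then each subject's own maps are
   sorted against their group's sorted set.  Individual maps are *not*
   sorted against the atlas directly; the atlas anchors only the group
   level.
6. **Backfit** (`backfit`): every GFP peak takes the label of its
   best-correlating (absolute value) individual template; ties go to the
   lowest class index.  The categorical labels are expanded to a continuous
   stream by the nearest-peak rule — each sample takes the label of its
   closest peak in time, an exact midpoint going to the earlier peak; samples
   before the first/after the last peak of an epoch inherit that peak's
   label; epochs without peaks stay unassigned.  ("Linear interpolation" of
   categorical labels can only mean this midpoint split.)  No temporal
   smoothing and no minimum-duration rejection by default.
7. **Parameters** (`parameters`): per subject and class, mean **duration**
   (ms), **occurrence** (onsets/s of labeled time) and **coverage** (fraction
   of labeled time), plus the K×K segment **transition matrix** counted
   within epochs only and row-normalized (conditional probabilities; a
   joint-frequency mode exists because published transition percentages use
   either convention).  Runs cut by an epoch boundary are excluded from mean
   duration by default — they are censored observations of a dwell — but
   count toward occurrence and coverage.  With `include_truncated=True`
   every run counts everywhere and the identity
   coverage = occurrence × duration/1000 is exact.
8. **Statistics** (`stats`): the SES composite averages the two parents'
   education (1–5) and occupation (1–10) scores into family scores, z-scores
   each across the sample (divisor n−1), and sums them; the extreme-group
   rule takes the top and bottom ⌈0.27·n⌉ as high/low groups (ties broken by
   subject id).  Pearson correlations relate SES to each parameter.  Each
   parameter family gets a two-way mixed repeated-measures ANCOVA —
   between-subject group, within-subject class, covariates age and a binary
   gender code — computed by the univariate split-plot approach: subject
   means regressed on [1, group, age, gender] for the between part, and
   within-subject deviations analyzed in an orthonormal (Helmert) contrast
   space with class, class×covariate and class×group terms.  Covariates are
   mean-centered and group effect-coded, so the class main effect is
   evaluated at the covariate means; no sphericity correction is applied.
   For 29+29 subjects this yields the df pattern F(1, 54) between and
   F(3, 162) within.  Partial eta² = SS_effect/(SS_effect+SS_error).  Post
   hoc group contrasts are per-class ANCOVAs with the p-value multiplied by
   K=4 (capped at 1).  Transition probabilities are compared per ordered
   pair by pooled-variance Student's t-tests, unadjusted (12 tests at K=4);
   Welch and Holm/Bonferroni variants are flags.  Covariates that are
   constant or perfectly aliased with the group factor are dropped by a rank
   check rather than crashing the fit.

## The synthetic generator

`synth` emulates the study's recording regime: 60 channels of the 10-10
system, 1000 Hz, 2-s epochs, ~4 min per subject, two groups of 29.

* **Templates** are parametric patterns over the 2-D projected montage:
  left–right and right–left diagonal gradients (A, B; direction cosines
  ±0.8, 0.6), an anterior–posterior gradient (C) and a fronto-central
  Gaussian maximum (D), all average-referenced and unit-norm.  Pairwise
  |r| ≤ 0.59 — deliberately not orthogonal, matching the moderate
  similarity of real canonical maps.
* **Label dynamics** are semi-Markov: segment classes follow a row-stochastic
  transition matrix with zero diagonal, segment lengths a geometric (or
  optionally gamma) dwell law with per-class means (defaults 80/70/90/75 ms,
  field-typical).  By default dwell times are quantized to half carrier
  periods so that state switches fall on carrier zero crossings — i.e. at
  GFP troughs, where real topographies change.  Without this, segments
  shorter than the inter-peak spacing would be undetectable *in principle*
  (no GFP peak falls inside them) and dwell recovery would be biased for any
  implementation.
* **Rendering**: sample t is `template[label(t)] · sin(2πft) · gain` plus
  spatially white Gaussian noise scaled so total signal power over noise
  power equals `snr`.  The signed 10-Hz carrier keeps all signal energy in
  the 2–20 Hz analysis band and makes the emitted topography alternate
  polarity within a state — exactly the physical property that motivates
  polarity-invariant analysis.  At unit SNR the 2–20 Hz filter removes most
  of the broadband noise, so backfits recover ≥90 % of samples; this mirrors
  the favorable effect of narrowband filtering on real data.
* **Cohorts**: group presets apply multiplicative offsets to dwell means and
  transition entries (rows renormalized).  The low-SES preset encodes the
  reported direction of effects — class-A dwell ×1.3, A↔B and A↔D switching
  ×1.4, B↔C and C↔D switching ×0.7 — which raises A's duration, occurrence
  and coverage and lowers C's occurrence and coverage in that group.  Only
  directions are anchored; the published figures are graphical, so effect
  *sizes* are this package's choice.  Subjects get multiplicative log-normal
  jitter (σ = 0.1) on dwell means and transition entries and a private
  derived seed; identical cohort seeds give bit-identical recordings.
* **Demographics** are synthesized per group (parental education/occupation
  ranges, age ≈ N(19.6, 1.7²) clipped to 17–26, ~64 % female), and a
  full-range survey generator drives the extreme-group split with one latent
  family-SES factor.

What the generator does **not** emulate: 1/f background spectra, ocular and
muscle artifacts, volume-conduction forward modeling, inter-channel noise
correlation, non-stationarity across the session.  Passing recovery tests
therefore show the *pipeline's* correctness and statistical behavior under a
clean generative model, not robustness to real-world artifacts.

## Numerical choices

* GFP peak subsampling: AAHC runs on at most 1000 evenly spaced peaks per
  subject by default (~4800 are available in 240 s); final assignment and
  GEV use all peaks.  Evenly spaced sampling keeps all epochs represented.
* Eigen-decomposition of the 60×60 member scatter gives centroids; singleton
  clusters are handled lazily.  Centroid signs are canonicalized (largest
  absolute channel positive) so output is invariant to input sign flips and
  covariant under channel permutation.
* Filter edge handling: epochs shorter than the forward–backward padding
  (~3× the filter span) are dropped with a logged count.
* Degenerate inputs: flat maps are rejected in correlation/clustering and
  left unassigned in backfitting; transition rows with no outgoing
  transitions are all-zero and flagged; classes with no counted segment get
  NaN duration.
* The vectorized segment-level cohort sampler used by the calibration
  studies draws from the same semi-Markov law as the per-sample generator
  (validated by equivalence tests); it exists so thousand-replicate
  type-I-error studies run in minutes.

## Problem sizes used in tests and the acceptance script

Study scale throughout: 29+29 subjects, 240 s each at 1000 Hz.  Monte-Carlo
calibration uses 1000 null replicates and 300 contrast replicates at the
segment level (3000 segments/subject).  Smoke tests in the unit suite use
smaller cohorts (6–12 subjects, 20–60 s); template recovery bounds are
asserted at study scale only, because per-class template quality degrades
when a class covers little of a short recording.

## Known limitations

* AAHC's greedy atomization can permanently dissolve a class represented by
  very few low-GFP maps; exactness versus exhaustive search is only
  guaranteed for separable, adequately populated fixtures.  Relatedly, when
  a group preset makes one class strongly dominant (the low-SES contrast
  puts ~2.3x more GFP peaks in class A than in class C), a minority of
  subjects' fits split the dominant class and absorb a scarce one, inflating
  group-mean duration error to ~5-8% even without sensor noise.  Recovery
  guarantees are therefore stated for offset-free dynamics; contrast cohorts
  are validated through the statistical layer (calibration and power), which
  is robust to these subject-level fit errors.
* The univariate RM-ANCOVA applies no sphericity correction; under strongly
  heterogeneous class variances its within-subject tests can drift from
  nominal level (the calibration study bounds this at the default
  conditions).
* GEV values on synthetic data (~85–95 %) are higher than typical empirical
  values (~70–80 %): the generator's maps are exactly four templates plus
  white noise, whereas real EEG contains non-microstate structure.
* The EDF writer emits plain 16-bit EDF (one record/s, integer sampling
  rates, no annotations) — sufficient for interchange with standard readers,
  not a general-purpose EDF library.
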