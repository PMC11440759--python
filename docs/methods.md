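# Methods

## The model

`stephen` classifies minute-epoch wrist-wearable output into four latent
physical-activity states — sedentary, standing/light activity (LPA),
moderate (MPA) and vigorous (VPA) — with an explicit-duration hidden
semi-Markov model (HSMM).

Per minute *t* the device reports a step count and a heart rate. Given the
latent state *k*, both are modelled as conditionally independent Negative
Binomial (NB) variables in mean/dispersion form,

    X | state k  ~  NB(mu_k, r_k),   Var X = mu_k + mu_k^2 / r_k,

so the dispersion `r` interpolates between heavy-tailed (`r` small) and
Poisson (`r` large). Heart rate is rounded to the nearest non-negative
integer before evaluation, since bpm exports may be fractional. The time
spent consecutively in a state (the sojourn) follows a Gamma distribution
discretised onto whole minutes,

    p(d) ∝ F(d) − F(d−1),  d = 1..d_max,

renormalised over the truncation window. Unlike the geometric sojourns of a
plain HMM, the Gamma sojourn represents persistent bouts directly — a long
standing spell with a stable, slightly elevated heart rate is one sojourn,
not a run of lucky self-transitions. On leaving a state the next state is
drawn from a zero-diagonal row-stochastic transition matrix (the standard
semi-Markov identifiability constraint).

Two variants share this machinery:

* **STEPHEN** — bivariate emissions (steps and heart rate);
* **STEPCODE** — the steps-only ablation, used to isolate what heart rate
  contributes.

### Why heart rate matters

Wrist devices register spurious steps during sedentary wrist movement
(folding laundry, gaming). Those minutes carry step counts that look like
activity but a heart rate that does not move. During model fitting the
sedentary state then absorbs the bursts as a heavy-tailed step distribution
(small `r`) anchored by the flat heart rate; during decoding, a burst minute
inside a sedentary bout stays sedentary rather than splitting the bout.
A steps-only model has no anchor, which degrades both the proportion of
time sedentary and — much more — the sedentary bout-length distribution.

## Estimation

Models are fitted **per subject** by EM on the explicit-duration forward /
backward recursions (implemented in log space, with numba kernels for the
O(T·K·d_max) inner loops). Observation streams are split into contiguous
segments at non-wear gaps; each segment restarts from the initial-state
distribution. The final sojourn of each segment is right-censored by
default: it contributes a survival term P(D ≥ observed remaining length)
instead of a pmf term, so long bouts in progress at the end of a wear period
are not penalised. The censored sojourns enter the E-step as survival
weights, so duration estimates are not biased downward either.

M-steps: the NB mean has the closed-form weighted-mean maximiser; the NB
dispersion and the Gamma sojourn (shape, scale) are maximised numerically
on the exact weighted objective, starting from the current parameters and
keeping the better of (current, optimised). Every block therefore never
decreases the EM objective — the likelihood trace is monotone up to
floating-point noise (asserted at 1e-8 in the tests). Emission means are
floored at 1e-3 and dispersions clamped to [1e-2, 1e6] to avoid degenerate
states.

### Initialisation

EM on this likelihood has genuinely attractive bad optima (e.g. merging the
two rare high-intensity states and splitting the heavy sedentary mass), so
initialisation is deliberate:

* minutes are grouped on a **3-minute running median** of the step count.
  States persist for minutes while step artifacts are isolated, so the
  median assigns burst minutes to their sedentary neighbourhood; the NB
  moment estimates (computed from the *raw* counts per group) then start
  exactly in the burst-absorbing basin described above;
* the first restart assigns each minute to the nearest of K centres spread
  **evenly across the log1p-step range** (deterministic). Mass-weighted
  centres — plain quantile groups or converged k-means — put several
  centres into the zero-step mass and merge the top states;
* further restarts draw k-means++ centres (two Lloyd steps only, for the
  same reason) under the run's seed, and jitter the moment means by
  U(0.8, 1.25);
* the best restart by final log-likelihood wins.

With the defaults (3 restarts) fits are reproducible given the seed and
recover well-separated 4-state parameters reliably.

### Labelling, bias adjustment, ensembling

Fitted states are unordered, so they are labelled by sorting on
(mean step count, then mean heart rate): the lowest becomes SEDENTARY, the
rest STANDING_LPA, MPA, VPA in order. An exact tie on both keys is treated
as a degenerate fit and raises rather than guessing.

To predict a subject the model was not trained on, each member model's
heart-rate means are shifted by the **resting-heart-rate bias** — the
target's mean HR over zero-step minutes minus the training subject's — so
the member's HR scale matches the target. Subjects with no zero-step
minutes fall back to the lowest step-count decile (with a warning). Each
member then decodes the target with the Viterbi algorithm (same censoring
convention, ties broken toward the lower state index then the shorter
duration, making decoding deterministic), its states are mapped through its
label map, and the per-minute **majority vote** across members gives the
final label. Vote ties go to the lowest-intensity label — conservative for
sedentary detection and deterministic.

## Sedentary metrics

* **Proportion of time sedentary** — sedentary minutes over worn minutes
  (predictions), or sitting seconds over recorded seconds (posture
  referent).
* **Usual bout duration (UBD)** — the bout length above and below which
  half of all sedentary time is accrued: the duration-weighted median of
  the bout durations (lower median on ties; an interpolated variant is
  available). Bouts are maximal runs of sedentary minutes, broken by any
  timestamp gap; bouts are pooled across the whole record per subject.

## Agreement statistics

Per-subject (estimate, referent) pairs are summarised by: absolute
percentage error with median (MDAPE) and IQR (linear-interpolation
quantiles); mean bias with Bland–Altman 95 % limits of agreement
(bias ± 1.96 × sample SD) and a proportional-bias OLS of the differences on
the pairwise means (slope, 95 % CI, p); TOST equivalence (max of the two
one-sided one-sample t p-values; margins ±0.05 for proportions, ±5 min for
UBD); and a paired Wilcoxon signed-rank comparison of two methods' APEs
(exact null for n ≤ 25 without ties, normal approximation with continuity
correction otherwise; zero differences dropped). The composition table
reports mean (SE) sitting/standing/stepping seconds per predicted class,
aggregated within subject first and then across subjects.

## Data handling

Minute CSVs are kept on a strict minute grid; duplicate minutes are an
error and missing minutes stay missing. A minute with zero or absent heart
rate is non-wear and is removed, as is the half-open window
[midnight, 05:00) where wear is unrepresentative of waking behaviour.
Daylight-saving misalignment between devices is handled as a user-supplied
constant minute offset (the inputs are timezone-naive local stamps).
Posture events are apportioned onto minutes by exact overlap with
[t, t + 60 s). Valid days require ≥ 600 worn awake minutes, ≥ 500 steps and
< 95 % of worn time in a single activity class; valid-day gating of model
training is exposed as a choice and off by default, since the minute stream
itself needs no minimum daily wear.

## The synthetic-data generator

The generator produces the paired data the validation design needs —
a device-like minute stream and a posture-events referent — from a known
4-state semi-Markov truth. Defaults (chosen as physiologically plausible,
well separated fixture values): step means 0.2 / 5 / 40 / 110 per minute
with dispersions 0.5 / 1 / 5 / 10; HR means 65 / 75 / 95 / 120 bpm with
dispersion 30; Gamma sojourn means 25 / 10 / 8 / 4 min truncated at
d_max = 60; two 960-minute days per subject starting 06:00 (about the 15 h
of daily wear typical of continuously worn trackers); per-subject
resting-HR offsets uniform on ±10 bpm; non-wear gaps Poisson(1)/day with
geometric mean length 20 min, stamped as zero HR; spurious contamination
adds an independent NB(mean 30, dispersion 2) burst to each sedentary
minute with probability `spurious_prob` while leaving heart rate, the true
labels and the referent events untouched. The referent events merge
consecutive same-label minutes (sitting = sedentary, standing =
standing/LPA, stepping = MPA/VPA) at 0.1 s resolution.

What the generator does **not** emulate: minute-to-minute HR
autocorrelation, circadian drift, HR-affecting medication, postural change
without step or HR signature, device-specific step-detection quirks, or
referent (posture logger) error. Passing tests therefore demonstrate
internal correctness and the direction of the heart-rate mechanism under
the model's own assumptions — not field accuracy on real cohorts.

## Numerical and design notes

* d_max defaults to 240 min for user-facing models (negligible truncated
  mass for realistic bouts); the synthetic experiments use d_max = 60 with
  sojourn means ≤ 25 min, and simulator and fitter share the same
  truncated, discretised sojourn law, so the generative model and the
  fitted family coincide.
* Cohort-scale experiments in the test-suite and the acceptance script use
  2-day subjects (~1,900 worn minutes), 11 training + 20 test subjects,
  and single-restart ensemble fits; parameter-recovery checks use one
  11-day subject (~10,500 minutes). These sizes were chosen so the whole
  study runs comfortably on one CPU while leaving the conclusions
  unchanged at larger sizes.
* EM convergence: relative log-likelihood change below `tol` (default
  1e-6); maximum 200 iterations.
* Fitting an over-provisioned K to structureless data (one iid NB stream,
  K = 2) legitimately *splits* the distribution into lower/upper
  components — that is the maximum-likelihood solution, not a failure; the
  occupancy-weighted mean still recovers the stream mean.
* Viterbi and majority-vote tie-breaks, quantile conventions, and the
  Bland–Altman x-axis (pairwise means) are fixed as documented above so
  every pipeline output is bit-reproducible given a seed.

## Known limitations

* Only the sedentary/non-sedentary boundary is validated by design; the
  STANDING_LPA / MPA / VPA split is emitted but untested against any
  referent.
* The resting-HR bias adjustment assumes HR differences between subjects
  are additive shifts; it cannot correct scale differences (e.g. beta
  blockers compressing HR range).
* Majority voting operates on labels after per-member labelling; members
  whose state spaces fit poorly simply get outvoted, but a systematically
  mislabelled ensemble (e.g. trained on one atypical cohort) will not
  self-correct.
* The bias-shift equivariance of predictions (shifting every target HR by a
  constant leaves STEPHEN output unchanged) holds exactly only up to the NB
  family not being closed under shifts; in practice decoded paths are
  unchanged for realistic shifts, and the property is exercised in the
  tests.
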