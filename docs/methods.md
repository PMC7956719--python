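# Methods

This note records the models, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Synthetic ECG generator

**Beat model.** A beat is the sum of five Gaussian bumps, one per fiducial
wave (P, Q, R, S, T), each with an amplitude (mV), a center offset relative
to the R peak (ms) and a width (ms). The R center is fixed at 0 and anchors
the beat. This is the simplest generative model whose fiducial ground truth
is exact by construction, which is what the detector and feature tests need.
It deliberately omits wave asymmetry (real T waves are skewed), PQ/ST
segment structure, and any coupling between heart rate and wave shape.

**Subject sampling.** `generate_subject_morphology(seed)` draws each
parameter from bounded physiologic ranges (heart rate 55–80 bpm, R amplitude
0.8–1.6 mV, T peak 200–320 ms after R, etc.). Two constraints are enforced
jointly with the heart rate so the generator stays consistent with the
downstream search windows: the P center is placed inside
`(−RR/6, −RR/10)` with a 30% margin on each side, and the T center inside
`(RR/10, RR/2)` with a 40 ms margin. Without this, a fast heart rate could
push a physiologically normal P peak outside its own search window and the
generator's ground truth would be unrecoverable by design rather than by
failure.

**Rhythm.** RR intervals are the subject's mean RR plus independent Gaussian
jitter (s.d. 15–40 ms), truncated at ±3 s.d. and floored at 250 ms. This
produces realistic RR-feature variance but not a realistic HRV spectrum
(no respiratory modulation, no long-range correlation) — out of scope.

**Day-to-day drift.** `DriftSpec` holds per-day multiplicative amplitude
factors and additive center shifts applied to the non-R waves (shifting the
R wave would just relabel beat time). Day 1 is required to be the identity.
The default is linear: amplitude factor `1 − 0.04·(day−1)` (day 6 → 0.80)
and center shift `+2 ms/day`. The scale was chosen once, as a realistic
session-to-session morphology change of a few percent per day reaching ~20%
over six days; with it, the synchronized-average beat RMSE versus day 1
rises monotonically (≈0.01 → 0.06 mV for a mid-amplitude subject),
reproducing the qualitative day-over-day growth seen in multi-day ECG
studies. The magnitudes are free parameters of the generator, not a fit to
any particular recording.

Because the drift is deterministic and shared by every beat of a day, a
whole day's beats cross a decision boundary together. This is the main
infidelity to real data and explains the sharp stage transitions in the
protocol results (e.g. TAR 0% → ~100% between stages): real intra-day
variability would smooth these curves. Passing the protocol tests therefore
shows that the *update machinery* tracks drift, not that these particular
TAR values transfer to clinical recordings.

**Noise.** Additive white Gaussian noise (default s.d. 0.02 mV) plus a
sinusoidal baseline wander (default 0.1 mV at 0.25 Hz). Every record is a
pure function of its seed.

## Preprocessing

A linear-phase windowed-sinc FIR bandpass, 1–35 Hz, Hamming taper. The
nominal order is 5383; it is forced even (5384 internally) so the group
delay is an integer number of samples, and the delay is compensated by
reflect-padding half the filter length on each side and convolving in
"valid" mode. The contract is the frequency response (flat within ±1 dB
over 2–30 Hz, below −40 dB at 0.2 Hz and 100 Hz for fs = 1000 Hz), not
coefficient identity — any design meeting the band spec would do. Whether
the original acquisition compensated delay or filtered bidirectionally is
unknown; delay compensation was chosen so that fiducial sample indices in
the filtered record align with the raw record's ground truth.

## Fiducial detection

QRS detection follows the Pan–Tompkins chain: 5–15 Hz bandpass, five-point
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds with a 200 ms refractory period and searchback at 1.66× the
running RR average. Two implementation choices: the stages are applied
zero-phase (filtfilt / centered kernels) so no group-delay bookkeeping is
needed, and every threshold is derived from the data itself, which makes
detection exactly invariant to amplitude rescaling (property-tested). The
R location is refined to the signal maximum within ±75 ms of the integrated
peak.

Q and S are the local minima nearest to R within ±60 ms on each side; the
half-width is an implementation choice (the source method reports detected
Q/S without a formula). P and T are signal maxima over the open intervals
`(R − RR/6, R − RR/10)` and `(R + RR/10, R + RR/2)`, where RR is the
record-global average R-to-R interval in ms. Open-interval bounds are
converted to samples and rounded inward (floor+1 / ceil−1), so located peaks
are strictly inside their windows; argmax ties break to the earliest sample.
Whether the RR average should be global or running is unspecified in the
source method; global is used. Beats whose windows leave the record (first
and last) are dropped and counted.

## Features

13 features per beat, fixed order: amplitudes `amp_XY = signal(Y) −
signal(X)` in mV (so `amp_RS` is typically negative — the sign convention is
fixed and documented rather than inferred); intervals in ms, with `int_RR`
taken to the *next* beat's R (the final beat is dropped, never imputed); and
vertex angles at Q, R and S between rays to the flanking peaks. An angle
mixes ms and mV, so amplitudes are scaled by an aspect constant (default
100 ms/mV, configurable) before the arccos; angles are reported in degrees.
Degenerate beats (collinear points give 180°, non-positive intervals) are
flagged invalid and dropped by the table builder. Feature extraction is
invariant to time translation and amplitude offset, and covariant under
amplitude scaling exactly as the aspect-plane formula predicts
(property-tested against an independent atan2 oracle).

## Incremental SVM

The solver follows Cauwenberghs–Poggio exactly: a new sample with
`y·f(x) > 1` is stored in the reserve set untouched (bit-identical
coefficients, by test). Otherwise its coefficient grows in the largest steps
that trigger no KKT event; at each step the margin-set coefficients and the
bias move along the direction obtained from the margin-system solve

```
[ 0    y_S^T ] [db      ]     [ y_c    ]
[ y_S  Q_SS  ] [dalpha_S]  = -[ Q_Sc   ] dalpha_c ,
```

and the step ends at the first of: the candidate reaching the margin
(joins S), the candidate reaching C (joins E), a margin coefficient hitting
0 (→ R) or C (→ E), or an error/reserve sample's margin value reaching 0
(→ S). Numerical choices:

* **Kernel convention** `K = exp(−||x−y||²/σ²)`; the other common convention
  divides by 2σ². sklearn's `gamma` equals `1/σ²` here. Defaults C = 7,
  σ = 2.
* **Jitter** `1e-10` on the margin-system diagonal guards near-singular
  systems (duplicate margin vectors, which SMOTE synthetics make likely);
  a failed solve falls back to a regularized least-squares direction.
* **Empty margin set**: only the bias can move; it slides toward the
  violating sample until it or a stored error/reserve sample lands on the
  margin and seeds S. Initial training seeds the state with one sample per
  class solved in closed form.
* **Caching**: kernel columns of margin/candidate samples are cached and
  extended lazily; per-event work is O(n·|S|) without materializing any
  n×|S| matrix. Margins `g_i` are maintained incrementally during events;
  the audit recomputes them from scratch, so bookkeeping drift cannot hide
  from the tests.
* **Event cap** 100 000 per increment; exceeding it raises a diagnostic
  error with a state dump (never observed in the suite).
* **Degenerate curvature** (candidate identical to a stored margin vector):
  the candidate can still progress to the box bound or trigger migrations;
  ties at zero step length resolve through the migration events.
* Ties at `f = 0` decide "accept".

Decremental unlearning is not implemented (samples are never removed on the
default path); an off-by-default `prune_reserve(threshold)` discards reserve
vectors with `y·f` above a threshold, trading exactness of future updates
for memory.

The batch reference (`batch_qp_oracle`) solves the same soft-margin dual
with libsvm, then *polishes* the solution: with the E/R assignment fixed,
the margin coefficients and bias are recomputed from the KKT equalities by
one linear solve. This removes libsvm's solver slack (~1e-6 in the margins)
so the oracle passes the same strict audit as the incremental state, and the
returned state supports further increments. It is the independent route in
every equivalence test, never the implementation.

SMOTE is the classic formulation: each synthetic point is
`x + u·(n − x)`, `u ~ U[0,1]`, `n` one of the k = 5 nearest minority
neighbours; the minority class is grown to the majority size. Balancing is
applied on day 1 only by default (a per-day flag exists); whether the
original protocol re-balanced later days is unknown.

## Protocol

Per subject: positive = the subject's beats, negative = pooled beats of all
other subjects. Features are z-scored with statistics frozen from the
subject's day-1 training pool — a scale that shifted with each day would
silently re-train the kernel geometry under the model. Day-1 training
presents the balanced set in a seed-derived shuffled order (final state is
order-independent; property-tested). Days 2–5 are presented beat-by-beat in
chronological order. After each stage the model is scored on (a) the
held-out day 6 and (b) the day after the latest trained day; the final
stage's "next day" is day 6 itself, since no day 7 exists. All imposter
beats of the test day are used (no subsampling). Decisions are per single
beat; a majority-vote aggregator exists behind `vote_window` but is off by
default and excluded from the acceptance surface.

The batch baseline trains one libsvm model per subject on exactly the
samples the incremental route saw (same day-1 balanced set, same seed path,
days 2–5 appended), so the comparison isolates the solver. Since the RBF
soft-margin dual has a unique decision function, the two routes agree to
solver precision and the observed ACC difference is 0.0 points.

The template baseline stores the mean standardized day-1 positive vector;
a beat is accepted when its RMS distance over the 13 standardized features
is at most 3.0 (pooled-s.d. units), and each accepted presented beat —
genuine or imposter, which is the scheme's known forgetting failure —
drags the template by rate 0.1. Threshold and rate are not specified by the
source method; both are config-exposed and only the directional FAR
comparison is asserted.

The timing benchmark pre-trains a ≥5000-sample model via the batch oracle
(whose output is a valid incremental state) and times 100 incremental
additions against one batch refit. The benchmark set uses moderate class
overlap so that error vectors are a small fraction (~10%) of stored
samples, matching the authentication regime; under heavy overlap (error
fractions near 40%) both routes slow down and the comparison degenerates
into measuring libsvm's shrinking heuristics rather than the update
mechanism.

## Problem sizes

Defaults mirror the modelled study (11 subjects × 6 days × 10 min at
1000 Hz). The test suite and acceptance script run the protocol at
11 × 6 × 2 min (~9 300 beats cohort-wide, ~8 800 increments per subject
model), the KKT-invariant run at 500 sequential increments with a full
audit after each, solver equivalence at n ∈ {40, 100, 200} × 5 seeds on
50×50 grids, and fiducial recovery on 11 × 60 s clean records. These sizes
were chosen so the whole suite completes in a couple of minutes while every
claim is still exercised at meaningful scale.

## Known limitations

* The generator's drift is deterministic and cohort-wide homogeneous; real
  drift is stochastic and subject-specific. Protocol numbers are therefore
  directional, not forecasts.
* Gaussian bumps underestimate the difficulty of P/T delineation on real
  ECG (low-amplitude P waves, biphasic T waves, muscle noise).
* The per-record global RR average misbehaves under strong arrhythmia;
  arrhythmia is explicitly out of scope.
* The incremental solver stores every sample ever seen (exactness requires
  it); memory grows linearly with data unless `prune_reserve` is enabled,
  which forfeits the exact-equivalence guarantee.
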