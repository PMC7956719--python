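# ecgauth

Adaptive ECG-based biometric authentication with an incremental support
vector machine.

## The problem

The electrocardiogram is a usable biometric: the shape of a heartbeat — the
P wave, the QRS complex, the T wave — differs from person to person and is
hard to spoof because it can only be measured on the body. It is also
unstable: a subject's beats drift from day to day with physical and
emotional state, so an authentication model trained once degrades. Retraining
from scratch on every new recording session is expensive, and the cost grows
with the accumulated data.

`ecgauth` implements the alternative: per-subject one-vs-rest SVM models that
are **updated online** as new beats arrive, using the Cauwenberghs–Poggio
incremental SVM. Each new labelled beat is integrated exactly — not
approximately — by perturbing the existing solution while keeping every
stored sample's Karush–Kuhn–Tucker condition satisfied:

```
alpha_i = 0      =>  y_i f(x_i) > 1      (reserve vectors, beyond the margin)
0 < alpha_i < C  =>  y_i f(x_i) = 1      (margin support vectors)
alpha_i = C      =>  y_i f(x_i) < 1      (error vectors, violating the margin)
```

with `f(x) = sum_i alpha_i y_i K(x_i, x) + b`,
`K(x, y) = exp(-||x - y||^2 / sigma^2)` and `sum_i alpha_i y_i = 0`.
A beat already classified beyond the margin (`y f > 1`) is stored in the
reserve set and changes nothing; any other beat triggers an adiabatic
coefficient update with exact bookkeeping of migrations between the margin
(S), error (E) and reserve (R) sets. The result after any sequence of
increments equals the batch solution on the same data, independent of
arrival order — full retraining becomes unnecessary.

## The pipeline

| stage | module | what it does |
|---|---|---|
| synthesis / I/O | `ecgauth.synthio` | multi-subject, multi-day synthetic ECG with known R-peak ground truth and controllable day-to-day drift; plain-text record I/O |
| preprocessing | `ecgauth.preprocess` | linear-phase FIR bandpass, 1–35 Hz, order 5383 (even-forced), delay-compensated |
| fiducial points | `ecgauth.fiducial` | Pan–Tompkins QRS detection; Q/S as nearest local minima within ±60 ms of R; P and T as maxima of RR-scaled windows `(R−RR/6, R−RR/10)` and `(R+RR/10, R+RR/2)` |
| features | `ecgauth.features` | 13 features per beat: PR/QR/RS/RT amplitudes, PR/QR/RS/RT/ST/RR intervals, vertex angles at Q, R, S |
| learning | `ecgauth.isvm` | the incremental SVM, a batch QP oracle for cross-checking, SMOTE class balancing, KKT auditing |
| experiment | `ecgauth.authpipe` | day-1 training, day-2–5 incremental updates, per-beat ACC/FAR/TAR on two test schedules, batch and template-update baselines, timing benchmark |

Authentication is scored per single beat with the standard biometric rates
(in percent): accuracy `ACC = (TP+TN)/total`, false acceptance rate
`FAR = FP/(TN+FP)` and true acceptance rate `TAR = TP/(TP+FN)`.

## Worked example

`examples/` contains one short script per capability. The headline one:

```sh
python examples/05_authentication_protocol.py
```

```
cohort: 5 subjects, 1930 beats featurized

cohort averages, day-6 test, after training through each day:
 stage   ACC  FAR   TAR
     1 80.00  0.0  0.00
     2 80.00  0.0  0.00
     3 80.00  0.0  0.00
     4 96.76  0.0 83.01
     5 99.94  0.0 99.67

pooled batch baseline ACC: 99.94%  (incremental day-5: 99.94%)
```

Reading it: the day-1 model rejects essentially all of the target's day-6
beats (TAR 0%) because the synthetic morphology has drifted for five days;
as the model absorbs days 2–5 incrementally, TAR climbs to 99.7% while FAR
stays at zero, and the final incremental model matches the accuracy of a
batch SVM retrained from scratch on all five days pooled. The synthetic
drift is systematic (every beat of a day drifts together), which makes the
stage-to-stage transitions sharper than on real recordings; the direction of
the effect is the point.

And the solver itself (`examples/04_incremental_svm.py`):

```
incremental sets: {'R': 63, 'S': 18, 'E': 39}   (S=margin, E=error, R=reserve)
batch oracle sets: {'R': 63, 'S': 18, 'E': 39}
max |f_incremental - f_batch| on a 50x50 grid: 7.88e-10
KKT audit: clean   sum(alpha*y) = -1.4e-14
```

A thin CLI mirrors the pipeline:
`ecgauth simulate | filter | detect | features | run-protocol` (see
`ecgauth --help`).

## Scope

Synthetic data stands in for clinical recordings (the study design this
mirrors used private 11-subject, 6-day recordings). Out of scope: Bayesian
hyperparameter search (fixed `C = 7`, `sigma = 2`), wavelet/deep feature
alternatives, multi-lead synthesis, arrhythmia robustness, and public-
database evaluation (external beats can still be fed in as CSV feature
tables). See `docs/methods.md` for the model details and design decisions.
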