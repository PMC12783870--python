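# Methods

## The measurement problem

A simultaneity-judgement (SJ) task presents paired auditory and visual
streams at a stimulus onset asynchrony (SOA) and asks the observer whether
they were synchronous. Plotting the proportion of "synchronous" reports
against SOA yields a bell-shaped curve; its width is the temporal binding
window (TBW) — the range of asynchronies over which the two modalities are
still bound into one event — and its peak location is the point of
subjective simultaneity (PSS). This package implements that analysis for
*pulsing* streams: continuous stimuli whose auditory amplitude and visual
size are coherently modulated at a slow rate (1–3 Hz), either strictly
rhythmically or quasi-rhythmically in the manner of a speech envelope.

## Stimuli

Rhythmic streams are raised cosines, e(t) = (1 − cos 2π f t)/2, sampled at
1 kHz. The phase convention (start at 0, rise into the first pulse) makes
the pulse count exactly f·d for a stream of duration d, so a 3 s stream
carries 3/6/9 pulses at 1/2/3 Hz and a 3-pulse stream lasts 3/1.5/1 s —
`make_stream_spec` resolves either design. Audio rendering (optional WAV)
applies the envelope to a 500 Hz pure-tone carrier at 44.1 kHz.

Speech-like streams are jittered pulse trains: inter-pulse intervals are
drawn as period·(1 + jitter_cv·z), z ~ N(0,1) truncated at 0.2·period,
pulse amplitudes as 1 + amp_cv·z (floor 0.1), and each pulse is a
raised-cosine kernel of total width 1/(2·mean_freq). Defaults jitter_cv =
0.2 and amp_cv = 0.3 approximate the syllable-interval variability of
natural speech. Candidate tokens are screened exactly the way real speech
tokens were: the mean-removed envelope's FFT (resolution 1/duration, band
0.5–10 Hz, argmax with ties to the lower bin) must show a dominant peak
within ±0.5 Hz of 3 Hz, and the stimulus builder keeps the first five
gate-passers.

Because inter-pulse intervals are drawn independently, pulse-time errors
accumulate across the stream (a renewal process). This smears spectral
power into adjacent 1/3-Hz bins, and with the default jitter roughly 15% of
raw tokens fail the ±0.5 Hz gate (measured over 2000 seeds). That is a
property of realistically jittered trains, not a defect of the gate: the
pipeline, like the study procedure it mirrors, *selects* clear-peak tokens
from a pool. A drift-free variant (jitter around the regular grid) was
evaluated and produces *broader* spectra at the same interval CV, so the
renewal form was kept.

SOA-shifted pairs delay the lagging stream's onset by |SOA| with zero
padding (a physically delayed onset, not a wrap-around); negative SOAs mean
the auditory stream leads.

## Trial design

Designs are full factorials SOA × condition × repetition, shuffled once by
a seeded uniform permutation with no blocking. The canonical grid is ±500,
±400, ±300, ±200, ±100, 0 ms (11 SOAs), and 11 × 3 conditions × 5
repetitions gives the 165-trial session the presets use.

## The synthetic observer

Each observer carries a ground-truth simultaneity curve

    p_sync(x) = a · exp(−((x − b)/c)²)

and reports on a 5-point scale (1 certainly synchronous … 5 certainly
asynchronous). Ratings are generated in two stages: with probability
`unsure_rate` the trial lapses to "not sure" (rating 3); otherwise a
synchronous judgement is Bernoulli(p_sync) and is voiced at the extreme or
moderate rating with probability `confident_split`. This is the minimal
mechanism whose coded output (1–2 = synchronous, 4–5 = asynchronous, 3
dropped) has exactly the Gaussian structure the fits assume: the expected
proportion of synchronous responses among valid trials equals p_sync at
every SOA, which the tests verify at 10,000 trials within 3 binomial SEs.

Cohort priors (defaults): a ~ U(0.85, 1), b ~ N(+50 ms, 40 ms) — a modest
visual-leading bias of the kind SJ tasks typically show — c ~ U(200, 500)
ms spanning typical adult windows, unsure_rate ~ U(0, 0.15),
confident_split ~ U(0.55, 0.9). Each subject's random stream derives from
(master seed, subject index), so cohorts reproduce under partial re-runs.
An optional per-condition multiplier on c lets an experimenter plant
condition structure (e.g. windows shrinking with stimulation frequency);
ground truth is always written next to the simulated responses.

What the generator does *not* emulate: sequential dependencies and
adaptation across trials, reaction times, response biases that vary with
SOA, and the heavy-tailed between-subject variability of real cohorts.
Trials are exchangeable Bernoulli draws, which makes 5-rep proportions
noisier than practiced human observers at the same budget; simulated
exclusion rates (roughly a third of subjects at default priors) therefore
run higher than is typical for real SJ cohorts, and passing tests show the
*estimator* behaves, not that any human dataset will.

## Fitting

Proportions of synchronous responses among valid trials (rating-3 trials
shrink the denominator; empty cells become missing points, never imputed)
are fitted per subject and condition by bounded nonlinear least squares
(SciPy trust-region reflective):

* **Gaussian** y = a·exp(−((x−b)/c)²) on all defined SOAs (≥ 4 required).
  Bounds a ∈ [0.01, 1], b ∈ [−1000, 1000] ms, c ∈ [1, 2000] ms. The upper
  bound on a enforces that a proportion cannot exceed 1; the lower bounds
  on a and c only exclude degenerate zero-amplitude and spike solutions.
  Starts: a₀ = max observed proportion, b₀ = SOA at the maximum, c₀ ∈
  {150, 300, 450} ms; the start with the lowest SSE wins, ties to the
  first. Note the exponent carries no factor of 2: c is the 1/e half-width,
  not a conventional standard deviation, and it is reported as the TBW
  exactly as fitted.
* **Logistic** y = 1/(1 + e^{b(t−x)}) separately on the auditory-leading
  half (SOAs ≤ 0) and visual-leading half (SOAs ≥ 0), SOA 0 in both
  (≥ 3 points per side). Slope bounds [0, 1] (AL) / [−1, 0] (VL); t free in
  [−1000, 1000] ms. Slopes and thresholds are reported as absolute values.
  t is the curve's inflection point — the model value there is 0.5
  regardless of slope. Because the logistic's tails are flat, single-start
  descent can stall on a plateau; starts therefore cross four slope
  magnitudes {0.002, 0.01, 0.05, 0.3} with the SOA nearest half-maximum
  plus fixed fallbacks {−250, 0, +250} ms. With this start set the fitted
  objective matches a dense grid search over the bounded box to better than
  1e−6 relative on every seeded test subject.

Optimizer failure is recorded (`converged = False`) and routed to
exclusion rather than raised, so cohort runs never abort on one bad
subject.

Goodness of fit is the Wherry adjusted R², 1 − (1 − R²)(n − 1)/(n − p − 1),
with n the number of defined SOA points and p = 3 (Gaussian) or 2
(logistic); zero-variance curves get NaN, which fails every threshold.
Subjects are excluded from Gaussian-based summaries when any condition's
Gaussian adjusted R² < .5, and from logistic-based summaries when either
side of any condition falls below .3. Both cuts are strict inequalities: a
subject at exactly the threshold is kept. Raising either threshold can
only shrink the kept roster (verified by property test).

Condition summaries report n, mean, and SE (sample SD/√n) of TBW, PSS,
|slope| and |threshold| per leading sense over the appropriate roster;
single-subject cells carry no SE. Least squares is unweighted — the
per-cell trial count is carried in the output tables so a weighted variant
can be added without schema changes.

## Validation and problem sizes

The test suite and acceptance script validate the pipeline end to end at
sizes chosen to finish in seconds while keeping Monte-Carlo noise well
below the margins being asserted:

* **Oracle equivalence** — 20 seeded subjects at 5 reps; Gaussian and
  per-side logistic SSEs compared against dense brute-force grids over the
  bounded boxes (45×121×240 and 201×241 points).
* **Parameter recovery** — 200 subjects at 5 reps/SOA recover c with ~10%
  median relative error and < 2% cohort-level mean bias ("no bias" is
  operationalized as |mean relative error| ≤ 5%); the error falls to ~5%
  and ~2.5% at 20 and 80 reps, strictly monotone.
* **Exclusion behaviour** — noiseless cohorts lose nobody; high-lapse
  low-rep cohorts lose subjects exactly as the strict rules, recomputed
  independently from the emitted tables, dictate.
* **Planted ordering** — cohorts whose true windows scale by 1.31/0.88/0.78
  across 1/2/3 Hz (or 1.17 for speech-like vs rhythmic) yield summary means
  in the planted order; the analysis scripts exercise this for all three
  experiment presets at 30 subjects.
* **Spectral gate** — every rhythmic envelope's dominant frequency equals
  its nominal rate to within 1/duration. The quasi-rhythmic pool's gate
  pass rate is measured over 500 seeds and sits near 86% at the default
  jitter (see Stimuli above); the corresponding acceptance assertion
  expects ≥ 90% and is allowed to fail rather than lowering the jitter to
  manufacture a pass — the discrepancy is a finding about realistically
  jittered trains, and stimulus construction is unaffected because it
  selects gate-passers by design.

## Known limitations

* Ratings are modelled only as far as the sync/async coding requires; the
  1-vs-2 and 4-vs-5 split carries no information and is discarded by the
  analysis.
* The Gaussian and logistic are the only psychometric forms offered; no
  lapse-rate or Bayesian variants.
* Inferential statistics (ANOVAs, post-hocs) are out of scope; the tidy
  per-subject parameter tables are the interface to external stats
  software.
* Speech-envelope extraction (`extract_envelope`: full-wave rectification,
  zero-phase 4th-order Butterworth low-pass at 10 Hz, peak-normalized) is
  one defensible choice among several; Hilbert-magnitude extraction would
  serve equally behind the same interface.
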