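# Methods

This note documents the models, numerical choices and known limitations of
`wristbp`, in the order data flows through the package.

## Signal model (module `sim`)

The simulator generates what the downstream stages need to be testable
against ground truth, and no more.

**ECG.** Each beat is a sum of three Gaussian bumps — P (amplitude 0.15,
sd 25 ms, 180 ms before the R peak), QRS (amplitude 1, sd 12 ms) and T
(amplitude 0.3, sd 60 ms, 220 ms after) — so the R peak is the unique
dominant maximum and its true time is known exactly.  No attempt is made
at 12-lead morphology: only R-peak timing matters downstream.

**PPG.** One pulse per beat, `w(t) = (t/2τ)² exp(2 − t/τ)`: a gamma-shaped
rise with exponential decay, unit peak at `t = 2τ`.  Its first derivative
has a single dominant maximum at `t* = (2 − √2) τ` after onset — a closed
form — so each pulse is placed to make the R-peak → derivative-peak lag
equal the prescribed PTT exactly.  The feature extractor therefore has an
analytic oracle.  The time constant τ defaults to 0.12 s and shrinks by
0.2 %/mmHg of diastolic pressure above 70 mmHg, giving the morphology
features a DBP signal.  Beat-to-beat variability: RR jitter sd 20 ms, PTT
jitter sd 2 ms, amplitude jitter 5 %.

**PTT–BP coupling.** `ptt = a − b·SBP` with slope `b = 0.001 s/mmHg` and
intercept `a = 0.40 s`; the intercept varies between subjects with sd
0.005 s (≈ 5 mmHg equivalent).  That subject-level offset is deliberate:
it is the systematic device error that per-subject calibration exists to
remove, physiologically standing in for vascular-tone and anatomy
differences.

**Noise.** White noise (sd 0.02 of pulse amplitude), baseline wander
(0.1 @ 0.25 Hz), powerline (0.02 @ 50 Hz, outside both passbands) —
values chosen so nominal recordings pass QC essentially always, as clinic
recordings taken under supervision would.  `bad_contact` models unstable
optical coupling as a slow random gain flicker (low-passed noise clipped
to [0.05, 1]) plus ~25 scattered noise bursts; it distorts most beats,
which is what makes whole-measurement exclusion the right response.

**Cohort.** SBP/DBP are bivariate normal (means 129.6/69.5, SDs 23.6/12.9
mmHg, correlation 0.6 — the correlation is this package's choice),
rejection-sampled to SBP > DBP + 10 and positive PTT.  Demographics match
the validated device's study population (age 20–90 uniform, height
162.2 ± 8.6 cm, weight 67.5 ± 12.3 kg); heart rate 70 ± 8 bpm.

**Manual reference.** Each reading is taken by two virtual observers
(error sd 2 mmHg each) who re-measure until they agree within 4 mmHg; the
reported value is their mean.  Because the observers' sum is independent
of their difference, the agreement rule does not bias the reading and its
error sd is exactly 2/√2 ≈ 1.41 mmHg.  Readings are not quantized to
2 mmHg gradations, keeping the error algebra exact.

**Device noise.** In study simulations the watch *reading* is the pipeline
estimate plus N(0, 6 mmHg) per measurement (plus any subject-level device
bias under test).  This is the catch-all for what the real sensing chain
adds beyond the idealized signal model; injecting it at the reading level
keeps the calibrated error model closed-form (below).

## Preprocessing (module `preprocess`)

Bandpass: 4th-order Butterworth, run forward–backward (zero phase,
effective 8th order); PPG 0.8–11 Hz, ECG 5–30 Hz.  R-peak detection:
squared derivative smoothed over 150 ms, adaptive threshold at 30 % of the
99th percentile, 0.25 s refractory period, then refinement to the local
ECG maximum (±100 ms).  Beats span each R-peak to 90 % of the local RR
interval; the last (incomplete) beat is dropped.

Beat quality is the mean pairwise Pearson correlation of the per-beat PPG
waveforms.  Beats are compared over their common time support (all
segments truncated to the shortest before resampling to a 100-point grid);
comparing full RR-stretched windows instead would decorrelate identical
pulses under ordinary heart-rate variability.  The 10 highest-quality
beats are selected.  The measurement gate uses the minimum pairwise
correlation over *all* beats of the measurement, threshold 0.90
(boundary passes): inconsistent pulse shapes anywhere in a 24-s window
indicate unstable contact, so the whole measurement is excluded rather
than patched.  Constant (flatlined) segments are assigned correlation 0.

## Features (module `features`)

21 features per beat: PTT (derivative-peak position in the R-anchored
segment; a constant-derivative or boundary-peaked segment flags the beat
invalid); an 8-band magnitude spectrum over 0.8–11 Hz (rFFT of the
mean-removed segment, band-integrated, normalized to sum 1 — gain
invariant); seven morphology descriptors (systolic amplitude, width at
half height, rise and decay times at the 10 % level, amplitude-normalized
pulse area, maximum upslope, downslope/upslope ratio); heart rate (median
RR); and age, sex code, height, weight.  The schema is versioned
(`bpfv-1`); second-derivative indices and HRV are deliberately out of
scope.

## Outlier screening (module `screen`)

Two passes in fixed order, single-shot (no iterative re-screening):
univariate mean ± 3 SD (zero-variance features never exclude; boundary
retained), then an undercomplete autoencoder fitted to the sigma
survivors, excluding rows with reconstruction MSE above mean + 3 SD
(one-sided; numerically-zero MSEs are never anomalous).  The autoencoder
is linear with a single undercomplete hidden layer (default bottleneck
⌈d/2⌉), fitted in closed form by SVD — the global optimum of the linear
reconstruction objective, hence exactly deterministic.  Known limitation
(inherent to reconstruction-based screens): if the bottleneck leaves
spare components beyond the data's intrinsic rank, a strong outlier
direction can be absorbed into a spare component and masked; choosing the
bottleneck near the intrinsic dimension avoids this.

## Estimation network (module `model`)

Fully connected, hidden layers linear → batch norm → activation, output
layer affine with two nodes (SBP, DBP) — so predictions are an exact
linear read-out of the final hidden activations, the property calibration
relies on.  Inputs are z-scored with training statistics stored in the
model.  Training: full-batch Adam (lr 0.01) on the MSE summed over both
outputs, relative-plateau stopping (1e-6 over 10 epochs) or early stopping
on a validation fold (patience 15) during cross-validation; batch-norm
inference statistics are frozen from a full training-set pass after the
last update.  Everything is deterministic given the seed (seeded init,
no minibatch shuffling).

Architecture search: every combination in the configured space (default
1–3 layers × 8/16/32 nodes × relu/tanh) is scored by subject-grouped
K-fold CV (all beats of a subject share a fold — leakage-safe), and the
argmin is refit on all rows.  Studies in the tests and acceptance script
use a compact space (1–2 layers × 16 nodes, relu, 3-fold) and a training
cohort of 30 subjects × 3 measurements: on the synthetic coupling the
extra candidates add nothing, and these sizes keep a full study in
seconds.

Per-measurement estimates are the median over the 10 per-beat predictions
(the aggregation is this package's choice; an affine calibration commutes
with the median, so calibrating per beat or per measurement is
equivalent).

Known limitation: uncalibrated subject-level accuracy degrades for
subjects far outside the training cohort's BP range (relu nets
extrapolate linearly at best) and the network can attach weight to
demographic features that carry no signal in the generator; both errors
are subject-constant and are absorbed by calibration, mirroring how the
physical device is used.

## Calibration (module `calibration`)

Per channel, from n ≥ 3 pairs: `manual = gain·device + offset` by least
squares with ridge penalty λ(gain − 1)², λ = 2000 mmHg² by default.  With
three pairs taken minutes apart the subject's true BP is essentially
constant, so the prediction spread is noise and the gain is unidentified;
λ = 2000 against a typical noise spread of ~70 mmHg² keeps the fitted gain
within a few percent of 1 (a prior sd of ~0.14), making calibration
predominantly an offset correction.  Degenerate spreads (< 1e-9) or gains
outside (0.25, 4) fall back to gain 1 with the mean difference as offset.
The correction is bound to the model by a parameter hash and is exactly
equivalent to rescaling/shifting the output layer
(`as_output_layer_adjustment`).

**Closed-form error model.**  With constant true BP T in a session,
device reading `T + b + w` (b subject bias, w per-measurement noise, sd
`s_w`), manual error sd `s_m = 2/√2`, and offset-dominated calibration on
n pairs with expected gain `g* = λ/(λ + (n−1)s_w²)`, a new calibrated
reading errs by `g(w_new − mean(w_cal)) + mean(e_man)`:

    σ_eff² = g*² s_w² (1 + 1/n) + s_m²/n

and the expected within-±x fraction is `2Φ(x/σ_eff) − 1`
(`study.expected_within_pct`).  The subject bias b cancels exactly.  Note
the (1 + 1/n) factor: a 3-pair-calibrated device necessarily propagates
1/3 of its own noise variance into every later reading, so its within-±10
fraction is below the uncalibrated-noise bound 2Φ(10/6) − 1 by design.
The synthetic end-to-end suite checks the simulated study against this
expectation, with the pipeline's own within-subject residual (measured on
noise-free replicates) added to `s_w`.

## Validation statistics (module `validation`)

Pairing follows the alternating M,W,M,W,M,W,M sequence: each watch
reading is compared with the temporally closest of its bracketing manual
readings; exact ties go to the previous one.  Bland–Altman bias and
sample SD (n − 1) with limits bias ± 1.96 SD; accuracy bins count
|diff| ≤ 5/10/15 inclusive; RMSE uses n, so the exact identity
`RMSE² = bias² + (n−1)/n·SD²` holds and is asserted in the tests.  The
paired t-test is two-sided; r > 0.90 is flagged as high correlation; zero
variance yields explicit NaN/degenerate results, never silent defaults.
Hypertension: a reading is high iff SBP > 135 or DBP > 85 (strict, as
printed in the shipped reference table), a subject hypertensive iff ≥ 2 of
3 readings are high.  The shipped published per-subject table is not
perfectly self-consistent between its digits and its printed
classifications (two borderline cells); the printed classifications are
treated as ground truth for the concordance figure, and `reference_data`
documents both.

## What the synthetic studies do and do not show

The simulator reproduces the *structure* of the clinical validation —
protocol, pairing, calibration arithmetic, noise budgets — with a PTT→BP
law that is exactly learnable.  Passing the end-to-end suite therefore
shows the pipeline is correct and self-consistent under its stated noise
model; it does not show that PTT and pulse morphology predict human BP at
any particular accuracy, nor that the feature set matches any commercial
device's.  Dicrotic-notch hemodynamics, arrhythmias, drift between
calibration and use, and posture effects are all out of scope.
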