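# Methods

This note documents the models, conventions and numerical choices behind
`emgipa`, and what the synthetic data can and cannot establish.

## Signal conventions

Amplitudes are µV everywhere inside the package; energy alone is
converted to mV at reporting, matching how interference-pattern
summaries are conventionally printed. The default sampling frequency is
12.5 kHz and the default record length 4 s of voluntary contraction.
Loaders reject non-finite samples outright. WAV files are written as
64-bit float (1 unit = 1 µV) so that round-trips are lossless — integer
PCM would perturb sample ranks and hence the permutation entropy;
integer-PCM input is still read, with an explicit µV-per-count scale.
No digital re-filtering is applied on load. EDF channels are read
through MNE and converted from volts to µV.

## Turn detection

The Willison criterion defines a turn as a direction reversal differing
by at least a threshold (default 100 µV) from the previous and following
turns; it does not prescribe an algorithm. We use a greedy single-pass
hysteresis: track the running extremum since the last accepted turn, and
accept it the moment the trace has moved at least one threshold away
from it in the opposite direction. Because acceptance itself requires a
full-threshold excursion, consecutive accepted turns alternate
maximum/minimum and differ by ≥ threshold by construction. The first
turn must additionally lie at least one threshold from the first sample,
which anchors the pass without a look-ahead. The implementation runs on
the sequence of local extrema (plateaus contribute their first sample),
which provably leaves the result unchanged; the test suite checks
equivalence against a naive sample-by-sample state machine on thousands
of random walks, including tied/plateau signals.

Two threshold conventions coexist deliberately: turn acceptance uses
"at least" (≥), while the Willison rate counts successive-sample
differences *strictly greater* than the threshold, following the
difference-count formula's inequality.

## Permutation entropy

Windows (x(t), x(t+τ), …, x(t+(n−1)τ)) advance by one sample; each maps
to the permutation that sorts it. Ties rank in temporal order (stable
sort) — the convention is documented rather than universal, and n, τ and
normalization are all configurable. Entropy is Shannon entropy in bits
over the observed pattern frequencies; unobserved patterns contribute
zero. Defaults are n = 3, τ = 2, unnormalized, the parameters quoted for
this analysis; note that published cohort entropy values of ~6.9–7.3
bits are impossible at n = 3 (bound log₂6 ≈ 2.585), so the order behind
those magnitudes is unrecoverable and we expose the parameters instead
of guessing. Being rank-based, the estimator is exactly invariant under
strictly monotone amplitude transforms, which the suite asserts.

## Undefined features

A recording with fewer than two turns has no mean interspike amplitude;
the feature is NaN and the subject is excluded from classification with
a logged warning, never imputed.

## Synthetic cohorts

Each subject's trace is a superposition of MUAP trains plus Gaussian
background noise. The building blocks:

- **MUAP template**: sum of `phases` alternating-sign Gaussian lobes
  spread over `duration_ms`, mean-subtracted, peak-normalized to
  `amplitude`. Simple, differentiable, and its extrema are countable by
  brute force, which makes the turn arithmetic testable.
- **Firing**: truncated-Gaussian renewal process, mean interval 1/rate,
  SD jitter_cv/rate (default CV 0.15), floored at 0.2/rate; first spike
  at a uniform fraction of one interval.
- **Healthy cohort defaults** (calibrated offline, then frozen): 50
  units/subject (Poisson), amplitude lognormal around 50 µV (CV 0.45),
  duration 2.2 ± 25% ms, 2–5 phases, rate 20 ± 20% Hz, background noise
  5 µV. Between-subject lognormal factors on amplitude (σ = 0.35,
  electrode coupling / contraction level) and rate (σ = 0.2).
- **Neuropathy**: each patient draws a severity s ~ U(0.35, 1). Unit
  survival is (1 − 0.92)^s of the pool; survivors are scaled ×(1+1.0·s)
  in amplitude and duration, gain ~2·s extra phases, and fire
  ×(1+0.10·s) faster. Independently of severity, each surviving unit
  carries 0–2 satellite components (probability 0.7 each): short, sharp
  late spikes (0.4–0.9 ms, 30–60% of the parent amplitude, 5–20 ms
  delay) modeling immature, slowly conducting sprouts.

Two structural choices matter and were made on physiological grounds:

1. **Background noise scales with the subject's amplitude factor.** The
   dominant "noise" at a needle tip during contraction is distant
   motor-unit activity, which rises and falls with the local signal, not
   an instrumentation floor. This makes permutation entropy a pure
   structure measure, insensitive to the electrode-coupling confound
   that moves turns and amplitude.
2. **Reinnervation complexity is present from the mild end of the
   severity spectrum, while unit loss tracks severity.** Clinically,
   polyphasia and satellites are early reinnervation signs; quantitative
   unit loss is what grades severity. Statistically, this decouples the
   entropy-bearing mechanism from the loss-bearing one, so entropy (and
   energy) carry information the turns-amplitude pair does not — which
   is exactly the regime in which adding them to the classifier helps.

With these defaults, 40+40 cohort feature means order as expected for
axonal neuropathy — turns/s lower (≈960 vs ≈700), interspike amplitude
higher (≈190 vs ≈215 µV), energy lower (≈515 vs ≈435 mV/s), entropy
higher (≈2.38 vs ≈2.47 bits) — and mean LOOCV accuracy rises from
≈0.74–0.83 (turns+amplitude) to ≈0.85–0.89 (all four features) across
seeds. Interspike-amplitude *magnitudes* cannot be matched to published
cohort means of ~59–100 µV: with a 100 µV threshold, consecutive
accepted turns differ by ≥ 100 µV by definition, so only the direction
of the group difference is meaningful here.

What the generator does **not** model: volume-conductor physics and
electrode geometry, force feedback (pool size and rates stand in for the
30% contraction level), 1/f or movement artifacts, firing-rate
modulation within a contraction, and myopathic change. Passing tests
therefore show that the *pipeline* behaves correctly on signals with the
assumed statistical structure, not that the classifier's absolute
accuracy transfers to patient data.

## Classification protocol

RBF-kernel SVM, kernel written exp(−‖x−y‖²/s²) with scale s = 1 on
standardized features (raw feature scales span three orders of
magnitude, which would otherwise dominate the kernel). The box
constraint is selected per training set from the grid 10⁻²…10³ by
stratified inner cross-validation (default 5 folds), ties resolved
toward the smaller constraint; the selection engine is deliberately a
plain grid, since reproducibility of the protocol, not the optimizer, is
what matters. Outer evaluation is leave-one-out: standardization and
constraint selection are refit on every fold, so the held-out subject
never influences its own model (asserted by a leakage test). With
`repeats > 1` the whole LOOCV is rerun under fresh inner-CV shuffles and
confusion counts are averaged, yielding fractional counts; the averaging
is a documented stand-in for whatever produced fractional counts in
prior reports, not a claim about their procedure. Positive class is
"neuropathic".

## Reporting

`compute_metrics` flags any rate with a zero denominator (and an MCC
with a zero marginal) as NaN rather than coercing to 0. Rates are
emitted as proportions; a formatter may render percent. The pipeline's
cohort summary uses Welch's two-sample t-test per feature as a
descriptive statistic of simulated group separation only.

## Problem sizes

Default test and acceptance runs simulate 40+40 subjects of 4 s at
12.5 kHz; direction and ordering claims average 5–10 independently
seeded cohort pairs with single-repeat LOOCV, sizes chosen as the
package's own reproducibility envelope.
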