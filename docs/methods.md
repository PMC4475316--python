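# Methods

## Signal model and feature extraction

The package treats an 8-lead ECG segment as a linear instantaneous
mixture `x(t) = A s(t) + n(t)`: under volume-conductor theory every lead
observes the same small set of cardiac sources with lead-specific
attenuations, so in the absence of noise the lead covariance
`R = A R_s Aᵀ` has rank N (the number of independent sources, about
three for the dominant components of the heartbeat). Noise adds `Q_n`
and populates the remaining eigenvalues. Quality assessment therefore
reduces to reading the eigenvalue spectrum of the sample covariance:

1. select leads I, II, V1–V6 in that fixed order (the four derived limb
   leads III, aVR, aVL, aVF are linear combinations of I and II and
   contribute only equipment quantisation noise);
2. subtract each lead's temporal mean — the only preprocessing;
3. form `R̂ = (1/K) X Xᵀ` over the full segment (one estimation window,
   no segmentation; the divisor is K, not K−1 — at K = 5000 the
   difference is 0.02%, but the estimator is fixed for reproducibility);
4. take the eigenvalues of the symmetric matrix, sorted descending.

Everything runs on raw digital ADC counts. This is a deliberate,
load-bearing choice: the decision thresholds live on the unscaled
digital scale (acceptable records have 3 ≤ log₁₀ λ₁ ≤ 5 there, i.e.
millivolt-scale QRS complexes at a conventional digitiser gain), and a
gain change of 10× shifts every log₁₀ eigenvalue by 2 and can legally
change the label. A test asserts this sensitivity rather than hiding it.

Numerical choices: covariance symmetry is enforced exactly by averaging
with its transpose; eigenvalues in (−10⁻¹²·trace, 0) are clamped to 0;
a more negative eigenvalue raises an error. The log₁₀ view maps
λ ≤ 10⁻¹² to −12 (numerically-zero eigenvalues pooled at a floor, the
same convention as pooling tiny eigenvalues into one histogram bin).
Classifier comparisons are evaluated in the *linear* domain
(λ vs 10^T) so that exact zeros from singular covariances never meet a
logarithm. The condition number κ = λ₁/λ₈ is exported as a diagnostic;
κ = +∞ when λ₈ = 0. It is not used by the classifiers: any threshold on
a ratio of eigenvalues is subsumed by thresholds on the eigenvalues
themselves.

## Rule classifiers

Three frozen rule sets are shipped (log₁₀ thresholds):

| model | rules (first match decides; default AC) |
|---|---|
| cart | λ₈ < 0.145 ⇒ UN; λ₁ ≥ 5.08 ⇒ UN |
| c45 | λ₈ ≤ 0.0870 ⇒ UN; λ₁ ≤ 4.86 ⇒ AC; λ₁ ≥ 7.91 ⇒ UN; λ₆ ≥ 2.23 ⇒ UN |
| ripper | λ₈ ≤ 0.0863 ⇒ UN; λ₁ ≥ 4.85 ∧ λ₃ ≥ 4.06 ⇒ UN; λ₁ ≥ 5.09 ∧ λ₂ ≥ 3.75 ⇒ UN |

Strict vs non-strict comparators follow the printed rule forms; at
measure-zero boundary points this cannot affect any continuous-valued
record. The `c45` topology is a reconstruction from the published
narrative (the original tree graphic is not machine-readable); the rule
order and the direction of the λ₆ gate follow the stated rationale —
energy outside the three main eigenvalues indicates several unexpected
noise sources — and the registry metadata flags the reconstruction.
Rule sets round-trip bit-exactly through JSON and can be replaced at the
CLI by a custom registry. UN is the positive class throughout
(sensitivity = fraction of UN called UN).

Reference labels from human annotator grades use the mapping A = 0.95,
B = 0.85, C = 0.75, D = 0.6, F = 0; a record is AC iff ≥ 2 grades
exist, their mean exceeds 0.7 and at most one grade is F. The mean is
computed in exact rational arithmetic so the 0.7 boundary is sharp; a
mean of exactly 0.7 resolves to UN (the published condition requires
"larger than 0.7", and rejecting the undecidable case is the safe
default for a QC gate). Records with fewer than two grades are UN; how
such records were originally labeled is unknown, so the conservative
choice is documented here rather than hidden.

## Synthetic generator

The generator emulates the *covariance structure* the method consumes,
not electrophysiology. Sources are sum-of-Gaussians beat trains
(P/QRS/T-like deflections, per-source morphology perturbations,
constant heart rate with ~10 ms per-beat jitter), orthogonalised by QR
so pairwise sample correlations are exactly zero, then scaled to
geometrically decaying powers (ratio 0.4). Mixing coefficients are
uniform in magnitude on [0.2, 1] with random signs, redrawn until well
conditioned. The default amplitude scale of 330 ADC counts per unit
source places a clean record's log₁₀ λ₁ near 4.0 — the middle of the
acceptable decade for 16-bit digital ECGs — and was fixed once from
that physical anchor.

Contamination events: white noise, 50/60 Hz powerline (common phase,
per-lead gain), baseline wander (~0.3 Hz), Hann-windowed transient
artifact bursts, flat-lead overwrite, and clipping at the 16-bit
ceiling (2¹⁵−1). Additive events sum onto the mixed signal; flat leads
then overwrite; clipping saturates last. The report attached to each
record lists every event with its measured injected power, so
signal/noise power additivity (trace additivity of the covariance) is
testable directly.

A default-configuration record is *noise-free* and hence exactly rank
3 — useful for subspace tests, but its λ₈ is numerically zero, which a
rank-gate rule correctly flags. Acceptable cohort draws therefore add a
small white sensor-noise floor (σ between 2 and 6 counts), emulating
the amplifier/quantisation noise that every real recording carries and
that keeps λ₈ in its observed decade (log₁₀ λ₈ ≈ 0.6–1.6). Unacceptable
draws take one of three modes, mixed uniformly: a flat lead; two
independent high-power transient artifacts (each injecting ≥ 100× the
cardiac power, plus broadband electrode shake); or broadband noise
swamping all leads (σ 400–700 counts with strong powerline and wander).
These reproduce the two observed failure regimes — collapsed spectra
(small λ₈) and inflated spectra (large λ₁…λ₃) — but they are a
*constructed* mixture: real unacceptable records also contain low-power
noise near the decision boundary, pacing/rhythm pathologies and
annotator disagreement, none of which the generator produces. Passing
cohort tests therefore demonstrates that the pipeline wiring and rule
semantics are correct and that the spectra land in the intended
decades; it does not certify real-data accuracy.

## Induction and cross-validation

The inducer is a minimal CART-style tree: greedy binary splits on
single log₁₀-eigenvalue thresholds, Gini impurity, candidate thresholds
at midpoints between consecutive distinct sorted values, ties broken by
lower feature index then lower threshold (fully deterministic), leaf
majority vote with ties resolved to UN, stopping at `max_depth`
(default 4), `min_leaf` (default 5) or zero Gini gain; no pruning. It
emulates the learning *workflow* at desk scale and makes no claim to
reproduce any specific off-the-shelf inducer's trees. `tree_to_rules`
flattens a tree into an equivalent conjunctive rule list (paths are
mutually exclusive, so order is immaterial) for the same registry
format the shipped classifiers use.

Cross-validation uses seeded stratified k-fold assignment (plain seeded
k-fold when a class is rarer than k, e.g. leave-one-out); per-fold and
pooled confusion metrics are reported over concatenated test
predictions, and AUC ranks pooled leaf UN-purity scores with midrank
tie handling. Greedy Gini induction cannot start on a perfectly
symmetric XOR arrangement (the first split has zero gain); the tests
document this known property rather than work around it.

## Problem sizes and reproducibility

Defaults everywhere follow the telemonitoring recording format: 8
leads, 10 s at 500 Hz (K = 5000), 16-bit amplitudes. The test suite and
the acceptance script use cohorts of 200 records (classifier metrics)
and 400 records (10-fold CV), and 10 noise-free records for subspace
statistics — sizes at which the measured proportions are stable to a
couple of points across seeds. All randomness flows through
`numpy.random.default_rng` seeded from a single user-supplied seed;
identical seeds reproduce records bit-for-bit, fold assignments and
induced trees included.

## Known limitations

* The rule thresholds are shipped constants learned elsewhere on real
  annotated data; this package validates their semantics and behaviour
  on synthetic cohorts, not their clinical error rates.
* The generator's artifact taxonomy is coarse (see above); cohort
  accuracies near 100% reflect well-separated synthetic classes, and
  the acceptance report should be read with that in mind.
* Only single-file WFDB format-16 records are supported; other signal
  formats raise a clear format error rather than being silently
  approximated.
* No filtering, resampling or baseline correction is performed by
  design; records at other sampling rates or gains are accepted but the
  thresholds assume the raw 500 Hz / 16-bit digital scale.
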