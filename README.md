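# ecgqc

Quality estimation for multi-lead ECG recordings from the eigenvalue
spectrum of the lead covariance matrix.

Telemonitoring and self-recorded ECGs are frequently unusable: detached
electrodes, motion artifacts, mains interference. `ecgqc` decides, in a
few matrix operations, whether a 10-second 12-lead (or 8-lead) recording
is clinically **Acceptable (AC)** or **Unacceptable (UN)** — fast enough
to run on the recording device and tell the technician to repeat the
trace while the patient is still connected. It is aimed at people
building ECG acquisition or QC pipelines who want an interpretable,
near-zero-cost quality gate rather than a black-box model.

## Method

All leads of an ECG observe the same cardiac activation through a volume
conductor, so the 8 linearly independent leads (I, II, V1–V6) follow the
linear mixing model

    x(t) = A s(t) + n(t)

with `s(t)` the N cardiac source signals (N ≈ 3 in a clean recording),
`A` the 8×N attenuation matrix and `n(t)` additive noise. Stacking the K
mean-centered samples into the 8×K matrix `X`, the sample covariance

    R̂ = (1/K) · X Xᵀ          (divisor K, no normalisation anywhere)

has eigenvalues λ₁ ≥ … ≥ λ₈ whose pattern encodes quality:

* a **flat or disconnected lead** collapses the spectrum — λ₈ → 0;
* **high-power artifacts** inflate the leading eigenvalues — λ₁ grows
  far beyond the usual acceptable decade (3 ≤ log₁₀ λ₁ ≤ 5 for raw
  16-bit digital amplitudes);
* extra energy in λ₆ betrays several unexpected noise sources beyond
  the ~3 cardiac components.

Three published first-match threshold rule sets over (λ₁, …, λ₈) are
shipped as frozen, versioned registries — a two-rule tree (`cart`), a
four-rule tree (`c45`) and a three-rule list (`ripper`), e.g. RIPPER:

    1  λ₈ ≤ 10^0.0863                          ⇒ UN
    2  λ₁ ≥ 10^4.85  ∧  λ₃ ≥ 10^4.06           ⇒ UN
    3  λ₁ ≥ 10^5.09  ∧  λ₂ ≥ 10^3.75           ⇒ UN
    4  otherwise                               ⇒ AC

The package also contains a synthetic 8-lead generator implementing the
mixing model with labeled contamination (flat leads, transient
artifacts, powerline, baseline wander, broadband noise), a CART-style
Gini threshold-tree inducer with a stratified k-fold CV harness, and a
reader/writer for WFDB (header + format-16 signal) and CSV records.
Everything operates on raw digital ADC counts — signals and eigenvalues
are deliberately never rescaled, because the thresholds live on that
scale.

## Worked example

Generate a small labeled cohort, extract features, classify:

```sh
ecgqc simulate -n 6 --seed 7 -o demo
ecgqc features demo/*.hea -o demo/features.csv
ecgqc classify --model ripper demo/*.hea -o demo/labels.csv
```

`demo/features.csv` (selected columns):

```
record_id  log10_lambda1  log10_lambda8    kappa
  syn0000          6.220          5.600    4.171
  syn0001          3.887          0.995  778.974
  syn0002          4.766          1.129 4341.569
  syn0003          6.875          3.208 4649.507
  syn0004          3.594          1.174  262.699
  syn0005          6.574          2.753 6620.896
```

`demo/labels.csv`:

```
record_id,model,label,firing_rule_index
syn0000,ripper,UN,2
syn0001,ripper,AC,4
syn0002,ripper,AC,4
syn0003,ripper,UN,2
syn0004,ripper,AC,4
syn0005,ripper,UN,3
```

Reading: `syn0001`, `syn0002` and `syn0004` have log₁₀ λ₁ in the
acceptable 3–5 decade and a healthy noise floor (log₁₀ λ₈ ≈ 1), so no UN
rule fires (rule 4 is the AC default). The other three carry injected
contamination: their λ₁ is 10–1000× too large and rules 2/3 fire. All
six labels match the generator's ground truth in `demo/manifest.json`.

The same works from Python:

```python
from ecgqc import extract_features, classify_ripper, read_wfdb_record

record = read_wfdb_record("demo/syn0001.hea")
spectrum = extract_features(record)      # lambda_1 .. lambda_8
print(spectrum.log10, classify_ripper(spectrum))
```

Annotator grades can be reduced to the reference label with
`aggregate_annotations(["A", "B"]) → AC` (two or more grades, average
value > 0.7, at most one F).

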