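# stnbeta

Decomposition of subthalamic-nucleus (STN) local field potential (LFP)
power spectra into a periodic **beta oscillation** and an aperiodic
**1/f broadband** background, with the downstream biomarker and cohort
statistics needed to ask: *does beta activity correlate with
Parkinsonian motor symptoms once the background is removed?*

## Why

Beta-band (13–30 Hz) power in STN recordings is the leading biomarker
for adaptive deep-brain stimulation, yet its correlation with untreated
motor symptoms has been inconsistent across studies. A likely culprit
is the electrophysiological broadband background — a 1/f-like spectral
floor reflecting the synaptic excitation/inhibition balance — which is
inevitably included in naive band-power readings and varies across
patients for reasons unrelated to beta. `stnbeta` separates the two
components, derives competing "with background" / "without background"
beta biomarkers, and quantifies the consequences at the cohort level.

## The model

Each power spectral density `P(f)` (µV²/Hz) is modeled, in log10 space
over 3–45 Hz, as the sum of two components:

    P(f) = B(f) + G(f)
    B(f) = a · exp(−f / τ) + c               (broadband: height a,
                                              decay constant τ [Hz],
                                              noise floor c)
    G(f) = A · exp(−(f − f0)² / (2σ²))        (beta peak: amplitude A,
                                              center f0 ∈ [13, 30] Hz,
                                              width σ [Hz])

Fitting is a deterministic three-stage procedure: robust broadband fit
with iterative peak masking, Gaussian initialization from the positive
beta-band residual, then joint bounded least squares of all six
parameters. When the spectrum comes from a Hann-tapered Welch estimate,
the fit folds the known 3-tap spectral-leakage kernel into the forward
model, so the *intrinsic* peak amplitude is recovered rather than the
leakage-broadened one.

The two biomarkers contrasted throughout are

* `beta_without_broadband` = A (the oscillation's own amplitude), and
* `beta_with_broadband` = A + B(f0) (total power at the peak, what a
  plain band-power reading picks up),

each also computed directly from the raw smoothed spectrum. Cohort
statistics are Spearman correlations with contralateral UPDRS-III
scores (bradykinesia, rigidity, tremor and their sums), Hotelling's
(1940) t test for the difference of two dependent correlations,
Benjamini–Hochberg FDR, frequency-resolved broadband-vs-age/symptom
profiles, and Wilcoxon signed-rank comparisons of sliding-window
stability. Because clinical recordings are not redistributable, the
package ships a fully seeded synthetic-data generator that emulates
the study design (13 patients × 2 hemispheres, 6-min resting
recordings at 2048 Hz) with known ground truth.

## Worked example

```sh
python examples/01_decompose_spectrum.py
```

```
broadband  a=9.09 (true 9.00)  tau=14.46 Hz (true 14.00)  c=0.238 (true 0.300)
beta       A=3.06 (true 3.20)  f0=21.09 Hz (true 21.00)  sigma=2.43 Hz (true 2.40)
goodness of fit R^2 = 0.9976
```

A 6-minute surrogate recording is synthesized from known parameters,
its Welch spectrum estimated (1-s Hann windows, 50% overlap), and the
model fitted: the oscillation's amplitude and frequency come back
within a few percent, and the model explains >99% of the log-spectrum.
The other scripts in `examples/` walk through the broadband confound
(`02`), the full cohort comparison (`03`), the age–broadband
correlation profile (`04`) and sub-second biomarker stability (`05`).
A thin CLI (`stnbeta simulate | psd | fit | stats`) exposes the same
pipeline for shell use; every run writes a resolved copy of its
configuration and is byte-reproducible given the same seed.

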