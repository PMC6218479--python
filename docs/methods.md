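# Methods

## Spectral model and fitting

A one-sided PSD `P(f)` (µV²/Hz) is decomposed as `B(f) + G(f)` with an
exponential broadband background `B(f) = a·exp(−f/τ) + c` and a
Gaussian beta peak `G(f) = A·exp(−(f−f0)²/(2σ²))`. The exponential-
plus-floor form captures the fast low-frequency decay of STN spectra
and the flat plateau at high frequencies where device noise dominates;
the floor is modeled explicitly (parameter `c`) rather than absorbed
into the exponential, because the plateau level carries physiological
and instrumental information of its own (it drives the high-frequency
limb of the age profile). The Gaussian is symmetric about `f0` and
constrained to the beta band.

Fitting happens in **log10 power vs linear frequency**, which
equalizes residual weight across a dynamic range of two to three
decades and matches how goodness of fit is conventionally reported for
spectra. The default fit range is **3–45 Hz**: below 3 Hz movement and
drift artifacts dominate; 45 Hz keeps a safe margin from 50 Hz line
noise. All of this is configurable (`FitConfig`).

Three deterministic stages:

1. **Robust broadband fit.** Least squares of `log10 B(f)` against the
   log spectrum, iteratively masking bins whose residual exceeds
   +2 robust SDs (1.4826·MAD) — the beta peak and any other narrowband
   excess — until the mask stabilizes or 5 iterations. The mask is
   never allowed to shrink below half the minimum bin count, so the
   baseline cannot be masked away.
2. **Peak initialization.** Moment-based Gaussian start values from
   the positive linear residual restricted to 13–30 Hz. If no
   positive residual exists anywhere in the band, the fit returns
   `A = 0` with a `no-peak` flag instead of erroring, so cohort
   pipelines keep every hemisphere (the flag is also set whenever the
   final `A` is below 1% of the broadband level at `f0`).
3. **Joint refinement.** Bounded trust-region least squares over all
   six parameters (`a, c, A ≥ 0`; `τ ∈ [0.5, 200]` Hz;
   `f0 ∈ [13, 30]` Hz; `σ ∈ [0.5, 6]` Hz) at tolerances 1e−14, making
   the result bit-reproducible and scale-equivariant (multiplying the
   input spectrum by k scales `a, c, A` by k and leaves `τ, f0, σ`).

**Taper-leakage correction.** The expectation of a Hann-tapered
periodogram at the natural bin spacing `1/T` is the true spectrum
convolved with a 3-tap kernel `[1/6, 2/3, 1/6]` (the Hann transform
vanishes at offsets of two or more bins). For Welch spectra the fit
convolves the model with this kernel, so the reported `A` and `σ` are
the intrinsic peak parameters, not the leakage-broadened ones; without
the correction, `A` is biased low by 5–15% at 1 Hz resolution for
σ ≈ 1.5–3 Hz. Grid-evaluated model spectra (no taper metadata) skip
the correction. R² is computed in observed space (smeared model vs
measured spectrum) over the fit range.

## Biomarkers

* `beta_without_broadband` = `A` — the oscillation isolated from the
  background; no-peak fits contribute 0.
* `beta_with_broadband` = `A + B(f0)` — total modeled power at the
  peak, i.e. what plain band power reports; for no-peak fits, `B` at
  the band center (21.5 Hz). The model-evaluated peak value was chosen
  as the "with background" definition because it is the cleanest
  single-number contrast with `A`: the two differ by exactly the
  broadband contribution at the peak.
* The **actual-spectrum pathway** mirrors both definitions without the
  model: the raw spectrum is smoothed with a 3-bin moving average, its
  maximum in 13–30 Hz located (ties break toward the lower frequency,
  for determinism; a maximum on the band edge is flagged, since a
  peak-free monotone spectrum maximizes at the edge), and the fitted
  broadband is subtracted (floored at 0) for the "without" version.
* `broadband_profile` evaluates the fitted `B(f)` on a 1–200 Hz grid
  for the frequency-resolved correlation analyses. Above the fit range
  this is an extrapolation of the exponential-plus-floor form; the
  floor dominates there, so the profile's high-frequency limb is
  effectively an estimate of `c`.

**Sliding windows.** 1-s windows advanced by 50 ms (95% overlap;
window count is exactly `floor((T−1)/0.05)+1`, with per-window start
indices rounded so the nominal stride never drifts). Each window gets
a single-taper Hann periodogram. The beta course is the mean log10
power in 13–30 Hz minus the reference fit's broadband log-level in the
band (so background drift does not read as beta change); the broadband
course is the mean log10 power in a peak-free 35–45 Hz band — a full
six-parameter fit per 1-s window would rest on ~43 noisy bins and is
not stable, so a band proxy is used (configurable). Both series are
**mean-centered per recording but not variance-scaled**: their
standard deviations are the stability measures being compared, and
z-scoring would fix both SDs at 1 and make the comparison vacuous.
Because the units of these SDs are package-specific (centered log10
power), only the beta-vs-broadband *ordering* is scientifically
interpretable, not the magnitudes.

## Cohort statistics

* **Spearman** correlation (average ranks for ties) with the two-sided
  t approximation `t = ρ√((n−2)/(1−ρ²))`, used at every n for
  consistency.
* **Hotelling's (1940) t** for the difference of two dependent
  correlations sharing a variable, on n−3 df. "Hotelling's t test" is
  implemented in its original form; Williams' (1959) modification is
  available behind `variant="williams"` for sensitivity analyses. The
  closed form is validated in-tree against a 10⁵-replicate Monte-Carlo
  sampling-distribution oracle (agreement within ±0.01 in p). Its
  empirical type-I error at n = 26 under a trivariate-Gaussian null is
  0.05–0.06 (computed by the acceptance script). A caveat worth
  knowing: when contamination is made extreme, the correlation between
  the two biomarkers collapses together with the with-background
  correlation, and the test's power against the equality null plateaus
  around 0.65 at planted ρ = 0.6, n = 26 (see
  `tests/test_stats.py::test_power_with_calibrated_attenuation`).
* **BH-FDR** (statsmodels' step-up implementation, verified against a
  literal step-up enumeration). Correction is applied **within each
  test family separately**: the 5 symptom targets of one pathway for
  the comparison tests, likewise for each correlation set, and all
  bins of one frequency profile. Joint correction across families
  would mix tests asking different questions.
* **Wilcoxon signed rank**, `W = min(T+, T−)`, zero differences
  dropped. The two-sided p is exact for n ≤ 25 — computed by dynamic
  programming over the sign-flip null on doubled (tie-averaged) ranks,
  verified against full 2ⁿ enumeration — and a tie-corrected normal
  approximation with continuity correction above.
* **Error bars** on correlation coefficients are seeded nonparametric
  bootstrap SDs over hemispheres (B = 2000 by default).
* The two hemispheres of a patient are treated as independent
  (n = 26), matching the study design being emulated; a patient-level
  cluster bootstrap would be the conservative alternative and is out
  of scope.

## Synthetic data generator

The generator emulates the statistical structure of the study: 13
patients × 2 hemispheres, 6-min resting recordings at 2048 Hz, one
spectrum and one contralateral score set (bradykinesia, rigidity,
tremor on 0–4 half-point grids; age per patient) per hemisphere.

Per-hemisphere ground truth (defaults, all configurable):

| parameter | prior | why |
|---|---|---|
| `a` | lognormal, mean 8.5 µV²/Hz, CV 0.7, −4%/yr age slope on ln a | across-subject broadband variance is the contamination under study; the age slope makes low-frequency broadband decline with age |
| `τ` | 18 Hz at age 45, −1/3 Hz per year, jitter SD 3 Hz, clipped to [6, 22] | decay shortens with age; the jitter spreads broadband power at the peak without a heavy right tail |
| `c` | 0.30 µV²/Hz at age 60, +3%/yr, jitter 0.01 | floor rises with age (drives the positive high-frequency age band) |
| `A` | uniform [2.6, 3.8] µV²/Hz | clearly detectable pathological peaks, as in patient spectra |
| `f0` | uniform [16, 24] Hz | centered in the beta band, away from the fitting bounds |
| `σ` | uniform [2, 3] Hz | well resolved at 1 Hz spectral resolution |

**Symptom coupling** uses a Gaussian copula: with target Spearman ρs,
the latent score correlates with the beta-amplitude latent at Pearson
`2·sin(πρs/6)`, which achieves ρs exactly in expectation on the
continuous scale; rounding to half points attenuates it only slightly
(verified within ±0.1). Defaults plant ρ = 0.88 (rigidity) and 0.68
(bradykinesia) on the **true** amplitude — deliberately above the
correlations one expects to *measure*, because estimation noise and
score rounding attenuate them to roughly 0.75 and 0.55 at the
biomarker level. Tremor is independent. Broadband parameters are
independent of all scores, so any with-background correlation deficit
is pure contamination.

**Spectra** are emitted on a 1 Hz grid (1–200 Hz) with multiplicative
log-normal noise of SD 0.02 log10 units — the estimator noise of a
6-min, 1-s-window Welch PSD — plus an optional smooth "model mismatch"
ripple (off by default). **Signals** are synthesized as spectrally
shaped Gaussian noise: the broadband part filtered to `B(f)`, the beta
part an independent narrowband Gaussian process (so its envelope
fluctuates naturally window to window), summing to the target PSD in
expectation; optional sinusoidal amplitude modulation of either
component (power-normalized) supports the stability analyses. All
output is deterministic given the seed.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of the study —
spectral shapes, planted monotone couplings, contamination, age
signatures — not real STN electrophysiology. Synthetic spectra lack
line noise, artifacts, tremor-band peaks, non-exponential aperiodic
structure and nonstationarity, so model fits are cleaner than on
patient data (R² ≈ 0.992–0.999 on default cohorts, versus ~0.95–0.99
reported for real recordings). Passing the suite demonstrates that the
pipeline recovers known ground truth and detects planted effects at
the study's sample size; it cannot certify performance on clinical
recordings. Under the default (deliberately heavy) contamination, a
few hemispheres per cohort have raw spectra whose beta peak does not
rise above the background at all — the raw-pathway agreement check is
therefore run at moderate broadband levels, the regime where raw peaks
are detectable.

## Problem sizes and numerical choices

Tests and the acceptance script use: 100 draws for noiseless recovery;
50 six-minute recordings for realistic recovery; 100 cohorts for the
planted-pattern rate; 50 for the age profile; 2000 replicates for the
type-I error; 26 two-minute recordings for the sliding-window
analysis. Optimizer tolerances are 1e−12/1e−14 (xtol/ftol/gtol);
ties in peak detection break toward lower frequency; all-zero spectra
are flagged degenerate and refused by the fitter; constant vectors
raise "zero rank variance" rather than returning NaN correlations.
CSV output uses `%.17g`, and readers use round-trip float parsing, so
files reproduce in-memory values bit-exactly.
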