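"""Synthetic LFP recordings and cohorts with known ground truth.

The study design being emulated: 13 Parkinsonian patients recorded
bilaterally at rest (26 hemispheres, 6 min each), each hemisphere
scored contralaterally on UPDRS-III bradykinesia, rigidity and tremor.
The generator draws per-hemisphere spectral parameters from priors,
couples bradykinesia and rigidity monotonically to the true beta
amplitude via a Gaussian copula (tremor stays independent), and couples
age to the broadband shape — amplitude and decay constant shrink and
the noise floor rises with age — which yields a negative age–broadband
correlation at low frequencies and a positive one near the floor.
Broadband amplitude varies widely across hemispheres independently of
the symptom scores, so a biomarker that keeps the background absorbs
that variance as contamination.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import (
    BetaParams,
    BroadbandParams,
    PowerSpectrum,
    TimeSeries,
    beta_value,
    broadband_value,
)

__all__ = ["GeneratorConfig", "SyntheticCohort", "gen_psd", "gen_lfp", "gen_cohort"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs of the cohort generator.

    Priors are per hemisphere unless noted.  ``psd_noise_sd`` is the
    SD, in log10-power units, of the multiplicative perturbation on
    cohort spectra; it represents Welch estimator noise plus the
    model mismatch of real spectra.  Couplings are target Spearman
    correlations between the true beta amplitude and each score.
    """

    n_patients: int = 13
    fs: float = 2048.0
    duration_s: float = 360.0
    # broadband priors: amplitude lognormal (mean, CV); tau and floor are
    # age-linked (slope per year) with additive Gaussian jitter
    a_mean: float = 8.5
    a_cv: float = 0.7
    a_age_slope: float = -0.04  # per-year slope on ln(a), anchored at age 60
    tau_at_45: float = 18.0
    tau_age_slope: float = -1.0 / 3.0
    tau_jitter_sd: float = 3.0
    tau_clip: tuple[float, float] = (6.0, 22.0)
    c_base: float = 0.30
    c_age_slope: float = 0.03  # fractional increase per year from age 60
    c_jitter_sd: float = 0.01
    c_min: float = 0.02
    # beta priors
    A_range: tuple[float, float] = (2.6, 3.8)
    f0_range: tuple[float, float] = (16.0, 24.0)
    sigma_range: tuple[float, float] = (2.0, 3.0)
    # cohort structure
    age_range: tuple[float, float] = (45.0, 78.0)
    # couplings target the *ground-truth* beta amplitude; measured
    # correlations land lower after estimation noise and score rounding
    rho_bradykinesia: float = 0.68
    rho_rigidity: float = 0.88
    rho_tremor: float = 0.0
    score_max: float = 4.0
    # observation noise on cohort PSDs (log10 units): per-bin estimator
    # noise plus an optional smooth model-mismatch ripple
    psd_noise_sd: float = 0.02
    psd_ripple_sd: float = 0.0
    psd_ripple_scale_hz: float = 8.0
    psd_grid_max: float = 200.0
    seed: int = 0

    @property
    def n_hemispheres(self) -> int:
        return 2 * self.n_patients


@dataclass
class SyntheticCohort:
    """One generated cohort: ground truth, clinical table and spectra."""

    ground_truth: pd.DataFrame
    clinical: pd.DataFrame
    psds: list[PowerSpectrum]
    signals: list[TimeSeries] = field(default_factory=list)
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    @property
    def hemisphere_ids(self) -> list[str]:
        return list(self.ground_truth["hemisphere_id"])


# ---------------------------------------------------------------------------
# Spectrum- and signal-level generation
# ---------------------------------------------------------------------------

def gen_psd(
    bb: BroadbandParams,
    beta: BetaParams,
    grid,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    ripple_sd: float = 0.0,
    ripple_scale_hz: float = 8.0,
) -> PowerSpectrum:
    """Model PSD on ``grid``, optionally log-normally perturbed.

    ``noise_sd`` is the per-bin SD in log10 units (estimator noise);
    ``ripple_sd`` adds a smooth correlated log-spectral distortion of
    Gaussian correlation length ``ripple_scale_hz``, emulating the
    model mismatch of real spectra (shoulders, shallow bumps).  Both
    perturbations have zero mean in log space, so the expected log PSD
    equals the log model PSD.  Zero noise gives the exact model curve.
    """
    grid = np.asarray(grid, dtype=float)
    if noise_sd < 0 or ripple_sd < 0:
        raise ValueError("noise SDs must be non-negative")
    power = broadband_value(bb, grid) + beta_value(beta, grid)
    if noise_sd > 0 or ripple_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        log_pert = np.zeros(grid.size)
        if ripple_sd > 0:
            from scipy.ndimage import gaussian_filter1d

            df = float(grid[1] - grid[0]) if grid.size > 1 else 1.0
            sig_bins = ripple_scale_hz / df
            raw = gaussian_filter1d(
                rng.standard_normal(grid.size), sig_bins, mode="nearest"
            )
            # renormalize: smoothing shrinks the marginal SD
            gain = 1.0 / np.sqrt(1.0 / (2.0 * np.sqrt(np.pi) * sig_bins))
            log_pert += ripple_sd * raw * gain
        if noise_sd > 0:
            log_pert += noise_sd * rng.standard_normal(grid.size)
        power = power * 10.0**log_pert
    df = float(grid[1] - grid[0]) if grid.size > 1 else 1.0
    return PowerSpectrum(frequencies=grid, power=power, window_s=1.0 / df, taper=None)


def _shaped_noise(
    target_psd: np.ndarray, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise whose one-sided PSD equals ``target_psd`` (length n//2+1)."""
    n_bins = target_psd.size
    amp = np.sqrt(target_psd * fs * n / 2.0)
    z = (rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins)) / np.sqrt(2.0)
    spec = amp * z
    spec[0] = 0.0  # no DC
    if n % 2 == 0:
        spec[-1] = spec[-1].real * np.sqrt(2.0)
    return np.fft.irfft(spec, n=n)


def _am_envelope(
    n: int, fs: float, depth: float, freq: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-power sinusoidal amplitude-modulation envelope."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    env = 1.0 + depth * np.sin(2 * np.pi * freq * t + phase)
    return env / np.sqrt(1.0 + depth**2 / 2.0)


def gen_lfp(
    bb: BroadbandParams,
    beta: BetaParams,
    duration_s: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    beta_am: tuple[float, float] | None = None,
    bb_am: tuple[float, float] | None = None,
    label: str = "",
) -> TimeSeries:
    """Time-domain realization of the two-component spectral model.

    The broadband part is spectrally shaped Gaussian noise with target
    one-sided PSD ``B(f)``; the beta part is an independent narrowband
    stochastic process (Gaussian-envelope band-pass noise centered at
    f0, width sigma), so its instantaneous amplitude genuinely
    fluctuates window to window.  Their expected PSDs add to the model.

    ``beta_am`` / ``bb_am`` optionally impose slow sinusoidal amplitude
    modulation, given as (depth, frequency_hz); the envelopes are
    power-normalized so the long-run PSD is preserved.
    """
    if fs < 400:
        raise ValueError("sampling rate must be at least 400 Hz")
    if duration_s < 10:
        raise ValueError("duration must be at least 10 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    x_bb = _shaped_noise(broadband_value(bb, freqs), n, fs, rng)
    if bb_am is not None:
        x_bb = x_bb * _am_envelope(n, fs, *bb_am, rng)
    if beta.A > 0:
        x_beta = _shaped_noise(beta_value(beta, freqs), n, fs, rng)
        if beta_am is not None:
            x_beta = x_beta * _am_envelope(n, fs, *beta_am, rng)
    else:
        x_beta = 0.0
    return TimeSeries(samples=x_bb + x_beta, sampling_rate=fs, label=label)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _copula_scores(
    z_anchor: np.ndarray, rho_s: float, rng: np.random.Generator, score_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Scores with target Spearman coupling to the anchor's latent normal.

    Uses the Gaussian-copula identity rho_pearson = 2 sin(pi rho_s / 6),
    which hits the target Spearman exactly in expectation on the
    continuous scale; half-point rounding attenuates it only slightly.
    Returns (continuous scores, rounded half-point scores).
    """
    if abs(rho_s) > 0.95:
        raise ValueError("infeasible coupling target: |rho| > 0.95")
    from scipy.stats import norm

    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z = rho_p * z_anchor + np.sqrt(1.0 - rho_p**2) * rng.standard_normal(z_anchor.size)
    cont = score_max * norm.cdf(z)
    rounded = np.round(cont * 2.0) / 2.0
    return cont, rounded


def gen_cohort(
    cfg: GeneratorConfig | None = None,
    seed: int | None = None,
    signals: bool = False,
) -> SyntheticCohort:
    """Generate one cohort: parameters, scores, spectra (and signals).

    Spectra are emitted on a 1 Hz grid up to ``psd_grid_max`` with
    multiplicative log-normal observation noise; with ``signals=True``
    full 6-min time series are synthesized as well (slower).  ``seed``
    overrides ``cfg.seed``.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_h = cfg.n_hemispheres

    # patient-level draws
    age_p = rng.uniform(*cfg.age_range, cfg.n_patients)
    age = np.repeat(age_p, 2)
    patient = np.repeat(np.arange(1, cfg.n_patients + 1), 2)
    side = np.tile(["L", "R"], cfg.n_patients)
    ids = [f"P{p:02d}{s}" for p, s in zip(patient, side)]

    # broadband: a varies independently of symptoms (the contamination)
    # but, like tau and c, carries the age signature
    sigma_ln = np.sqrt(np.log(1.0 + cfg.a_cv**2))
    a = cfg.a_mean * np.exp(
        sigma_ln * rng.standard_normal(n_h)
        - 0.5 * sigma_ln**2
        + cfg.a_age_slope * (age - 60.0)
    )
    tau = (
        cfg.tau_at_45
        + cfg.tau_age_slope * (age - 45.0)
        + cfg.tau_jitter_sd * rng.standard_normal(n_h)
    )
    tau = np.clip(tau, *cfg.tau_clip)
    c = cfg.c_base * (1.0 + cfg.c_age_slope * (age - 60.0)) + cfg.c_jitter_sd * rng.standard_normal(n_h)
    c = np.clip(c, cfg.c_min, None)

    # beta: amplitude anchors the symptom coupling
    z_a = rng.standard_normal(n_h)
    from scipy.stats import norm

    A = cfg.A_range[0] + (cfg.A_range[1] - cfg.A_range[0]) * norm.cdf(z_a)
    f0 = rng.uniform(*cfg.f0_range, n_h)
    sigma = rng.uniform(*cfg.sigma_range, n_h)

    brady_cont, brady = _copula_scores(z_a, cfg.rho_bradykinesia, rng, cfg.score_max)
    rigid_cont, rigid = _copula_scores(z_a, cfg.rho_rigidity, rng, cfg.score_max)
    tremor_cont, tremor = _copula_scores(z_a, cfg.rho_tremor, rng, cfg.score_max)

    ground_truth = pd.DataFrame(
        {
            "hemisphere_id": ids,
            "patient": patient,
            "age": age,
            "a": a,
            "tau": tau,
            "c": c,
            "A": A,
            "f0": f0,
            "sigma": sigma,
            "bradykinesia_cont": brady_cont,
            "rigidity_cont": rigid_cont,
            "tremor_cont": tremor_cont,
        }
    )
    clinical = pd.DataFrame(
        {
            "hemisphere_id": ids,
            "bradykinesia": brady,
            "rigidity": rigid,
            "tremor": tremor,
            "age": age,
        }
    )

    grid = np.arange(1.0, cfg.psd_grid_max + 0.5)
    psds = [
        gen_psd(
            BroadbandParams(a=a[i], tau=tau[i], c=c[i]),
            BetaParams(A=A[i], f0=f0[i], sigma=sigma[i]),
            grid,
            noise_sd=cfg.psd_noise_sd,
            rng=rng,
            ripple_sd=cfg.psd_ripple_sd,
            ripple_scale_hz=cfg.psd_ripple_scale_hz,
        )
        for i in range(n_h)
    ]
    ts_list: list[TimeSeries] = []
    if signals:
        ts_list = [
            gen_lfp(
                BroadbandParams(a=a[i], tau=tau[i], c=c[i]),
                BetaParams(A=A[i], f0=f0[i], sigma=sigma[i]),
                cfg.duration_s,
                cfg.fs,
                seed=rng,
                label=ids[i],
            )
            for i in range(n_h)
        ]
    return SyntheticCohort(
        ground_truth=ground_truth,
        clinical=clinical,
        psds=psds,
        signals=ts_list,
        config=cfg,
    )
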