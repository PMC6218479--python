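"""Spectral model for subthalamic LFP power spectra.

The power spectral density (PSD) of a resting-state STN recording is
modeled as the sum of two physiologically distinct components:

* an aperiodic **broadband** background ``B(f) = a * exp(-f / tau) + c``
  — an exponential decay toward a constant floor ``c``, indexing the
  1/f-like background whose level reflects the synaptic
  excitation/inhibition balance (plus device noise in ``c``), and
* a periodic **beta** component ``G(f) = A * exp(-(f - f0)^2 / (2 sigma^2))``
  — a Gaussian peak in the 13–30 Hz band, the pathological rhythm of
  the untreated Parkinsonian state.

Fitting is performed in log10-power space over a configurable frequency
range (default 3–45 Hz, avoiding slow drift and 50 Hz line noise), in
three stages: a robust broadband fit with iterative peak masking, a
Gaussian fit to the positive residual in the beta band, and a joint
bounded least-squares refinement of all six parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.ndimage import uniform_filter1d

__all__ = [
    "TimeSeries",
    "PowerSpectrum",
    "BroadbandParams",
    "BetaParams",
    "FitConfig",
    "SpectralFit",
    "estimate_psd",
    "broadband_value",
    "beta_value",
    "model_psd",
    "fit_spectrum",
    "goodness_of_fit",
    "detect_raw_beta_peak",
    "BETA_BAND",
]

#: Canonical beta band (Hz).
BETA_BAND = (13.0, 30.0)

_LOG_FLOOR = 1e-300  # guards log10 of an exactly-zero model evaluation


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """A single-channel LFP recording.

    Parameters
    ----------
    samples
        Amplitude values in µV (arbitrary reference).
    sampling_rate
        Sampling rate in Hz; must exceed twice the highest analysis
        frequency (≥ 400 Hz to cover the 150–200 Hz broadband band).
    label
        Free-text channel/hemisphere label.
    """

    samples: np.ndarray
    sampling_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class PowerSpectrum:
    """A one-sided power spectral density on a uniform frequency grid.

    ``power`` is a spectral density in µV²/Hz. ``degenerate`` flags an
    all-zero spectrum (e.g. from an all-zero signal); downstream fitting
    refuses degenerate spectra.
    """

    frequencies: np.ndarray
    power: np.ndarray
    window_s: float | None = None
    overlap: float | None = None
    taper: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must have equal length")
        if self.frequencies.size >= 2 and not np.all(np.diff(self.frequencies) > 0):
            raise ValueError("frequencies must be strictly increasing")

    @property
    def df(self) -> float:
        """Frequency resolution (Hz)."""
        return float(self.frequencies[1] - self.frequencies[0])

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.frequencies >= lo) & (self.frequencies <= hi)


@dataclass(frozen=True)
class BroadbandParams:
    """Exponential broadband background ``B(f) = a*exp(-f/tau) + c``.

    ``a`` is the amplitude above the floor at 0 Hz, ``tau`` the decay
    constant in Hz, ``c`` the constant floor (device noise plateau).
    B is monotone non-increasing in frequency and tends to ``c``.
    """

    a: float
    tau: float
    c: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.a < 0 or self.c < 0:
            raise ValueError("a and c must be non-negative")


@dataclass(frozen=True)
class BetaParams:
    """Gaussian beta peak ``G(f) = A*exp(-(f-f0)^2 / (2 sigma^2))``."""

    A: float
    f0: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.A < 0:
            raise ValueError("A must be non-negative")


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the spectral fit; defaults suit 1 Hz resolution.

    ``fit_range`` excludes slow drift (< 3 Hz) and 50 Hz line noise.
    ``mask_threshold`` is the robust-SD multiple above which log-power
    residuals are treated as peak bins during the stage-1 broadband fit.
    """

    fit_range: tuple[float, float] = (3.0, 45.0)
    beta_band: tuple[float, float] = BETA_BAND
    sigma_bounds: tuple[float, float] = (0.5, 6.0)
    tau_bounds: tuple[float, float] = (0.5, 200.0)
    mask_threshold: float = 2.0
    max_mask_iter: int = 5
    no_peak_rel_threshold: float = 0.01
    min_bins: int = 20


@dataclass
class SpectralFit:
    """Result of fitting the two-component model to one PSD.

    ``residuals`` are modeled-minus-actual in log10-power space over the
    fitted bins.  ``no_peak`` marks spectra where no credible beta peak
    rises above the broadband background (A forced to 0 rather than
    erroring, so cohort pipelines keep every hemisphere).
    """

    broadband: BroadbandParams
    beta: BetaParams
    fit_range: tuple[float, float]
    r_squared: float
    residuals: np.ndarray
    no_peak: bool = False
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def broadband_value(p: BroadbandParams, f):
    """Evaluate the broadband background ``a*exp(-f/tau) + c`` at ``f`` (Hz)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = p.a * np.exp(-f / p.tau) + p.c
    return float(out) if out.ndim == 0 else out


def beta_value(p: BetaParams, f):
    """Evaluate the Gaussian beta peak at ``f`` (Hz)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = p.A * np.exp(-((f - p.f0) ** 2) / (2.0 * p.sigma**2))
    return float(out) if out.ndim == 0 else out


def model_psd(fit: SpectralFit, frequencies, allow_extrapolation: bool = False):
    """Modeled PSD (broadband + beta) at the given frequencies.

    Frequencies outside ``fit.fit_range`` are refused unless
    ``allow_extrapolation`` is set, since the model was only constrained
    inside the fitted range.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    lo, hi = fit.fit_range
    if not allow_extrapolation and (np.any(frequencies < lo) or np.any(frequencies > hi)):
        raise ValueError(
            "frequencies outside fit_range; pass allow_extrapolation=True to override"
        )
    return broadband_value(fit.broadband, frequencies) + beta_value(fit.beta, frequencies)


# ---------------------------------------------------------------------------
# PSD estimation
# ---------------------------------------------------------------------------

def estimate_psd(ts: TimeSeries, window_s: float = 1.0, overlap: float = 0.5) -> PowerSpectrum:
    """Welch PSD of a recording (one-sided density; DC bin dropped).

    Hann-tapered segments of ``window_s`` seconds with fractional
    ``overlap`` are averaged; frequency resolution is ``1/window_s``.

    Raises
    ------
    ValueError
        If the signal is shorter than two windows, contains non-finite
        samples (the first offending index is named), or ``overlap`` is
        outside [0, 1).
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if ts.duration_s < 2 * window_s:
        raise ValueError(
            f"signal of {ts.duration_s:.3f} s is shorter than two "
            f"{window_s:.3f} s windows"
        )
    bad = np.flatnonzero(~np.isfinite(ts.samples))
    if bad.size:
        raise ValueError(f"non-finite sample at index {bad[0]}")

    nperseg = int(round(window_s * ts.sampling_rate))
    noverlap = int(round(overlap * nperseg))
    freqs, power = signal.welch(
        ts.samples,
        fs=ts.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
    )
    # the DC bin carries the (detrended) mean, not physiology
    freqs, power = freqs[1:], power[1:]
    degenerate = bool(np.all(power == 0))
    return PowerSpectrum(
        frequencies=freqs,
        power=power,
        window_s=window_s,
        overlap=overlap,
        taper="hann",
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

#: Expected spectral-leakage kernel of a Hann-tapered periodogram at the
#: natural bin spacing 1/T: the window transform vanishes at offsets of
#: two or more bins, leaving exactly these three taps.
HANN_KERNEL = np.array([1.0, 4.0, 1.0]) / 6.0


def _smear(power_ext: np.ndarray, kernel: np.ndarray | None) -> np.ndarray:
    """Taper-leakage forward model: convolve (already edge-extended) power."""
    if kernel is None:
        return power_ext
    return np.convolve(power_ext, kernel, mode="valid")


def _extend(f: np.ndarray, pad: int) -> np.ndarray:
    df = f[1] - f[0]
    return np.concatenate(
        [f[0] + df * np.arange(-pad, 0), f, f[-1] + df * np.arange(1, pad + 1)]
    )


def _lin_broadband(theta, f):
    a, tau, c = theta
    return a * np.exp(-f / tau) + c


def _lin_model(theta, f):
    a, tau, c, amp, f0, sigma = theta
    return (
        a * np.exp(-f / tau)
        + c
        + amp * np.exp(-((f - f0) ** 2) / (2.0 * sigma**2))
    )


def _log_broadband(theta, f, kernel=None):
    return np.log10(np.maximum(_smear(_lin_broadband(theta, f), kernel), _LOG_FLOOR))


def _log_model(theta, f, kernel=None):
    return np.log10(np.maximum(_smear(_lin_model(theta, f), kernel), _LOG_FLOOR))


def _initial_broadband(f: np.ndarray, p: np.ndarray, cfg: FitConfig) -> np.ndarray:
    """Data-driven deterministic starting point for (a, tau, c)."""
    n_tail = max(3, f.size // 8)
    c0 = float(np.median(p[-n_tail:]))
    p_lo = float(np.median(p[: max(3, f.size // 8)]))
    a0 = max(p_lo - c0, 0.05 * max(p_lo, _LOG_FLOOR))
    # tau from the frequency where the excess above floor drops by e
    excess = p - c0
    target = a0 / math.e
    above = np.flatnonzero(excess > target)
    if above.size and above[-1] + 1 < f.size:
        tau0 = max(float(f[above[-1] + 1] - f[0]), 1.0)
    else:
        tau0 = 0.3 * (f[-1] - f[0])
    tau0 = float(np.clip(tau0, cfg.tau_bounds[0] * 1.01, cfg.tau_bounds[1] * 0.99))
    return np.array([a0, tau0, max(c0, 1e-3 * p_lo)])


def _robust_sd(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def fit_spectrum(psd: PowerSpectrum, config: FitConfig | None = None) -> SpectralFit:
    """Fit the Gaussian-beta + exponential-broadband model to a PSD.

    Three deterministic stages:

    1. Robust broadband fit: least squares of log10 B(f) against
       log10 power, iteratively masking bins whose residual exceeds
       ``mask_threshold`` robust SDs (the beta peak and any other
       narrowband excess), until the mask stabilizes or
       ``max_mask_iter`` iterations.
    2. Moment-based Gaussian initialization from the positive linear
       residual restricted to the beta band.  No positive residual ⇒
       A = 0 with the ``no_peak`` flag (not an error).
    3. Joint bounded least squares of all six parameters in
       log10-power space.

    The returned fit is bit-reproducible for identical inputs.
    """
    cfg = config or FitConfig()
    if psd.degenerate:
        raise ValueError("cannot fit a degenerate (all-zero) power spectrum")
    lo, hi = cfg.fit_range
    if lo < psd.frequencies[0] or hi > psd.frequencies[-1]:
        raise ValueError("fit_range must lie within the PSD frequency support")
    sel = psd.band_mask(lo, hi)
    f = psd.frequencies[sel]
    p = psd.power[sel]
    if f.size < cfg.min_bins:
        raise ValueError(f"need at least {cfg.min_bins} bins in fit_range, got {f.size}")
    if np.any(p <= 0):
        raise ValueError("power must be strictly positive within fit_range")
    y = np.log10(p)

    # Hann-tapered Welch estimates smear the spectrum with a known 3-tap
    # kernel; fold that into the forward model so the *intrinsic* peak
    # parameters (not the leakage-broadened ones) are recovered.
    kernel = HANN_KERNEL if psd.taper == "hann" else None
    f_ext = _extend(f, 1) if kernel is not None else f

    # --- stage 1: robust broadband fit with peak masking -------------------
    theta_bb = _initial_broadband(f, p, cfg)
    bb_lower = np.array([0.0, cfg.tau_bounds[0], 0.0])
    bb_upper = np.array([np.inf, cfg.tau_bounds[1], np.inf])
    theta_bb = np.clip(theta_bb, bb_lower + 1e-12, None)
    mask = np.ones(f.size, dtype=bool)
    for _ in range(cfg.max_mask_iter):
        res = optimize.least_squares(
            lambda th: _log_broadband(th, f_ext, kernel)[mask] - y[mask],
            theta_bb,
            bounds=(bb_lower, bb_upper),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        theta_bb = res.x
        resid = y - _log_broadband(theta_bb, f_ext, kernel)
        sd = max(_robust_sd(resid[mask]), 1e-12)
        new_mask = resid <= cfg.mask_threshold * sd
        if new_mask.sum() < cfg.min_bins // 2:  # never mask away the baseline
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask

    # --- stage 2: Gaussian init from the positive beta-band residual -------
    b_lo, b_hi = cfg.beta_band
    beta_sel = (f >= b_lo) & (f <= b_hi)
    lin_resid = p - 10.0 ** _log_broadband(theta_bb, f_ext, kernel)
    pos = lin_resid[beta_sel]
    fb = f[beta_sel]
    no_peak_stage2 = not np.any(pos > 0)
    if no_peak_stage2:
        amp0, f00, sig0 = 0.0, 0.5 * (b_lo + b_hi), 2.0
    else:
        i = int(np.argmax(pos))
        amp0 = float(pos[i])
        f00 = float(np.clip(fb[i], b_lo, b_hi))
        w = np.clip(pos, 0.0, None)
        sig0 = float(np.sqrt(np.sum(w * (fb - f00) ** 2) / np.sum(w))) if w.sum() > 0 else 2.0
        sig0 = float(np.clip(sig0, cfg.sigma_bounds[0] * 1.01, cfg.sigma_bounds[1] * 0.99))

    # --- stage 3: joint refinement in log10 space ---------------------------
    flags: list[str] = []
    if no_peak_stage2:
        res = optimize.least_squares(
            lambda th: _log_broadband(th, f_ext, kernel) - y,
            theta_bb,
            bounds=(bb_lower, bb_upper),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if not res.success:
            raise RuntimeError(
                f"broadband-only refinement failed to converge (stage 3): {res.x}"
            )
        a, tau, c = res.x
        amp, f00, sig0 = 0.0, 0.5 * (b_lo + b_hi), 2.0
        theta = np.array([a, tau, c, amp, f00, sig0])
    else:
        theta0 = np.array([*theta_bb, amp0, f00, sig0])
        lower = np.array([0.0, cfg.tau_bounds[0], 0.0, 0.0, b_lo, cfg.sigma_bounds[0]])
        upper = np.array(
            [np.inf, cfg.tau_bounds[1], np.inf, np.inf, b_hi, cfg.sigma_bounds[1]]
        )
        theta0 = np.clip(theta0, lower + 1e-12, upper - 1e-12)
        res = optimize.least_squares(
            lambda th: _log_model(th, f_ext, kernel) - y,
            theta0,
            bounds=(lower, upper),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
        if not res.success:
            raise RuntimeError(
                f"joint six-parameter refinement failed to converge (stage 3): {res.x}"
            )
        theta = res.x

    a, tau, c, amp, f0_fit, sigma_fit = theta
    bb = BroadbandParams(a=float(a), tau=float(tau), c=float(c))
    no_peak = no_peak_stage2 or amp <= cfg.no_peak_rel_threshold * broadband_value(
        bb, float(f0_fit)
    )
    if no_peak:
        flags.append("no-peak")
    beta = BetaParams(
        A=float(amp),
        f0=float(np.clip(f0_fit, b_lo, b_hi)),
        sigma=float(sigma_fit),
    )
    residuals = _log_model(theta, f_ext, kernel) - y

    fit = SpectralFit(
        broadband=bb,
        beta=beta,
        fit_range=(lo, hi),
        r_squared=float("nan"),
        residuals=residuals,
        no_peak=no_peak,
        flags=flags,
    )
    fit.r_squared = goodness_of_fit(fit, psd)
    return fit


def goodness_of_fit(fit: SpectralFit, psd: PowerSpectrum) -> float:
    """Coefficient of determination between modeled and actual log10 PSD.

    Computed over the fit range only; 1 means a perfect fit, 0 the
    skill of the mean spectrum, negative worse than the mean.
    """
    sel = psd.band_mask(*fit.fit_range)
    y = np.log10(psd.power[sel])
    f = psd.frequencies[sel]
    if psd.taper == "hann":
        # compare in observed space: the Welch estimate smears the model
        modeled = _smear(model_psd(fit, _extend(f, 1), allow_extrapolation=True), HANN_KERNEL)
    else:
        modeled = model_psd(fit, f, allow_extrapolation=True)
    yhat = np.log10(np.maximum(modeled, _LOG_FLOOR))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual spectrum has zero variance over the fit range")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def detect_raw_beta_peak(
    psd: PowerSpectrum, band: tuple[float, float] = BETA_BAND
) -> tuple[float, float, bool]:
    """Locate the beta peak on the raw (lightly smoothed) spectrum.

    A 3-bin moving average suppresses single-bin estimator spikes; the
    maximum within ``band`` is returned as ``(peak_freq, peak_power,
    edge_peak)``.  Ties break toward the lower frequency.  ``edge_peak``
    is True when the maximum sits on a band edge, i.e. there is no
    interior peak (typical of a peak-free, monotone broadband spectrum).
    """
    sel = psd.band_mask(*band)
    if not np.any(sel):
        raise ValueError("beta band contains no frequency bins")
    smoothed = uniform_filter1d(psd.power, size=3, mode="nearest")
    idx = np.flatnonzero(sel)
    i = idx[int(np.argmax(smoothed[idx]))]  # argmax returns first max: low-f tie-break
    edge = i == idx[0] or i == idx[-1]
    return float(psd.frequencies[i]), float(smoothed[i]), bool(edge)
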