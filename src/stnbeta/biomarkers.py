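"""Beta-band biomarkers derived from the two-component spectral model.

Two competing definitions of "beta activity" are contrasted throughout:

* **without broadband** — the Gaussian amplitude ``A``, i.e. the height
  of the oscillatory peak above the aperiodic background;
* **with broadband** — the total modeled power at the peak frequency,
  ``A + B(f0)``, the quantity a naive band-power reading picks up.

Both are also computed on the actual (unmodeled) spectrum via the raw
smoothed peak, with and without subtraction of the fitted broadband.
The per-frequency broadband profile and 1-s sliding-window time courses
feed the cohort-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .spectral import (
    BETA_BAND,
    PowerSpectrum,
    SpectralFit,
    TimeSeries,
    broadband_value,
    detect_raw_beta_peak,
)

__all__ = [
    "BiomarkerSet",
    "SlidingWindowSeries",
    "beta_without_broadband",
    "beta_with_broadband",
    "actual_beta_biomarkers",
    "broadband_profile",
    "compute_biomarkers",
    "biomarker_table",
    "sliding_window_series",
    "variability",
]

#: Center of the beta band, used when no peak was fitted.
BAND_CENTER = 0.5 * (BETA_BAND[0] + BETA_BAND[1])

#: Default grid for per-frequency broadband profiles (Hz).
PROFILE_GRID = np.arange(1.0, 201.0)


@dataclass
class BiomarkerSet:
    """Per-hemisphere biomarker bundle (one row of the cohort table)."""

    hemisphere_id: str
    beta_without_bb: float
    beta_with_bb: float
    actual_without_bb: float
    actual_with_bb: float
    peak_freq: float
    r_squared: float
    broadband_profile: np.ndarray
    flags: tuple[str, ...] = ()


@dataclass
class SlidingWindowSeries:
    """Beta / broadband amplitude time courses over sliding windows.

    Amplitudes are mean log10 band power, mean-centered per recording
    (so only fluctuations, not absolute levels, are compared).
    """

    window_starts: np.ndarray
    beta_amp: np.ndarray
    bb_amp: np.ndarray
    window_s: float = 1.0
    overlap: float = 0.95

    @property
    def step_s(self) -> float:
        return self.window_s * (1.0 - self.overlap)

    @property
    def n_windows(self) -> int:
        return self.window_starts.size


def beta_without_broadband(fit: SpectralFit) -> float:
    """Beta amplitude isolated from the background: the Gaussian height A.

    No-peak fits contribute 0 (the flag travels with the fit) so cohort
    pipelines keep every hemisphere.
    """
    return 0.0 if fit.no_peak else fit.beta.A


def beta_with_broadband(fit: SpectralFit) -> float:
    """Total modeled power at the beta peak, broadband included.

    ``A + B(f0)``; for no-peak fits, the broadband value at the band
    center (21.5 Hz), i.e. what a band-power biomarker would report.
    """
    if fit.no_peak:
        return broadband_value(fit.broadband, BAND_CENTER)
    return fit.beta.A + broadband_value(fit.broadband, fit.beta.f0)


def actual_beta_biomarkers(
    psd: PowerSpectrum, fit: SpectralFit, band: tuple[float, float] = BETA_BAND
) -> tuple[float, float]:
    """Biomarker pair read off the actual spectrum rather than the model.

    ``with_bb`` is the lightly smoothed raw PSD value at the detected
    peak; ``without_bb`` subtracts the fitted broadband at the same
    frequency (floored at zero).  Exactly: with_bb − without_bb =
    min(with_bb, B(peak_freq)).
    """
    peak_freq, peak_power, _edge = detect_raw_beta_peak(psd, band)
    with_bb = peak_power
    without_bb = max(peak_power - broadband_value(fit.broadband, peak_freq), 0.0)
    return with_bb, without_bb


def broadband_profile(fit: SpectralFit, grid=PROFILE_GRID) -> np.ndarray:
    """Fitted broadband power evaluated per frequency bin of ``grid``."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("profile grid must be non-negative")
    return broadband_value(fit.broadband, grid)


def compute_biomarkers(
    psd: PowerSpectrum,
    fit: SpectralFit,
    hemisphere_id: str = "",
    grid=PROFILE_GRID,
) -> BiomarkerSet:
    """Bundle all per-hemisphere biomarkers from one spectrum + fit."""
    with_bb, without_bb = actual_beta_biomarkers(psd, fit)
    peak = BAND_CENTER if fit.no_peak else fit.beta.f0
    return BiomarkerSet(
        hemisphere_id=hemisphere_id,
        beta_without_bb=beta_without_broadband(fit),
        beta_with_bb=beta_with_broadband(fit),
        actual_without_bb=without_bb,
        actual_with_bb=with_bb,
        peak_freq=peak,
        r_squared=fit.r_squared,
        broadband_profile=broadband_profile(fit, grid),
        flags=tuple(fit.flags),
    )


def biomarker_table(sets: list[BiomarkerSet]) -> pd.DataFrame:
    """Tidy one-row-per-hemisphere table of scalar biomarkers."""
    return pd.DataFrame(
        {
            "hemisphere_id": [s.hemisphere_id for s in sets],
            "beta_without_bb": [s.beta_without_bb for s in sets],
            "beta_with_bb": [s.beta_with_bb for s in sets],
            "actual_without_bb": [s.actual_without_bb for s in sets],
            "actual_with_bb": [s.actual_with_bb for s in sets],
            "peak_freq": [s.peak_freq for s in sets],
            "r_squared": [s.r_squared for s in sets],
            "flags": [";".join(s.flags) for s in sets],
        }
    )


def sliding_window_series(
    ts: TimeSeries,
    ref_fit: SpectralFit,
    window_s: float = 1.0,
    overlap: float = 0.95,
    beta_band: tuple[float, float] = BETA_BAND,
    bb_band: tuple[float, float] = (35.0, 45.0),
) -> SlidingWindowSeries:
    """Sub-second time courses of beta and broadband levels.

    Each 1-s window (95 % overlap ⇒ 50 ms stride) gets a single-taper
    (Hann) periodogram.  ``beta_amp`` is the mean log10 power in the
    beta band minus the reference fit's broadband log-level there, so a
    rise in the background does not read as a rise in beta; ``bb_amp``
    is the mean log10 power in a peak-free band (default 35–45 Hz)
    tracking the background itself.  Both series are mean-centered per
    recording; their standard deviations quantify sub-second stability,
    the quantity relevant to closed-loop stimulation triggers.
    """
    if window_s > ts.duration_s:
        raise ValueError("window longer than recording")
    if ts.duration_s < 10.0:
        raise ValueError("recording must be at least 10 s for stable window series")
    fs = ts.sampling_rate
    nwin = int(round(window_s * fs))
    step = window_s * (1.0 - overlap)
    # keep the nominal stride exactly: start indices are rounded per
    # window rather than accumulating an integer-sample step
    n_windows = int(np.floor((ts.duration_s - window_s) / step + 1e-9)) + 1
    starts_idx = np.round(step * fs * np.arange(n_windows)).astype(int)
    starts_idx = np.minimum(starts_idx, ts.n_samples - nwin)

    idx = np.arange(nwin)[None, :] + starts_idx[:, None]
    frames = ts.samples[idx]
    taper = _sig.get_window("hann", nwin)
    scale = 1.0 / (fs * np.sum(taper**2))
    spec = np.fft.rfft(frames * taper, axis=1)
    psd = (np.abs(spec) ** 2) * scale
    psd[:, 1:-1] *= 2.0  # one-sided density
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)

    def _band_log(lo: float, hi: float) -> np.ndarray:
        m = (freqs >= lo) & (freqs <= hi)
        return np.log10(np.maximum(psd[:, m], 1e-300)).mean(axis=1)

    ref_bb = broadband_value(ref_fit.broadband, freqs)
    beta_m = (freqs >= beta_band[0]) & (freqs <= beta_band[1])
    ref_level = float(np.log10(ref_bb[beta_m]).mean())
    beta_amp = _band_log(*beta_band) - ref_level
    bb_amp = _band_log(*bb_band)
    beta_amp = beta_amp - beta_amp.mean()
    bb_amp = bb_amp - bb_amp.mean()

    starts = starts_idx / fs
    return SlidingWindowSeries(
        window_starts=starts,
        beta_amp=beta_amp,
        bb_amp=bb_amp,
        window_s=window_s,
        overlap=overlap,
    )


def variability(s: SlidingWindowSeries) -> tuple[float, float]:
    """Sample SDs of the beta and broadband window series.

    The pair (sd_beta, sd_bb) quantifies how stable each component is
    over time within one recording.
    """
    if s.n_windows < 2:
        raise ValueError("need at least two windows to compute variability")
    return (
        float(np.std(s.beta_amp, ddof=1)),
        float(np.std(s.bb_amp, ddof=1)),
    )
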