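"""End-to-end convenience: spectra → fits → biomarkers → cohort statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .biomarkers import PROFILE_GRID, biomarker_table, compute_biomarkers
from .spectral import FitConfig, PowerSpectrum, SpectralFit, fit_spectrum
from .stats import build_cohort, compare_biomarkers, correlation_profile
from .synthetic import SyntheticCohort

__all__ = ["fit_cohort", "analyze_cohort"]


def fit_cohort(
    psds: list[PowerSpectrum],
    ids: list[str] | None = None,
    config: FitConfig | None = None,
    grid=PROFILE_GRID,
) -> tuple[list[SpectralFit], pd.DataFrame, np.ndarray]:
    """Fit every hemisphere's spectrum and tabulate its biomarkers.

    Returns the fits, the tidy biomarker table and the hemispheres ×
    bins matrix of broadband profiles on ``grid``.
    """
    ids = ids or [f"h{i:02d}" for i in range(len(psds))]
    fits = [fit_spectrum(psd, config) for psd in psds]
    sets = [
        compute_biomarkers(psd, fit, hemisphere_id=i, grid=grid)
        for psd, fit, i in zip(psds, fits, ids)
    ]
    profiles = np.vstack([s.broadband_profile for s in sets])
    return fits, biomarker_table(sets), profiles


def analyze_cohort(
    cohort: SyntheticCohort,
    fit_config: FitConfig | None = None,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int = 0,
    profile_covariates: tuple[str, ...] = ("bradykinesia", "rigidity", "tremor", "age"),
) -> dict:
    """Run the full analysis a cohort of recordings would get.

    Returns a dict with keys ``fits``, ``biomarkers``, ``table`` (the
    joined cohort table), ``comparisons`` (with/without-broadband
    correlation contrasts) and ``profiles`` (per-frequency broadband
    correlation profile per covariate).
    """
    grid = PROFILE_GRID
    fits, bio, profiles = fit_cohort(
        cohort.psds, cohort.hemisphere_ids, fit_config, grid
    )
    table = build_cohort(bio, cohort.clinical)
    comparisons = compare_biomarkers(table, alpha=alpha, n_boot=n_boot, seed=seed)
    prof_results = {
        cov: correlation_profile(
            profiles, table[cov].to_numpy(dtype=float), grid, alpha=alpha
        )
        for cov in profile_covariates
        if table[cov].nunique() > 1
    }
    return {
        "fits": fits,
        "biomarkers": bio,
        "profiles_matrix": profiles,
        "grid": grid,
        "table": table,
        "comparisons": comparisons,
        "profiles": prof_results,
    }
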