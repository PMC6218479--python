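"""Plain-text readers and writers binding the pipeline together.

All on-disk formats are text: delimited signal files with a JSON
sidecar for the sampling rate, two-column PSD CSVs, JSON fit reports,
tidy biomarker and clinical CSVs, and YAML/JSON configuration.  Power
is stored in linear units; log transforms are internal only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectral import (
    BetaParams,
    BroadbandParams,
    FitConfig,
    PowerSpectrum,
    SpectralFit,
    TimeSeries,
)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_psd_csv",
    "write_psd_csv",
    "fit_to_dict",
    "write_fit_json",
    "read_fit_json",
    "read_clinical_csv",
    "load_config",
    "dump_config",
]

_FLOAT_FMT = "%.17g"  # full round-trip precision

CLINICAL_SCHEMA = ["hemisphere_id", "bradykinesia", "rigidity", "tremor", "age"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    """Single-column text file plus a JSON sidecar with the metadata."""
    path = Path(path)
    np.savetxt(path, ts.samples, fmt=_FLOAT_FMT)
    meta = {"sampling_rate_hz": ts.sampling_rate, "label": ts.label, "units": "uV"}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_timeseries(path: str | Path, sampling_rate: float | None = None) -> TimeSeries:
    """Read a one- or two-column delimited signal file.

    With two columns the first is time (ignored beyond inferring the
    rate when no sidecar exists).  The sampling rate comes from, in
    order: the ``sampling_rate`` argument, the JSON sidecar
    (``<file>.json``), or the time column.
    """
    path = Path(path)
    data = np.loadtxt(path, delimiter=None if path.suffix != ".csv" else ",", ndmin=2)
    if data.shape[1] == 1:
        samples, t = data[:, 0], None
    elif data.shape[1] == 2:
        t, samples = data[:, 0], data[:, 1]
    else:
        raise ValueError(f"{path}: expected 1 or 2 columns, got {data.shape[1]}")
    label = path.stem
    if sampling_rate is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if "sampling_rate_hz" not in meta:
                raise ValueError(f"{sidecar}: sidecar missing sampling_rate_hz")
            sampling_rate = float(meta["sampling_rate_hz"])
            label = meta.get("label", label)
        elif t is not None:
            sampling_rate = 1.0 / float(np.median(np.diff(t)))
        else:
            raise ValueError(f"{path}: no sampling rate (no sidecar, argument or time column)")
    return TimeSeries(samples=samples, sampling_rate=float(sampling_rate), label=label)


def write_psd_csv(psd: PowerSpectrum, path: str | Path) -> None:
    pd.DataFrame({"frequency_hz": psd.frequencies, "power": psd.power}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_psd_csv(path: str | Path) -> PowerSpectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("frequency_hz", "power"):
        if col not in df.columns:
            raise ValueError(f"{path}: PSD CSV missing column {col!r}")
    f = df["frequency_hz"].to_numpy(dtype=float)
    window_s = 1.0 / float(f[1] - f[0]) if f.size > 1 else None
    return PowerSpectrum(
        frequencies=f, power=df["power"].to_numpy(dtype=float), window_s=window_s
    )


def fit_to_dict(fit: SpectralFit) -> dict:
    return {
        "broadband": {"a": fit.broadband.a, "tau": fit.broadband.tau, "c": fit.broadband.c},
        "beta": {"A": fit.beta.A, "f0": fit.beta.f0, "sigma": fit.beta.sigma},
        "fit_range": list(fit.fit_range),
        "r_squared": fit.r_squared,
        "flags": list(fit.flags),
    }


def write_fit_json(fit: SpectralFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2) + "\n")


def read_fit_json(path: str | Path) -> SpectralFit:
    d = json.loads(Path(path).read_text())
    return SpectralFit(
        broadband=BroadbandParams(**d["broadband"]),
        beta=BetaParams(**d["beta"]),
        fit_range=tuple(d["fit_range"]),
        r_squared=d["r_squared"],
        residuals=np.array([]),
        no_peak="no-peak" in d["flags"],
        flags=list(d["flags"]),
    )


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CLINICAL_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical CSV missing columns: {', '.join(missing)}")
    return df


def load_config(path: str | Path, cls):
    """Load a YAML/JSON config into dataclass ``cls``, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    for f in dataclasses.fields(cls):
        if f.name in raw and isinstance(raw[f.name], list):
            raw[f.name] = tuple(raw[f.name])
    return cls(**raw)


def dump_config(cfg, path: str | Path) -> None:
    """Write the fully resolved config next to a run's outputs."""
    d = dataclasses.asdict(cfg)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# default fit config is importable for CLI resolution
DEFAULT_FIT_CONFIG = FitConfig()
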