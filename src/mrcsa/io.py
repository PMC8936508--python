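"""File I/O: delimited-text and array-archive readers, writers, fixtures.

CSV dialect is fixed (comma separator, '.' decimal, UTF-8, optional single
header row) so files round-trip independently of locale.  Every run writes a
JSON manifest echoing the resolved parameters so that a run can be reproduced
from the manifest alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import MrcsaConfig, SpectrumEstimate, TimeSeriesPair, ValidationError
from .connectivity import ComparisonResult, ConnectivityResult, MultichannelTrials
from .estimators import FractalFraction, SlopeFit
from .simulate import (
    McArfimaParams,
    OscillationSpec,
    inject_oscillations,
    simulate_mc_arfima,
    synthesize_powerlaw_pair,
)

__all__ = [
    "read_pair",
    "read_multichannel",
    "write_pair",
    "write_spectrum",
    "write_matrix",
    "write_comparison",
    "write_manifest",
    "results_record",
    "generate_fixture",
    "FIXTURE_SCENARIOS",
]


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    first = path.open(encoding="utf-8").readline()
    has_header = any(
        not _is_number(tok) for tok in first.strip().split(sep) if tok != ""
    )
    df = pd.read_csv(
        path,
        sep=sep,
        header=0 if has_header else None,
        encoding="utf-8",
        float_precision="round_trip",
    )
    if not has_header:
        df.columns = [f"ch{i}" for i in range(df.shape[1])]
    bad = df.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        raise ValidationError(f"missing/invalid value at row {row}, column {col!r} of {path}")
    return df


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_pair(path: str | Path, fs: float, columns: tuple[int, int] = (0, 1)) -> TimeSeriesPair:
    """Read a two-channel pair from delimited text (samples in rows)."""
    df = _read_table(Path(path))
    if df.shape[1] < 2:
        raise ValidationError(f"{path} has {df.shape[1]} column(s); a pair needs two")
    i, j = columns
    return TimeSeriesPair(df.iloc[:, i].to_numpy(), df.iloc[:, j].to_numpy(), fs)


def read_multichannel(
    path: str | Path,
    fs: float | None = None,
    fmt: str | None = None,
    trial_length: int | None = None,
) -> MultichannelTrials:
    """Read a multichannel recording from CSV/TSV, NPZ or EDF.

    CSV columns map to channels in header order (samples in rows).  NPZ
    archives hold ``data`` (channels x samples or channels x samples x
    trials) plus optional ``fs`` and ``labels``.  ``trial_length`` splits a
    continuous recording into equally long trials.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".npz": "npz", ".edf": "edf"}.get(path.suffix.lower(), "csv")
    if fmt == "csv":
        df = _read_table(path)
        data = df.to_numpy().T
        labels = [str(c) for c in df.columns]
        if fs is None:
            raise ValidationError("a sampling rate is required for delimited-text input")
    elif fmt == "npz":
        if not path.exists():
            raise ValidationError(f"input file not found: {path}")
        archive = np.load(path, allow_pickle=False)
        if "data" not in archive:
            raise ValidationError(f"{path} lacks a 'data' array")
        data = archive["data"]
        if fs is None:
            if "fs" not in archive:
                raise ValidationError(f"{path} embeds no sampling rate and none was given")
            fs = float(archive["fs"])
        labels = (
            [str(l) for l in archive["labels"]]
            if "labels" in archive
            else [f"ch{i}" for i in range(data.shape[0])]
        )
    elif fmt == "edf":
        try:
            import mne
        except ImportError as exc:
            raise ValidationError("EDF input requires the optional 'mne' dependency") from exc
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
        data = raw.get_data()
        fs = float(raw.info["sfreq"])
        labels = list(raw.ch_names)
    else:
        raise ValidationError(f"unknown format {fmt!r}; expected csv, npz or edf")

    data = np.asarray(data, dtype=float)
    if trial_length is not None:
        if data.ndim != 2:
            raise ValidationError("trial_length only applies to continuous 2-D input")
        n_trials = data.shape[1] // trial_length
        if n_trials < 1:
            raise ValidationError(
                f"trial_length {trial_length} exceeds the recording length {data.shape[1]}"
            )
        data = data[:, : n_trials * trial_length].reshape(data.shape[0], n_trials, trial_length)
        data = np.transpose(data, (0, 2, 1))
    return MultichannelTrials(data=data, fs=fs, channel_labels=labels)


def write_pair(pair: TimeSeriesPair, path: str | Path, labels: tuple[str, str] = ("x", "y")) -> None:
    pd.DataFrame({labels[0]: pair.x, labels[1]: pair.y}).to_csv(path, index=False)


def write_spectrum(spec: SpectrumEstimate, path: str | Path) -> None:
    pd.DataFrame({"freq": spec.freqs, "mixed": spec.mixed, "fractal": spec.fractal}).to_csv(
        path, index=False
    )


def write_matrix(matrix: np.ndarray, labels: list[str], path: str | Path) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path)


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_comparison(result: ComparisonResult, path: str | Path) -> None:
    edges = result.edges.copy()
    edges["family"] = "edge"
    diag = result.diagonal.copy()
    diag["family"] = "auto"
    pd.concat([edges, diag], ignore_index=True).to_csv(path, index=False)


def config_record(config: MrcsaConfig) -> dict:
    return {
        "h_values": list(map(float, config.scheme.h_values)),
        "n_segments": config.segmentation.n_segments,
        "segment_fraction": config.segmentation.fraction,
        "fit_band": list(config.fit_band),
        "window": config.window,
        "smooth_rel_bw": config.smooth_rel_bw,
        "smooth_min_bins": config.smooth_min_bins,
    }


def write_manifest(path: str | Path, command: str, **fields) -> None:
    manifest = {"command": command, "version": __version__, **fields}
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")


def results_record(fit: SlopeFit, fraction: FractalFraction) -> dict:
    """Tidy record of a slope fit and fractal fraction for JSON/CSV output."""
    return {
        "beta_xy": fit.beta,
        "intercept": fit.intercept,
        "band": list(fit.band),
        "n_points": fit.n_points,
        "r_squared": fit.r_squared,
        "percent_fractal": fraction.percent,
    }


FIXTURE_SCENARIOS = (
    "pure_arfima",
    "arfima_osc10",
    "arfima_osc10_20",
    "powerlaw_oracle",
    "multichannel_demo",
)


def generate_fixture(name: str, seed: int, out_dir: str | Path) -> dict:
    """Write a deterministic simulation scenario (CSV + manifest) to ``out_dir``.

    Returns the manifest dictionary, which records the theoretical
    cross-spectral exponent of the generated data.
    """
    if name not in FIXTURE_SCENARIOS:
        raise ValidationError(
            f"unknown scenario {name!r}; choose one of {', '.join(FIXTURE_SCENARIOS)}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fs = 500.0
    n = 10_000
    manifest: dict = {"scenario": name, "seed": seed, "fs": fs, "n_samples": n}

    if name == "powerlaw_oracle":
        beta_x, beta_y = 0.4, 0.6
        pair = synthesize_powerlaw_pair(beta_x, beta_y, 8192, fs, seed)
        manifest.update(
            beta_x=beta_x, beta_y=beta_y, beta_theoretical=(beta_x + beta_y) / 2, n_samples=8192
        )
        write_pair(pair, out / "pair.csv")
    elif name == "multichannel_demo":
        rng = np.random.default_rng(seed)
        betas = [0.4, 0.8]
        chans = [synthesize_powerlaw_pair(b, b, 4096, fs, rng).x for b in betas]
        data = np.stack(chans)[:, :, None]
        np.savez(out / "trials.npz", data=data, fs=fs, labels=np.array(["chA", "chB"]))
        manifest.update(beta_channels=betas, n_samples=4096, n_trials=1)
    else:
        params = McArfimaParams()
        pair = simulate_mc_arfima(params, n, fs, seed)
        oscs = {
            "pure_arfima": [],
            "arfima_osc10": [OscillationSpec(10.0, 0.64)],
            "arfima_osc10_20": [OscillationSpec(10.0, 0.64), OscillationSpec(20.0, 0.64)],
        }[name]
        pair = inject_oscillations(pair, oscs, params.beta_theoretical, seed + 1)
        manifest.update(
            beta_theoretical=params.beta_theoretical,
            params=asdict(params),
            oscillations=[asdict(o) for o in oscs],
        )
        write_pair(pair, out / "pair.csv")

    write_manifest(out / "manifest.json", "simulate", **manifest)
    return manifest
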