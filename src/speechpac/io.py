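"""Plain-text and WAV I/O for signals, spectra, comodulograms and cohorts.

All tabular artifacts are TSV with a single ``#``-prefixed metadata line
(key=value pairs) so files round-trip without sidecar lookups; cohort
directories additionally carry a JSON manifest with the generating config
and per-subject ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .pac import Comodulogram
from .signals import EnvelopeSignal, RoiTimeSeries
from .synthetic import Cohort, CohortEntry, SyntheticCohortConfig

__all__ = [
    "write_envelope_tsv",
    "read_envelope_tsv",
    "write_roi_tsv",
    "read_roi_tsv",
    "write_spectrum_tsv",
    "write_comodulogram_tsv",
    "read_comodulogram_tsv",
    "write_cohort",
    "read_cohort",
    "sonify_envelope",
    "write_wav",
    "read_wav",
]


def _meta_line(**kwargs) -> str:
    return "# " + " ".join(f"{k}={v}" for k, v in kwargs.items()) + "\n"


def _read_meta(path: Path) -> Dict[str, str]:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        return {}
    out = {}
    for token in first[1:].split():
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def _signal_frame(trials: np.ndarray, fs: float) -> pd.DataFrame:
    n_trials, n_samples = trials.shape
    return pd.DataFrame(
        {
            "trial": np.repeat(np.arange(n_trials), n_samples),
            "time_s": np.tile(np.arange(n_samples) / fs, n_trials),
            "value": trials.reshape(-1),
        }
    )


def _write_signal(path, trials, fs, **meta) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_meta_line(fs=fs, **meta))
        _signal_frame(trials, fs).to_csv(
            fh, sep="\t", index=False, float_format="%.8g"
        )


def _read_signal(path):
    meta = _read_meta(Path(path))
    df = pd.read_csv(path, sep="\t", comment="#")
    n_trials = df["trial"].nunique()
    trials = df["value"].to_numpy().reshape(n_trials, -1)
    return trials, float(meta["fs"]), meta


def write_envelope_tsv(envelope: EnvelopeSignal, path) -> None:
    _write_signal(
        path, envelope.trials, envelope.fs, condition=envelope.condition
    )


def read_envelope_tsv(path) -> EnvelopeSignal:
    trials, fs, meta = _read_signal(path)
    return EnvelopeSignal(
        trials=trials, fs=fs, condition=meta.get("condition", "normal")
    )


def write_roi_tsv(ts: RoiTimeSeries, path) -> None:
    _write_signal(
        path,
        ts.trials,
        ts.fs,
        subject=ts.subject,
        condition=ts.condition,
        roi=ts.roi,
    )


def read_roi_tsv(path) -> RoiTimeSeries:
    trials, fs, meta = _read_signal(path)
    return RoiTimeSeries(
        trials=trials,
        fs=fs,
        subject=meta.get("subject", "S01"),
        condition=meta.get("condition", "normal"),
        roi=meta.get("roi", "LAC"),
    )


def write_spectrum_tsv(
    freqs: np.ndarray, values: np.ndarray, path, value_col: str = "power", **meta
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if meta:
            fh.write(_meta_line(**meta))
        pd.DataFrame({"freq_hz": freqs, value_col: values}).to_csv(
            fh, sep="\t", index=False, float_format="%.8g"
        )


def write_comodulogram_tsv(comod: Comodulogram, path) -> None:
    """Long-format TSV (phase_hz, amp_hz, mi_bits) plus a JSON sidecar."""
    path = Path(path)
    fp, fa = np.meshgrid(comod.phase_freqs, comod.amp_freqs, indexing="ij")
    pd.DataFrame(
        {
            "phase_hz": fp.reshape(-1),
            "amp_hz": fa.reshape(-1),
            "mi_bits": comod.mi.reshape(-1),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")
    sidecar = {
        "phase_source": comod.phase_source,
        "subject": comod.subject,
        "condition": comod.condition,
        "roi": comod.roi,
        "n_phase_freqs": int(len(comod.phase_freqs)),
        "n_amp_freqs": int(len(comod.amp_freqs)),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1)
    )


def read_comodulogram_tsv(path) -> Comodulogram:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    phase_freqs = np.unique(df["phase_hz"].to_numpy())
    amp_freqs = np.unique(df["amp_hz"].to_numpy())
    mi = df["mi_bits"].to_numpy().reshape(len(phase_freqs), len(amp_freqs))
    return Comodulogram(
        phase_freqs=phase_freqs,
        amp_freqs=amp_freqs,
        mi=mi,
        phase_source=meta.get("phase_source", "stimulus"),
        subject=meta.get("subject", ""),
        condition=meta.get("condition", ""),
        roi=meta.get("roi", ""),
    )


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """One TSV per subject x condition (envelope) and per ROI (neural),
    plus ``manifest.json`` echoing the config and per-subject ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for entry in cohort.entries:
        stem = f"{entry.subject}_{entry.condition}"
        env_path = out_dir / f"{stem}_envelope.tsv"
        write_envelope_tsv(entry.envelope, env_path)
        files.append(env_path.name)
        for roi, ts in entry.neural.items():
            roi_path = out_dir / f"{stem}_{roi}.tsv"
            write_roi_tsv(ts, roi_path)
            files.append(roi_path.name)
    manifest = {
        "config": _config_to_dict(cohort.config),
        "ground_truth": cohort.ground_truth,
        "files": files,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir / "manifest.json"


def _config_to_dict(config: SyntheticCohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["rois"] = list(d["rois"])
    return d


def config_from_dict(d: dict) -> SyntheticCohortConfig:
    d = dict(d)
    if "rois" in d:
        d["rois"] = tuple(d["rois"])
    return SyntheticCohortConfig(**d)


def read_cohort(in_dir) -> Cohort:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    config = config_from_dict(manifest["config"])
    entries = []
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        for condition in config.tempo_factors:
            stem = f"{subject}_{condition}"
            env = read_envelope_tsv(in_dir / f"{stem}_envelope.tsv")
            neural = {
                roi: read_roi_tsv(in_dir / f"{stem}_{roi}.tsv")
                for roi in config.rois
            }
            entries.append(
                CohortEntry(
                    subject=subject,
                    condition=condition,
                    envelope=env,
                    neural=neural,
                )
            )
    return Cohort(
        config=config, entries=entries, ground_truth=manifest["ground_truth"]
    )


def sonify_envelope(
    envelope: EnvelopeSignal,
    audio_fs: float = 8000.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Amplitude-modulated white noise carrying the envelope (audible check).

    Returns a waveform at ``audio_fs`` whose cochlear envelope recovers the
    input, which exercises the envelope-extraction path end to end.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    env = envelope.concatenated()
    n_out = int(round(env.size * audio_fs / envelope.fs))
    t_env = np.arange(env.size) / envelope.fs
    t_out = np.arange(n_out) / audio_fs
    env_up = np.interp(t_out, t_env, env)
    carrier = rng.standard_normal(n_out)
    wave = env_up * carrier
    peak = np.max(np.abs(wave))
    return wave / peak * 0.9 if peak > 0 else wave


def write_wav(path, waveform: np.ndarray, fs: float) -> None:
    wavfile.write(path, int(fs), waveform.astype(np.float32))


def read_wav(path):
    """Read a WAV file; integer PCM is rescaled to [-1, 1] floats."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:  # average stereo to mono
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return data, float(fs)
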