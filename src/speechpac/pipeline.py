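"""End-to-end workflow: simulate -> envelope -> entrain -> pac -> stats -> report.

Each stage is a plain function operating on in-memory objects and writing
plain-text outputs, so stages can also be re-run independently from the
files a previous stage produced.  ``run_all`` chains them and records a
run manifest (config hash, seed, package version, per-stage file listing,
timestamps).  Result tables are written deterministically: an identical
config yields byte-identical tables.

Outputs per condition and ROI mirror the standard reporting layout of
rate-manipulation studies: group coherence spectra, comodulograms, cluster
masks, per-subject peak tables, group mean(SE) summaries, and an ordering
summary of peak frequencies versus tempo factor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as spio
from .entrainment import (
    BandDefinition,
    band_peak,
    coherence_spectrum,
    delta_band,
    surrogate_coherence_spectrum,
    theta_band,
)
from .envelope import envelope_power_spectrum
from .pac import PacConfig, comodulogram, pac_peak, surrogate_comodulogram
from .stats import PermutationConfig, cluster_permutation_paired, significant_mask
from .synthetic import Cohort, SyntheticCohortConfig, generate_cohort

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "load_config",
    "config_hash",
    "run_all",
    "report_tables",
    "ordering_summary",
]

logger = logging.getLogger(__name__)

_PKG_VERSION = "0.1.0"


@dataclasses.dataclass
class PipelineConfig:
    """Parsed pipeline configuration (one section per stage)."""

    simulate: SyntheticCohortConfig
    pac: PacConfig
    stats: PermutationConfig
    phase_source: str = "stimulus"
    theta_bands: Optional[Dict[str, BandDefinition]] = None
    delta_bands: Optional[Dict[str, BandDefinition]] = None
    raw: dict = dataclasses.field(default_factory=dict)

    def theta_band_for(self, condition: str) -> BandDefinition:
        if self.theta_bands and condition in self.theta_bands:
            return self.theta_bands[condition]
        return theta_band(condition)

    def delta_band_for(self, condition: str) -> BandDefinition:
        if self.delta_bands and condition in self.delta_bands:
            return self.delta_bands[condition]
        return delta_band(condition)


def _bands_from_dict(d: Optional[dict], name: str):
    if not d:
        return None
    return {
        cond: BandDefinition(name, float(lo), float(hi))
        for cond, (lo, hi) in d.items()
    }


def _pac_config_from_dict(d: dict) -> PacConfig:
    d = dict(d)
    kw = {}
    if {"phase_fmin", "phase_fmax"} <= d.keys():
        step = float(d.pop("phase_step", 0.5))
        kw["phase_freqs"] = np.round(
            np.arange(d.pop("phase_fmin"), d.pop("phase_fmax") + step / 2, step),
            6,
        )
    if {"amp_fmin", "amp_fmax"} <= d.keys():
        step = float(d.pop("amp_step", 0.5))
        kw["amp_freqs"] = np.round(
            np.arange(d.pop("amp_fmin"), d.pop("amp_fmax") + step / 2, step), 6
        )
    for key in ("phase_halfwidth", "amp_halfwidth", "n_bins", "edge_trim",
                "bias_correction"):
        if key in d:
            kw[key] = d.pop(key)
    if d:
        raise ValueError(f"unknown pac config keys: {sorted(d)}")
    return PacConfig(**kw)


def load_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file path or a dict."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source or {})
    sim = spio.config_from_dict(raw.get("simulate", {}))
    pac_cfg = _pac_config_from_dict(raw.get("pac", {}))
    stats_cfg = PermutationConfig(**raw.get("stats", {}))
    entr = raw.get("entrainment", {})
    return PipelineConfig(
        simulate=sim,
        pac=pac_cfg,
        stats=stats_cfg,
        phase_source=raw.get("phase_source", "stimulus"),
        theta_bands=_bands_from_dict(entr.get("theta_bands"), "theta"),
        delta_bands=_bands_from_dict(entr.get("delta_bands"), "delta"),
        raw=raw,
    )


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the full configuration (stable under re-serialization)."""
    canonical = {
        "simulate": spio._config_to_dict(cfg.simulate),
        "pac": {
            "phase_freqs": list(map(float, cfg.pac.phase_freqs)),
            "amp_freqs": list(map(float, cfg.pac.amp_freqs)),
            "phase_halfwidth": cfg.pac.phase_halfwidth,
            "amp_halfwidth": cfg.pac.amp_halfwidth,
            "n_bins": cfg.pac.n_bins,
            "edge_trim": cfg.pac.edge_trim,
            "bias_correction": cfg.pac.bias_correction,
        },
        "stats": dataclasses.asdict(cfg.stats),
        "phase_source": cfg.phase_source,
    }
    blob = json.dumps(canonical, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stages: Dict[str, List[str]]
    timestamps: Dict[str, float]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig, out_dir: Path) -> Cohort:
    cohort = generate_cohort(cfg.simulate)
    spio.write_cohort(cohort, out_dir / "cohort")
    return cohort


def stage_envelope(cohort: Cohort, out_dir: Path) -> List[str]:
    """Group-average envelope power spectrum per condition."""
    env_dir = out_dir / "envelope"
    env_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for condition in cohort.conditions:
        spectra = []
        freqs = None
        for subject in cohort.subjects:
            spec = envelope_power_spectrum(
                cohort.get(subject, condition).envelope
            )
            freqs, power = spec.freqs, spec.power
            spectra.append(power)
        path = env_dir / f"envelope_spectrum_{condition}.tsv"
        spio.write_spectrum_tsv(
            freqs,
            np.mean(spectra, axis=0),
            path,
            value_col="power",
            condition=condition,
        )
        files.append(str(path))
    return files


def stage_entrain(
    cohort: Cohort, cfg: PipelineConfig, out_dir: Path
) -> Tuple[dict, List[str]]:
    """Coherence and surrogate-coherence spectra per subject/condition/ROI.

    Returns ``arrays[(condition, roi)] = (real, surrogate)`` stacked over
    subjects in sorted subject order, plus the files written.
    """
    ent_dir = out_dir / "entrainment"
    ent_dir.mkdir(parents=True, exist_ok=True)
    files: List[str] = []
    arrays: dict = {}
    for condition in cohort.conditions:
        for roi in cohort.config.rois:
            real_rows, surr_rows = [], []
            for subject in cohort.subjects:
                entry = cohort.get(subject, condition)
                real = coherence_spectrum(entry.envelope, entry.neural[roi])
                surr = surrogate_coherence_spectrum(
                    entry.envelope, entry.neural[roi]
                )
                real_rows.append(real.coherence)
                surr_rows.append(surr.coherence)
                for kind, spec in (("real", real), ("surrogate", surr)):
                    path = (
                        ent_dir
                        / f"coherence_{subject}_{condition}_{roi}_{kind}.tsv"
                    )
                    spio.write_spectrum_tsv(
                        spec.freqs,
                        spec.coherence,
                        path,
                        value_col="coherence",
                        subject=subject,
                        condition=condition,
                        roi=roi,
                        kind=kind,
                    )
                    files.append(str(path))
            arrays[(condition, roi)] = (
                np.stack(real_rows),
                np.stack(surr_rows),
            )
    return arrays, files


def stage_coherence_stats(
    arrays: dict, cfg: PipelineConfig, out_dir: Path
) -> Tuple[dict, List[str]]:
    """Cluster permutation test of real vs surrogate coherence (1-D)."""
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    files: List[str] = []
    masks: dict = {}
    from .entrainment import COHERENCE_GRID

    for (condition, roi), (real, surr) in sorted(arrays.items()):
        clusters = cluster_permutation_paired(real, surr, cfg.stats)
        mask = significant_mask(
            clusters, cfg.stats.alpha, shape=real.shape[1:]
        )
        masks[(condition, roi)] = mask
        rows = [
            {
                "cluster_id": f"c{k + 1}",
                "p_value": c.p_value,
                "polarity": c.polarity,
                "extent_bins": int(c.mask.sum()),
                "f_lo": float(COHERENCE_GRID[c.mask].min()),
                "f_hi": float(COHERENCE_GRID[c.mask].max()),
                "cluster_stat": c.cluster_stat,
            }
            for k, c in enumerate(clusters)
        ]
        summary = pd.DataFrame(
            rows,
            columns=[
                "cluster_id", "p_value", "polarity", "extent_bins",
                "f_lo", "f_hi", "cluster_stat",
            ],
        )
        path = stats_dir / f"coherence_clusters_{condition}_{roi}.tsv"
        summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
        files.append(str(path))
        mpath = stats_dir / f"coherence_mask_{condition}_{roi}.tsv"
        spio.write_spectrum_tsv(
            COHERENCE_GRID,
            mask.astype(int),
            mpath,
            value_col="significant",
            condition=condition,
            roi=roi,
        )
        files.append(str(mpath))
    return masks, files


def stage_coherence_peaks(
    cohort: Cohort, arrays: dict, cfg: PipelineConfig, out_dir: Path
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-subject (Coh_max, f_c) in the delta and theta bands of interest."""
    from .entrainment import COHERENCE_GRID, CoherenceSpectrum

    rows = []
    for (condition, roi), (real, _) in sorted(arrays.items()):
        for s_idx, subject in enumerate(cohort.subjects):
            spec = CoherenceSpectrum(
                freqs=COHERENCE_GRID.copy(),
                coherence=real[s_idx],
                subject=subject,
                condition=condition,
                roi=roi,
            )
            for band in (
                cfg.delta_band_for(condition),
                cfg.theta_band_for(condition),
            ):
                peak = band_peak(spec, band)
                rows.append(
                    {
                        "subject": subject,
                        "condition": condition,
                        "roi": roi,
                        "band": band.name,
                        "coh_max": peak.peak_value,
                        "f_c": peak.peak_freq,
                    }
                )
    peaks = pd.DataFrame(rows).sort_values(
        ["band", "condition", "roi", "subject"], kind="stable"
    )
    path = out_dir / "report" / "coherence_peaks.tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    peaks.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return peaks, [str(path)]


def stage_pac(
    cohort: Cohort, cfg: PipelineConfig, out_dir: Path
) -> Tuple[dict, List[str]]:
    """Comodulograms and surrogates per subject/condition/ROI."""
    pac_dir = out_dir / "pac"
    pac_dir.mkdir(parents=True, exist_ok=True)
    files: List[str] = []
    arrays: dict = {}
    for condition in cohort.conditions:
        for roi in cohort.config.rois:
            real_rows, surr_rows = [], []
            for subject in cohort.subjects:
                entry = cohort.get(subject, condition)
                real = comodulogram(
                    entry.envelope,
                    entry.neural[roi],
                    cfg.phase_source,
                    cfg.pac,
                )
                surr = surrogate_comodulogram(
                    entry.envelope,
                    entry.neural[roi],
                    cfg.phase_source,
                    cfg.pac,
                )
                real_rows.append(real.mi)
                surr_rows.append(surr.mi)
                for kind, com in (("real", real), ("surrogate", surr)):
                    path = (
                        pac_dir / f"comod_{subject}_{condition}_{roi}_{kind}.tsv"
                    )
                    spio.write_comodulogram_tsv(com, path)
                    files.append(str(path))
            arrays[(condition, roi)] = (
                np.stack(real_rows),
                np.stack(surr_rows),
            )
    return arrays, files


def stage_pac_stats(
    pac_arrays: dict, cfg: PipelineConfig, out_dir: Path
) -> Tuple[dict, List[str]]:
    """2-D cluster permutation test on the comodulogram grids."""
    stats_dir = out_dir / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    files: List[str] = []
    masks: dict = {}
    fp, fa = cfg.pac.phase_freqs, cfg.pac.amp_freqs
    for (condition, roi), (real, surr) in sorted(pac_arrays.items()):
        clusters = cluster_permutation_paired(real, surr, cfg.stats)
        mask = significant_mask(
            clusters, cfg.stats.alpha, shape=real.shape[1:]
        )
        masks[(condition, roi)] = mask
        rows = [
            {
                "cluster_id": f"c{k + 1}",
                "p_value": c.p_value,
                "polarity": c.polarity,
                "extent_bins": int(c.mask.sum()),
                "f_phase_lo": float(fp[np.any(c.mask, axis=1)].min()),
                "f_phase_hi": float(fp[np.any(c.mask, axis=1)].max()),
                "f_amp_lo": float(fa[np.any(c.mask, axis=0)].min()),
                "f_amp_hi": float(fa[np.any(c.mask, axis=0)].max()),
                "cluster_stat": c.cluster_stat,
            }
            for k, c in enumerate(clusters)
        ]
        summary = pd.DataFrame(
            rows,
            columns=[
                "cluster_id", "p_value", "polarity", "extent_bins",
                "f_phase_lo", "f_phase_hi", "f_amp_lo", "f_amp_hi",
                "cluster_stat",
            ],
        )
        path = stats_dir / f"pac_clusters_{condition}_{roi}.tsv"
        summary.to_csv(path, sep="\t", index=False, float_format="%.6g")
        files.append(str(path))
        mgrid_fp, mgrid_fa = np.meshgrid(fp, fa, indexing="ij")
        mpath = stats_dir / f"pac_mask_{condition}_{roi}.tsv"
        pd.DataFrame(
            {
                "phase_hz": mgrid_fp.reshape(-1),
                "amp_hz": mgrid_fa.reshape(-1),
                "significant": mask.astype(int).reshape(-1),
            }
        ).to_csv(mpath, sep="\t", index=False, float_format="%.6g")
        files.append(str(mpath))
    return masks, files


def stage_pac_peaks(
    cohort: Cohort,
    pac_arrays: dict,
    pac_masks: dict,
    cfg: PipelineConfig,
    out_dir: Path,
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-subject (MI_max, f_phase, f_amp) within the significant cluster.

    When a condition/ROI has no significant cluster the whole matrix is
    searched and the row flagged ``cluster_id="global"`` (with a warning),
    so downstream summaries keep every condition.
    """
    from .pac import Comodulogram

    rows = []
    for (condition, roi), (real, _) in sorted(pac_arrays.items()):
        mask = pac_masks[(condition, roi)]
        cluster_id = "c1"
        if not mask.any():
            warnings.warn(
                f"no significant PAC cluster for {condition}/{roi}; "
                "using the global argmax"
            )
            mask = np.ones_like(mask, dtype=bool)
            cluster_id = "global"
        for s_idx, subject in enumerate(cohort.subjects):
            com = Comodulogram(
                phase_freqs=cfg.pac.phase_freqs,
                amp_freqs=cfg.pac.amp_freqs,
                mi=real[s_idx],
                phase_source=cfg.phase_source,
                subject=subject,
                condition=condition,
                roi=roi,
            )
            peak = pac_peak(com, mask)
            rows.append(
                {
                    "subject": subject,
                    "condition": condition,
                    "roi": roi,
                    "cluster_id": cluster_id,
                    "mi_max": peak.mi_max,
                    "f_phase": peak.f_phase,
                    "f_amp": peak.f_amp,
                }
            )
    peaks = pd.DataFrame(rows).sort_values(
        ["condition", "roi", "subject"], kind="stable"
    )
    path = out_dir / "report" / "pac_peaks.tsv"
    path.parent.mkdir(parents=True, exist_ok=True)
    peaks.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return peaks, [str(path)]


# ---------------------------------------------------------------- reporting


def report_tables(
    peaks: pd.DataFrame,
    value_cols: Optional[List[str]] = None,
    group_cols: Tuple[str, ...] = ("condition", "roi"),
) -> pd.DataFrame:
    """Group mean and standard error of each peak quantity.

    One row per group (condition x ROI x band when present); per quantity
    the numeric mean, the standard error SD/sqrt(n), and a formatted
    ``mean(SE)`` string.  A single-subject group reports SE = 0 with a
    warning.
    """
    if peaks.empty:
        raise ValueError("empty peaks table")
    group_cols = [c for c in group_cols if c in peaks.columns]
    if "band" in peaks.columns and "band" not in group_cols:
        group_cols = ["band"] + group_cols
    if value_cols is None:
        skip = set(group_cols) | {"subject", "cluster_id"}
        value_cols = [
            c
            for c in peaks.columns
            if c not in skip and pd.api.types.is_numeric_dtype(peaks[c])
        ]
    rows = []
    for keys, grp in peaks.groupby(group_cols, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_cols, keys))
        n = grp["subject"].nunique() if "subject" in grp.columns else len(grp)
        row["n"] = n
        for col in value_cols:
            vals = grp[col].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            if len(vals) < 2:
                warnings.warn(
                    f"single subject in group {row}; SE reported as 0"
                )
                se = 0.0
            else:
                se = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            row[f"{col}_mean"] = mean
            row[f"{col}_se"] = se
            row[f"{col}"] = f"{mean:.2f}({se:.2f})"
        rows.append(row)
    return pd.DataFrame(rows)


def ordering_summary(
    peaks: pd.DataFrame,
    tempo_factors: Dict[str, float],
    freq_col: str,
) -> pd.DataFrame:
    """Group-mean peak frequency per condition, ordered by tempo factor.

    The ``increasing`` flag reports whether the group means are strictly
    increasing with the tempo factor (the rate-following signature).
    Conditions missing from the table are dropped with a warning.
    """
    rows = []
    for condition, factor in sorted(
        tempo_factors.items(), key=lambda kv: kv[1]
    ):
        grp = peaks[peaks["condition"] == condition]
        if grp.empty:
            warnings.warn(f"condition {condition!r} missing from peaks table")
            continue
        rows.append(
            {
                "condition": condition,
                "tempo_factor": factor,
                f"{freq_col}_mean": float(grp[freq_col].mean()),
            }
        )
    out = pd.DataFrame(rows)
    means = out[f"{freq_col}_mean"].to_numpy()
    out["increasing"] = bool(np.all(np.diff(means) > 0)) if len(means) > 1 else True
    return out


# ---------------------------------------------------------------- run_all


def run_all(config, out_dir) -> RunManifest:
    """Run the full pipeline and write all tables under ``out_dir``.

    ``config`` is a YAML path or a dict (see :func:`load_config`).  Any
    stage failure raises :class:`StageError` naming the stage.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: Dict[str, List[str]] = {}
    timestamps: Dict[str, float] = {}

    def _run(name, fn, *args):
        t0 = time.time()
        try:
            result = fn(*args)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise StageError(name, str(exc)) from exc
        logger.info("stage %-16s %6.1f s", name, time.time() - t0)
        timestamps[name] = time.time()
        return result

    cohort = _run("simulate", stage_simulate, cfg, out_dir)
    stages["simulate"] = [str(out_dir / "cohort" / "manifest.json")]

    stages["envelope"] = _run("envelope", stage_envelope, cohort, out_dir)

    coh_arrays, files = _run("entrain", stage_entrain, cohort, cfg, out_dir)
    stages["entrain"] = files

    _, files = _run(
        "coherence_stats", stage_coherence_stats, coh_arrays, cfg, out_dir
    )
    stages["coherence_stats"] = files

    coh_peaks, files = _run(
        "coherence_peaks", stage_coherence_peaks, cohort, coh_arrays, cfg,
        out_dir,
    )
    stages["coherence_peaks"] = files

    pac_arrays, files = _run("pac", stage_pac, cohort, cfg, out_dir)
    stages["pac"] = files

    pac_masks, files = _run(
        "pac_stats", stage_pac_stats, pac_arrays, cfg, out_dir
    )
    stages["pac_stats"] = files

    pac_peaks, files = _run(
        "pac_peaks", stage_pac_peaks, cohort, pac_arrays, pac_masks, cfg,
        out_dir,
    )
    stages["pac_peaks"] = files

    report_dir = out_dir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    coh_summary = report_tables(coh_peaks)
    coh_summary.to_csv(
        report_dir / "coherence_summary.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    pac_summary = report_tables(pac_peaks)
    pac_summary.to_csv(
        report_dir / "pac_summary.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    factors = cfg.simulate.tempo_factors
    theta_peaks = coh_peaks[coh_peaks["band"] == "theta"]
    orderings = []
    for col, table in (
        ("f_c", theta_peaks),
        ("f_phase", pac_peaks),
        ("f_amp", pac_peaks),
    ):
        summ = ordering_summary(table, factors, col)
        summ.insert(0, "quantity", col)
        summ = summ.rename(columns={f"{col}_mean": "group_mean"})
        orderings.append(summ)
    ordering = pd.concat(orderings, ignore_index=True)
    ordering.to_csv(
        report_dir / "ordering_summary.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    stages["report"] = [
        str(report_dir / "coherence_summary.tsv"),
        str(report_dir / "pac_summary.tsv"),
        str(report_dir / "ordering_summary.tsv"),
    ]
    timestamps["report"] = time.time()

    manifest = RunManifest(
        config_hash=config_hash(cfg),
        seed=cfg.simulate.seed,
        version=_PKG_VERSION,
        stages=stages,
        timestamps=timestamps,
    )
    manifest.write(out_dir / "run_manifest.json")
    for file_list in stages.values():
        for f in file_list:
            if not Path(f).exists():
                raise StageError("manifest", f"listed output missing: {f}")
    return manifest
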