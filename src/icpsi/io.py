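"""Recording containers, tidy-table readers/writers and the pipeline driver.

A recording is stored one file per patient, either as plain CSV (header
comment lines carry ``fs`` and ``t0``; columns ``time``, ``icp``, ``abp`` and
optional truth channels) or as an HDF5 container (datasets per channel,
``fs``/``t0`` as attributes).  Times are seconds from t0; all intervals in
the pipeline are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from icpsi.simulate import RawRecording, SimConfig, CohortSpec, simulate_cohort
from icpsi.pulses import beat_table, ClassifierConfig
from icpsi.indices import process_recording, summarize_patient
from icpsi.burden import hourly_metrics, fit_lag_grid
from icpsi.heatmaps import GridSpec, cohort_cell_stats, cell_density, render, render_png
from icpsi.stats import cohort_filter, compare_groups, fit_outcome_logistic

__all__ = [
    "FormatError",
    "RunConfig",
    "read_recording",
    "write_recording",
    "run_pipeline",
]

log = logging.getLogger("icpsi")

_REQUIRED_CHANNELS = ("icp", "abp")


class FormatError(ValueError):
    """Raised when a recording file violates the container contract."""


def _check_fs(fs: float, path: str) -> None:
    if not (50.0 <= fs <= 250.0):
        raise FormatError(f"{path}: fs={fs} Hz outside the supported 50-250 Hz range")


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording; format chosen by extension (.csv or .h5/.hdf5)."""
    path = Path(path)
    if path.suffix == ".csv":
        _write_csv(rec, path)
    elif path.suffix in (".h5", ".hdf5"):
        _write_h5(rec, path)
    else:
        raise FormatError(f"{path}: unknown recording extension {path.suffix!r}")


def read_recording(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if path.suffix == ".csv":
        return _read_csv(path)
    if path.suffix in (".h5", ".hdf5"):
        return _read_h5(path)
    raise FormatError(f"{path}: unknown recording extension {path.suffix!r}")


def _write_csv(rec: RawRecording, path: Path) -> None:
    df = pd.DataFrame({"time": rec.time, "icp": rec.icp, "abp": rec.abp})
    if "artifact" in rec.truth:
        df["truth_artifact"] = rec.truth["artifact"].astype(int)
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs}\n# t0={rec.t0}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def _read_csv(path: Path) -> RawRecording:
    fs = t0 = None
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "fs":
                fs = float(val)
            elif key.strip() == "t0":
                t0 = float(val)
    if fs is None:
        raise FormatError(f"{path}: header does not declare fs")
    _check_fs(fs, str(path))
    df = pd.read_csv(path, comment="#")
    for ch in _REQUIRED_CHANNELS:
        if ch not in df.columns:
            raise FormatError(f"{path}: missing required channel column '{ch}'")
    if df["icp"].isna().any() or df["abp"].isna().any():
        raise FormatError(f"{path}: icp/abp contain missing values")
    truth = {}
    if "truth_artifact" in df.columns:
        truth["artifact"] = df["truth_artifact"].to_numpy().astype(bool)
    return RawRecording(
        fs=fs, icp=df["icp"].to_numpy(), abp=df["abp"].to_numpy(), t0=t0 or 0.0, truth=truth
    )


def _write_h5(rec: RawRecording, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["fs"] = rec.fs
        f.attrs["t0"] = rec.t0
        f.create_dataset("icp", data=rec.icp)
        f.create_dataset("abp", data=rec.abp)
        g = f.create_group("truth")
        for k, v in rec.truth.items():
            g.create_dataset(k, data=np.asarray(v))


def _read_h5(path: Path) -> RawRecording:
    import h5py

    with h5py.File(path, "r") as f:
        if "fs" not in f.attrs:
            raise FormatError(f"{path}: header does not declare fs")
        fs = float(f.attrs["fs"])
        _check_fs(fs, str(path))
        for ch in _REQUIRED_CHANNELS:
            if ch not in f:
                raise FormatError(f"{path}: missing required channel '{ch}'")
        icp = f["icp"][:]
        abp = f["abp"][:]
        if len(icp) != len(abp):
            raise FormatError(f"{path}: icp/abp length mismatch ({len(icp)} vs {len(abp)})")
        truth = {k: f["truth"][k][:] for k in f.get("truth", {})}
        return RawRecording(fs=fs, icp=icp, abp=abp, t0=float(f.attrs.get("t0", 0.0)), truth=truth)


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run: paths, seed, constants."""

    seed: int = 0
    n_patients: int = 10
    duration: float = 1800.0
    fs: float = 100.0
    artifact_rate: float = 2.0
    min_beats_per_psi_window: int = 30
    min_monitoring_hours: float = 12.0
    lags: tuple[int, ...] = (1, 2, 3)
    heatmap_grids: tuple[str, ...] = ("psi", "psi_icp", "psi_prx", "psi_cpp")
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    version: str = "0.1.0"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["lags"] = list(self.lags)
        d["heatmap_grids"] = list(self.heatmap_grids)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "classifier" in d and isinstance(d["classifier"], dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        if "lags" in d:
            d["lags"] = tuple(d["lags"])
        if "heatmap_grids" in d:
            d["heatmap_grids"] = tuple(d["heatmap_grids"])
        return cls(**d)


_GRID_FACTORIES = {
    "psi": GridSpec.psi,
    "psi_icp": GridSpec.psi_icp,
    "psi_prx": GridSpec.psi_prx,
    "psi_cpp": GridSpec.psi_cpp,
}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Simulate a cohort and run every analysis stage, writing all artifacts.

    Emits, under ``out_dir``: per-patient recording CSVs, beat tables, minute
    series and a cohort ``summaries.csv``/``metadata.csv``; lagged LMM
    results when enough hourly data exist; heatmap cell tables and PNGs; a
    group-comparison/logistic report; and ``pipeline.log`` with per-stage
    exclusion and GMT counts.  Deterministic given config + seed.
    """
    out = Path(out_dir)
    for sub in ("recordings", "beats", "minutes", "heatmaps"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "simulate"
    try:
        spec = CohortSpec(
            n_patients=config.n_patients,
            seed=config.seed,
            duration=config.duration,
            fs=config.fs,
            base_config=SimConfig(artifact_rate=config.artifact_rate),
        )
        cohort = simulate_cohort(spec)
        log.info("simulate: %d patients, %.1f min each", len(cohort), config.duration / 60.0)

        stage = "beats"
        minute_frames: dict[str, pd.DataFrame] = {}
        summary_rows, meta_rows = [], []
        for rec, meta in cohort:
            pid = meta["patient"]
            write_recording(rec, out / "recordings" / f"{pid}.csv")
            beats = beat_table(rec.icp, rec.fs, t0=rec.t0, config=config.classifier)
            beats.to_csv(out / "beats" / f"{pid}.csv", index=False)
            n_art = int((beats["klass"] == "ARTIFACT").sum())
            log.info("beats[%s]: %d pulses, %d artifact", pid, len(beats), n_art)
            stage = "process"
            mins = process_recording(rec, beats, min_beats=config.min_beats_per_psi_window)
            mins.to_csv(out / "minutes" / f"{pid}.csv", index=False)
            minute_frames[pid] = mins
            summ = summarize_patient(mins)
            gmt_str = ", ".join(f"{k}={v:.2f}h" for k, v in summ.gmt_hours.items())
            log.info("process[%s]: GMT %s of %.2fh monitored", pid, gmt_str, summ.monitoring_hours)
            row = {"patient": pid, **summ.as_row()}
            summary_rows.append(row)
            meta_rows.append(meta)
        summaries = pd.DataFrame(summary_rows)
        metadata = pd.DataFrame(meta_rows)
        summaries.to_csv(out / "summaries.csv", index=False)
        metadata.to_csv(out / "metadata.csv", index=False)

        stage = "screen"
        merged = metadata.merge(summaries, on="patient")
        included, tally = cohort_filter(merged, min_hours=config.min_monitoring_hours)
        log.info("screen: %s", tally)

        stage = "predict"
        hourly_parts = []
        for pid, mins in minute_frames.items():
            hm = hourly_metrics(mins, patient=pid)
            if len(hm):
                hourly_parts.append(hm)
        results = pd.DataFrame()
        if hourly_parts:
            hourly = pd.concat(hourly_parts, ignore_index=True)
            max_lag_ok = hourly.groupby("patient")["hour"].count().max() or 0
            lags = tuple(l for l in config.lags if l < max_lag_ok)
            if lags:
                results = fit_lag_grid(
                    hourly, outcomes=["icp_mean"], predictors=["psi_mean"], lags=lags
                )
        results.to_csv(out / "lmm_results.csv", index=False)
        log.info("predict: %d models fitted", len(results))

        stage = "heatmap"
        analysable = metadata.dropna(subset=["gos"])
        for name in config.heatmap_grids:
            grid = _GRID_FACTORIES[name]()
            try:
                hm = cohort_cell_stats(minute_frames, analysable, grid)
            except ValueError as exc:
                log.info("heatmap[%s]: skipped (%s)", name, exc)
                continue
            hm.cell_table().to_csv(out / "heatmaps" / f"{name}_cells.csv", index=False)
            img = render(hm.r, mask=~hm.eligible, mode="outcome")
            render_png(img, str(out / "heatmaps" / f"{name}_outcome.png"), grid=grid)
            dens = render(cell_density(hm), mode="density")
            render_png(
                dens, str(out / "heatmaps" / f"{name}_density.png"), mode="density", grid=grid
            )
            log.info("heatmap[%s]: %d/%d cells eligible", name, int(hm.eligible.sum()), grid.n_cells)

        stage = "report"
        report_lines = [f"cohort screen tally: {tally}"]
        if included["gos"].notna().sum() >= 4 and included["gos"].nunique() > 1:
            for outc in ("mortality", "favourable"):
                cmp_df = compare_groups(included, outcome=outc)
                cmp_df.to_csv(out / f"compare_{outc}.csv", index=False)
                report_lines.append(f"{outc}: {int(cmp_df['defined'].sum())} comparisons defined")
        (out / "report.txt").write_text("\n".join(report_lines) + "\n")
        return {"tally": tally, "n_models": len(results), "out": str(out)}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
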