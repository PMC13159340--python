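"""PSI, AmpICP, RAP, PRx, CPP and good-monitoring-time accounting.

Windowing rules, on a single convention: every window (1.5 s, 10 s, 1 min,
5 min, 1 h) is left-closed/right-open and anchored at the recording start t0.

* ICP samples below -30 or above 200 mmHg are rejected for all calculations
  (bounds strict: the endpoint values themselves are retained).
* PSI: weighted average of pulse morphology class numbers (1-4, weights =
  class occurrence counts, artifact beats excluded) per consecutive
  non-overlapping 5-min window; absent when fewer than ``min_beats``
  non-artifact beats fall in the window.
* AmpICP: max-minus-min ICP over a sliding 1.5-s window updated every second,
  then the median of those per-second values per non-overlapping 5-min
  window; values valid only in (0.04, 40) mmHg.
* Mean ICP/ABP are down-sampled to 0.1 Hz (10-s means, >= 50 % valid samples
  per bin) after artifact rejection; the ICP pulse amplitude used by RAP is
  the fundamental cardiac harmonic of each fully valid 10-s segment.
* RAP / PRx: moving Pearson correlation over the trailing 30 ten-second
  values (5 min), emitted every minute — RAP pairs mean ICP with the
  fundamental-harmonic amplitude, PRx pairs mean ABP with mean ICP.
* Minute series: PSI and AmpICP are up-sampled from the 5-min grid to the
  1-min grid by value-hold; CPP = ABP - ICP per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICP_REJECT_LOW",
    "ICP_REJECT_HIGH",
    "AMP_VALID_LOW",
    "AMP_VALID_HIGH",
    "PSI_BIN_EDGES",
    "reject_icp_range",
    "detect_flatline",
    "psi_5min",
    "psi_series",
    "amp_icp_5min",
    "amp_icp_series",
    "downsample_10s",
    "fundamental_amplitude",
    "ten_second_series",
    "rap",
    "prx",
    "assemble_minute_series",
    "summarize_patient",
    "process_recording",
    "PatientSummary",
]

ICP_REJECT_LOW = -30.0
ICP_REJECT_HIGH = 200.0
AMP_VALID_LOW = 0.04
AMP_VALID_HIGH = 40.0
CARDIAC_BAND_HZ = (40.0 / 60.0, 180.0 / 60.0)
PSI_BIN_EDGES = np.arange(1.0, 4.01, 0.5)  # six 0.5-wide bins over [1, 4]

MINUTE_COLUMNS = ["minute", "icp", "abp", "cpp", "amp_icp", "rap", "prx", "psi"]


def reject_icp_range(icp: np.ndarray) -> np.ndarray:
    """Validity mask: True where -30 <= ICP <= 200 mmHg and finite."""
    icp = np.asarray(icp, dtype=float)
    return np.isfinite(icp) & (icp >= ICP_REJECT_LOW) & (icp <= ICP_REJECT_HIGH)


def detect_flatline(x: np.ndarray, fs: float, window_s: float = 3.0, tol: float = 0.01) -> np.ndarray:
    """Automatic artifact mask for sensor dropouts: True where the signal is flat.

    A sample is flagged when it belongs to a ``window_s``-long stretch whose
    peak-to-peak range is below ``tol`` mmHg (dead sensor / disconnection).
    """
    x = np.asarray(x, dtype=float)
    w = max(int(round(window_s * fs)), 2)
    if len(x) < w:
        return np.zeros(len(x), dtype=bool)
    view = np.lib.stride_tricks.sliding_window_view(x, w)
    flat_start = (view.max(axis=1) - view.min(axis=1)) < tol
    mask = np.zeros(len(x), dtype=bool)
    idx = np.flatnonzero(flat_start)
    for i in idx:  # flat windows are rare; loop is fine
        mask[i : i + w] = True
    return mask


# ---------------------------------------------------------------------------
# PSI


def psi_5min(classes: np.ndarray, min_beats: int = 30) -> float:
    """Weighted-average class number over one 5-min window's beats.

    ``classes`` holds the class labels of the window's beats; artifact beats
    (any non-integer label) are excluded.  NaN when fewer than ``min_beats``
    non-artifact beats remain.
    """
    vals = np.asarray([k for k in classes if isinstance(k, (int, np.integer))], dtype=float)
    if len(vals) < min_beats:
        return float("nan")
    return float(vals.mean())


def psi_series(beats: pd.DataFrame, duration: float, t0: float = 0.0, min_beats: int = 30) -> pd.DataFrame:
    """PSI per consecutive non-overlapping 5-min window anchored at t0.

    ``beats`` is the per-beat table from :func:`icpsi.pulses.beat_table`.
    Returns a DataFrame with ``t`` (window start, s) and ``psi``.
    """
    n_win = int(np.ceil(duration / 300.0))
    starts = t0 + 300.0 * np.arange(n_win)
    vals = np.full(n_win, np.nan)
    if len(beats):
        win = np.floor((beats["onset_s"].to_numpy() - t0) / 300.0).astype(int)
        for w in range(n_win):
            klasses = beats.loc[win == w, "klass"].tolist()
            vals[w] = psi_5min(klasses, min_beats=min_beats)
    return pd.DataFrame({"t": starts, "psi": vals})


# ---------------------------------------------------------------------------
# AmpICP


def _per_second_amplitudes(icp: np.ndarray, fs: float, valid: np.ndarray) -> np.ndarray:
    """Min-to-max ICP over sliding 1.5-s windows updated every second.

    Per-second values whose window contains any invalid sample are NaN.
    """
    n = len(icp)
    w = int(round(1.5 * fs))
    n_sec = int(np.floor((n - w) / fs)) + 1
    if n_sec <= 0:
        return np.empty(0)
    starts = np.round(np.arange(n_sec) * fs).astype(int)
    idx = starts[:, None] + np.arange(w)[None, :]
    seg = icp[idx]
    ok = valid[idx].all(axis=1)
    amp = seg.max(axis=1) - seg.min(axis=1)
    amp[~ok] = np.nan
    return amp


def amp_icp_5min(per_second_amps: np.ndarray) -> float:
    """AmpICP for one 5-min window: median of valid per-second amplitudes.

    The result is retained only when it falls in the (0.04, 40) mmHg validity
    range; otherwise NaN.
    """
    a = per_second_amps[np.isfinite(per_second_amps)]
    if len(a) == 0:
        return float("nan")
    med = float(np.median(a))
    if not (AMP_VALID_LOW < med < AMP_VALID_HIGH):
        return float("nan")
    return med


def amp_icp_series(icp: np.ndarray, fs: float, valid: np.ndarray, t0: float = 0.0) -> pd.DataFrame:
    """AmpICP per non-overlapping 5-min window.  Columns ``t``, ``amp_icp``."""
    amps = _per_second_amplitudes(np.asarray(icp, float), fs, np.asarray(valid, bool))
    duration = len(icp) / fs
    n_win = int(np.ceil(duration / 300.0))
    vals = np.full(n_win, np.nan)
    sec = np.arange(len(amps))
    for w in range(n_win):
        sel = (sec >= 300 * w) & (sec < 300 * (w + 1))
        if sel.any():
            vals[w] = amp_icp_5min(amps[sel])
    return pd.DataFrame({"t": t0 + 300.0 * np.arange(n_win), "amp_icp": vals})


# ---------------------------------------------------------------------------
# 10-s series, RAP, PRx


def downsample_10s(x: np.ndarray, fs: float, valid: np.ndarray, t0: float = 0.0) -> pd.DataFrame:
    """10-s (0.1 Hz) means of valid samples; NaN where < 50 % of a bin is valid.

    Columns ``t`` (bin start, s) and ``mean``.
    """
    x = np.asarray(x, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n = len(x)
    w = int(round(10.0 * fs))
    n_bin = n // w
    vals = np.full(n_bin, np.nan)
    for b in range(n_bin):
        sl = slice(b * w, (b + 1) * w)
        v = valid[sl]
        if v.mean() >= 0.5:
            vals[b] = x[sl][v].mean()
    return pd.DataFrame({"t": t0 + 10.0 * np.arange(n_bin), "mean": vals})


def fundamental_amplitude(segment: np.ndarray, fs: float) -> float:
    """Amplitude of the fundamental cardiac harmonic of a 10-s ICP segment.

    The discrete Fourier magnitude of the de-meaned segment is searched over
    the cardiac band (40-180 beats/min); the amplitude is scaled so a pure
    sinusoid of peak amplitude A returns A.  NaN when no peak above the
    0.04 mmHg floor exists in band.
    """
    seg = np.asarray(segment, dtype=float)
    n = len(seg)
    if n < 8 or not np.all(np.isfinite(seg)):
        return float("nan")
    spec = np.abs(np.fft.rfft(seg - seg.mean())) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= CARDIAC_BAND_HZ[0]) & (freqs <= CARDIAC_BAND_HZ[1])
    if not band.any():
        return float("nan")
    peak = float(spec[band].max())
    if peak < AMP_VALID_LOW:
        return float("nan")
    return peak


def ten_second_series(
    icp: np.ndarray,
    abp: np.ndarray,
    fs: float,
    valid_icp: np.ndarray,
    valid_abp: np.ndarray | None = None,
    t0: float = 0.0,
) -> pd.DataFrame:
    """0.1-Hz series of mean ICP, mean ABP and fundamental-harmonic amplitude.

    Columns ``t``, ``mean_icp``, ``mean_abp``, ``fund_amp``.  ``fund_amp``
    requires the full 10-s segment to be valid.
    """
    if valid_abp is None:
        valid_abp = np.isfinite(np.asarray(abp, float))
    d_icp = downsample_10s(icp, fs, valid_icp, t0)
    d_abp = downsample_10s(abp, fs, valid_abp, t0)
    w = int(round(10.0 * fs))
    icp = np.asarray(icp, float)
    valid_icp = np.asarray(valid_icp, bool)
    fund = np.full(len(d_icp), np.nan)
    for b in range(len(d_icp)):
        sl = slice(b * w, (b + 1) * w)
        if valid_icp[sl].all():
            fund[b] = fundamental_amplitude(icp[sl], fs)
    return pd.DataFrame(
        {
            "t": d_icp["t"],
            "mean_icp": d_icp["mean"],
            "mean_abp": d_abp["mean"],
            "fund_amp": fund,
        }
    )


def _moving_pearson(
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    t0: float,
    window: int = 30,
    min_valid: int = 15,
) -> pd.DataFrame:
    """Trailing-window Pearson r over ``window`` 10-s pairs, emitted per minute.

    A value is emitted at each whole minute m >= window/6 using the trailing
    ``window`` grid points; NaN when fewer than ``min_valid`` pairs are valid
    or either channel has zero variance in the window.
    """
    n = len(x)
    n_min = int(np.floor((t[-1] + 10.0 - t0) / 60.0)) if n else 0
    minutes, vals = [], []
    for m in range(1, n_min + 1):
        end = int(round((m * 60.0) / 10.0))  # grid points fully before minute m
        start = end - window
        if start < 0:
            minutes.append(m)
            vals.append(np.nan)
            continue
        xs = x[start:end]
        ys = y[start:end]
        ok = np.isfinite(xs) & np.isfinite(ys)
        if ok.sum() < min_valid:
            r = np.nan
        else:
            xv, yv = xs[ok], ys[ok]
            if np.std(xv) == 0 or np.std(yv) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(xv, yv)[0, 1])
        minutes.append(m)
        vals.append(r)
    return pd.DataFrame({"minute": minutes, "r": vals})


def rap(ten: pd.DataFrame, t0: float = 0.0) -> pd.DataFrame:
    """RAP: moving Pearson r of 10-s mean ICP and fundamental-harmonic
    amplitude over the trailing 5 min, updated every minute.  Columns
    ``minute``, ``rap``."""
    out = _moving_pearson(
        ten["mean_icp"].to_numpy(), ten["fund_amp"].to_numpy(), ten["t"].to_numpy(), t0
    )
    return out.rename(columns={"r": "rap"})


def prx(ten: pd.DataFrame, t0: float = 0.0) -> pd.DataFrame:
    """PRx: moving Pearson r of 30 consecutive 10-s mean ABP and mean ICP
    values, updated every minute.  Columns ``minute``, ``prx``."""
    out = _moving_pearson(
        ten["mean_abp"].to_numpy(), ten["mean_icp"].to_numpy(), ten["t"].to_numpy(), t0
    )
    return out.rename(columns={"r": "prx"})


# ---------------------------------------------------------------------------
# minute series and patient summary


def assemble_minute_series(
    ten: pd.DataFrame,
    psi5: pd.DataFrame,
    amp5: pd.DataFrame,
    rap_df: pd.DataFrame,
    prx_df: pd.DataFrame,
    duration: float,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Merge all channels onto the 1-min grid.

    Mean ICP/ABP per minute are the mean of that minute's valid 10-s values
    (>= 3 of 6 required); CPP = ABP - ICP where both are present; PSI and
    AmpICP are value-held from their 5-min windows onto each constituent
    minute (up-sampling from 0.0033 to 0.017 Hz); RAP/PRx land on their
    emission minutes.  Columns: ``minute, icp, abp, cpp, amp_icp, rap, prx,
    psi``.
    """
    n_min = int(np.ceil(duration / 60.0))
    out = pd.DataFrame({"minute": np.arange(n_min)})
    ten_min = np.floor((ten["t"].to_numpy() - t0) / 60.0).astype(int)
    icp_m = np.full(n_min, np.nan)
    abp_m = np.full(n_min, np.nan)
    for m in range(n_min):
        sel = ten_min == m
        for col, dest in (("mean_icp", icp_m), ("mean_abp", abp_m)):
            v = ten.loc[sel, col].to_numpy()
            good = np.isfinite(v)
            if sel.sum() > 0 and good.sum() >= max(int(np.ceil(sel.sum() / 2.0)), 1):
                dest[m] = v[good].mean()
    out["icp"] = icp_m
    out["abp"] = abp_m
    out["cpp"] = abp_m - icp_m
    win5 = np.minimum(out["minute"] // 5, len(psi5) - 1) if len(psi5) else None
    out["amp_icp"] = amp5["amp_icp"].to_numpy()[np.minimum(out["minute"] // 5, len(amp5) - 1)] if len(amp5) else np.nan
    for df, col in ((rap_df, "rap"), (prx_df, "prx")):
        s = np.full(n_min, np.nan)
        if len(df):
            mm = df["minute"].to_numpy().astype(int)
            keep = (mm >= 0) & (mm < n_min)
            s[mm[keep]] = df[col].to_numpy()[keep]
        out[col] = s
    out["psi"] = psi5["psi"].to_numpy()[win5] if len(psi5) else np.nan
    return out[MINUTE_COLUMNS]


@dataclass
class PatientSummary:
    """Whole-monitoring medians, GMT hours and %GMT of PSI per 0.5-wide bin."""

    medians: dict
    gmt_hours: dict
    monitoring_hours: float
    psi_bin_pct: np.ndarray  # six bins [1,1.5) ... [3.5,4]

    def as_row(self) -> dict:
        row = {f"{k}_median": v for k, v in self.medians.items()}
        row.update({f"gmt_hours_{k}": v for k, v in self.gmt_hours.items()})
        row["monitoring_hours"] = self.monitoring_hours
        for i, (lo, hi) in enumerate(zip(PSI_BIN_EDGES[:-1], PSI_BIN_EDGES[1:])):
            row[f"psi_pct_{lo:.1f}_{hi:.1f}"] = self.psi_bin_pct[i]
        return row


def summarize_patient(minutes: pd.DataFrame) -> PatientSummary:
    """Medians over the full good monitoring time plus the PSI bin profile.

    Channel medians use each channel's own valid minutes; %GMT of PSI per bin
    is valid-PSI-minutes-in-bin / total-valid-PSI-minutes x 100 over the six
    0.5-wide bins from 1 to 4 (last bin closed above).  Channels with zero
    GMT yield NaN medians and a zero bin profile.
    """
    medians, gmt = {}, {}
    for ch in ("psi", "amp_icp", "rap", "icp", "prx", "cpp", "abp"):
        v = minutes[ch].to_numpy(dtype=float)
        good = np.isfinite(v)
        gmt[ch] = good.sum() / 60.0
        medians[ch] = float(np.median(v[good])) if good.any() else float("nan")
    psi = minutes["psi"].to_numpy(dtype=float)
    psi = psi[np.isfinite(psi)]
    if len(psi):
        counts, _ = np.histogram(psi, bins=PSI_BIN_EDGES)
        pct = counts / len(psi) * 100.0
    else:
        pct = np.zeros(len(PSI_BIN_EDGES) - 1)
    return PatientSummary(
        medians=medians,
        gmt_hours=gmt,
        monitoring_hours=len(minutes) / 60.0,
        psi_bin_pct=pct,
    )


def process_recording(rec, beats: pd.DataFrame | None = None, min_beats: int = 30) -> pd.DataFrame:
    """Full index chain for one recording: artifact masks -> minute series.

    ``rec`` is a :class:`icpsi.simulate.RawRecording` (or any object with
    ``icp``, ``abp``, ``fs``, ``t0``).  ``beats`` is the per-beat class table;
    computed with default settings when omitted.
    """
    from icpsi.pulses import beat_table

    icp = np.asarray(rec.icp, float)
    abp = np.asarray(rec.abp, float)
    valid_icp = reject_icp_range(icp) & ~detect_flatline(icp, rec.fs)
    valid_abp = np.isfinite(abp)
    if beats is None:
        beats = beat_table(icp, rec.fs, t0=rec.t0)
    duration = len(icp) / rec.fs
    ten = ten_second_series(icp, abp, rec.fs, valid_icp, valid_abp, t0=rec.t0)
    psi5 = psi_series(beats, duration, t0=rec.t0, min_beats=min_beats)
    amp5 = amp_icp_series(icp, rec.fs, valid_icp, t0=rec.t0)
    rap_df = rap(ten, t0=rec.t0)
    prx_df = prx(ten, t0=rec.t0)
    return assemble_minute_series(ten, psi5, amp5, rap_df, prx_df, duration, t0=rec.t0)
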