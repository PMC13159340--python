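"""ICP cardiac-pulse segmentation, P1/P2/P3 location and morphology grading.

The classifier is a transparent rule-based grading of each beat into four
morphology classes (1 = normal, P1 dominant with a crisp dicrotic notch, up to
4 = severely pathological rounded mono-peak) plus an artifact class, driven by
the measured P2/P1 height ratio and the dicrotic-notch depth.  Class
boundaries are explicit, config-exposed constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "ARTIFACT",
    "Pulse",
    "ClassifierConfig",
    "detect_pulses",
    "locate_subpeaks",
    "classify_pulse",
    "beat_table",
]

ARTIFACT = "ARTIFACT"

# fractional-latency windows used to label detected maxima as P1/P2/P3
_P_WINDOWS = ((0.03, 0.26), (0.26, 0.46), (0.46, 0.75))


@dataclass
class ClassifierConfig:
    """Tunable decision constants of the rule-based grader."""

    p2_p1_low: float = 0.9  # class 1/2 boundary on the P2/P1 ratio
    p2_p1_high: float = 1.1  # class 2/3 boundary
    notch_min_frac: float = 0.05  # notch depth (fraction of pulse height) called "distinct"
    min_amplitude: float = 0.5  # mmHg; flatter pulses are artifacts
    max_amplitude: float = 50.0  # mmHg
    baseline_low: float = -30.0  # mmHg
    baseline_high: float = 200.0  # mmHg
    smooth_cutoff_hz: float = 15.0
    peak_prominence_frac: float = 0.05


@dataclass
class Pulse:
    """One segmented cardiac ICP pulse (half-open sample span [onset, offset))."""

    onset: int
    offset: int
    samples: np.ndarray
    fs: float
    subpeaks: dict = field(default_factory=dict)  # label -> (latency_frac, height mmHg)
    notch_depth: float | None = None
    klass: int | str | None = None

    @property
    def duration(self) -> float:
        return (self.offset - self.onset) / self.fs

    @property
    def amplitude(self) -> float:
        return float(np.ptp(self.samples))


def _bandpass(x: np.ndarray, fs: float, lo: float = 0.5, hi: float = 10.0) -> np.ndarray:
    nyq = fs / 2.0
    sos = signal.butter(2, [lo / nyq, min(hi / nyq, 0.99)], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def detect_pulses(icp: np.ndarray, fs: float) -> list[Pulse]:
    """Segment an ICP trace into contiguous trough-to-trough cardiac pulses.

    Troughs are found on a 0.5-10 Hz band-passed copy and refined to the raw
    local minimum.  Segments whose implied beat rate falls outside 40-180 bpm
    are emitted with ``klass = ARTIFACT`` pre-assigned; an all-constant signal
    yields no pulses.
    """
    if not (50.0 <= fs <= 250.0):
        raise ValueError(f"fs must lie in [50, 250] Hz, got {fs}")
    icp = np.asarray(icp, dtype=float)
    if len(icp) < fs:
        return []
    if np.ptp(icp) < 1e-9:
        return []
    filt = _bandpass(icp, fs)
    amp = float(np.std(filt))
    if amp < 1e-6:
        return []
    # dominant cardiac frequency sets the minimum spacing between beats, so
    # intra-beat features (the dicrotic trough) cannot split a pulse
    freqs, pxx = signal.welch(filt, fs=fs, nperseg=min(len(filt), int(20 * fs)))
    band = (freqs >= 40.0 / 60.0) & (freqs <= 180.0 / 60.0)
    if band.any() and pxx[band].max() > 0:
        f0 = float(freqs[band][np.argmax(pxx[band])])
        min_dist = max(int(0.6 * fs / f0), int(fs * 60.0 / 180.0 * 0.6))
    else:
        min_dist = int(fs * 60.0 / 180.0)  # max 180 bpm
    # systolic upstrokes: peaks of the filtered derivative
    deriv = np.gradient(filt) * fs
    dstd = float(np.std(deriv))
    if dstd < 1e-9:
        return []
    upstrokes, _ = signal.find_peaks(deriv, distance=min_dist, prominence=1.0 * dstd)
    if len(upstrokes) < 2:
        return []
    # pulse onset = foot of the upstroke: walk the smoothed raw signal back
    # from the max-slope point to the start of its rising run
    sm = _smooth(icp, fs, 15.0)
    dsm = np.diff(sm, prepend=sm[0])
    max_back = int(0.3 * fs / (f0 if band.any() else 1.0))
    refined = []
    for u in upstrokes:
        i = u
        lo = max(u - max_back, 1)
        while i > lo and dsm[i - 1] > 0:
            i -= 1
        refined.append(i)
    refined = np.unique(refined)
    pulses: list[Pulse] = []
    for i0, i1 in zip(refined[:-1], refined[1:]):
        if i1 <= i0 + 3:
            continue
        p = Pulse(onset=int(i0), offset=int(i1), samples=icp[i0:i1].copy(), fs=fs)
        rate = 60.0 / p.duration
        if not (40.0 <= rate <= 180.0):
            p.klass = ARTIFACT
        pulses.append(p)
    return pulses


def _smooth(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    if cutoff >= fs / 2.0:
        return x
    sos = signal.butter(2, cutoff / (fs / 2.0), btype="low", output="sos")
    padlen = min(3 * 6, len(x) - 1)
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def locate_subpeaks(pulse: Pulse, fs: float | None = None, config: ClassifierConfig | None = None) -> Pulse:
    """Find P1/P2/P3 candidates on the smoothed pulse and the dicrotic notch.

    Local maxima of a zero-phase low-passed copy are assigned to P1/P2/P3 by
    fractional-latency windows (ties within a window keep the higher peak);
    sub-peaks that do not exist are simply absent from ``pulse.subpeaks``.
    Heights are measured above the pulse minimum.  ``notch_depth`` is the drop
    from the smaller of the P2/P3 peaks to the trough between them, or None
    when either peak is missing.
    """
    cfg = config or ClassifierConfig()
    fs = fs or pulse.fs
    x = pulse.samples
    n = len(x)
    if n < max(int(0.25 * fs), 8):
        pulse.subpeaks = {}
        pulse.notch_depth = None
        return pulse
    sm = _smooth(x, fs, cfg.smooth_cutoff_hz)
    base = sm.min()
    height = sm.max() - base
    if height <= 0:
        pulse.subpeaks = {}
        pulse.notch_depth = None
        return pulse
    peaks, _ = signal.find_peaks(sm, prominence=cfg.peak_prominence_frac * height)
    # an early dominant maximum at the very start of the window can be missed
    # by find_peaks if the pulse onset is the argmax; include boundary argmax
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(sm))])
    subpeaks: dict[str, tuple[float, float]] = {}
    lat = peaks / n
    for label, (lo, hi) in zip(("P1", "P2", "P3"), _P_WINDOWS):
        cand = peaks[(lat >= lo) & (lat < hi)]
        if len(cand) == 0:
            continue
        best = cand[int(np.argmax(sm[cand]))]
        subpeaks[label] = (best / n, float(sm[best] - base))
    pulse.subpeaks = subpeaks
    if "P2" in subpeaks and "P3" in subpeaks:
        i2 = int(subpeaks["P2"][0] * n)
        i3 = int(subpeaks["P3"][0] * n)
        trough = float(sm[i2 : i3 + 1].min() - base)
        pulse.notch_depth = float(min(subpeaks["P2"][1], subpeaks["P3"][1]) - trough)
    else:
        pulse.notch_depth = None
    return pulse


def classify_pulse(pulse: Pulse, config: ClassifierConfig | None = None) -> int | str:
    """Assign the morphology class (1-4) or ARTIFACT to a located pulse.

    Rules (P2/P1 is the measured height ratio; notch depth as a fraction of
    pulse height):

    * artifact -- amplitude, duration or baseline outside physiological
      bounds (flat pulses, spikes, off-scale baselines, non-cardiac rates);
    * class 4 -- rounded mono-peak (fewer than two sub-peaks resolved);
    * class 3 -- P2/P1 above ``p2_p1_high`` (tidal wave clearly dominant,
      notch degraded or gone);
    * class 2 -- P2/P1 in [``p2_p1_low``, ``p2_p1_high``] with a notch;
    * class 1 -- P1 > P2 > P3 all present with a distinct notch.
    """
    cfg = config or ClassifierConfig()
    if pulse.klass == ARTIFACT:
        return ARTIFACT
    if not pulse.subpeaks and pulse.notch_depth is None and pulse.klass is None:
        # caller must run locate_subpeaks first; a degenerate empty result is
        # distinguished by the sentinel set below
        pass
    x = pulse.samples
    amp = pulse.amplitude
    if (
        amp < cfg.min_amplitude
        or amp > cfg.max_amplitude
        or x.min() < cfg.baseline_low
        or x.max() > cfg.baseline_high
        or not (40.0 <= 60.0 / pulse.duration <= 180.0)
    ):
        pulse.klass = ARTIFACT
        return ARTIFACT
    sp = pulse.subpeaks
    n_sub = len(sp)
    height = max((h for _, h in sp.values()), default=0.0)
    notch_frac = (pulse.notch_depth / height) if (pulse.notch_depth is not None and height > 0) else None
    if n_sub <= 1:
        pulse.klass = 4
    else:
        p1 = sp.get("P1", (None, 0.0))[1]
        p2 = sp.get("P2", (None, 0.0))[1]
        ratio = p2 / p1 if p1 > 0 else np.inf
        if ratio > cfg.p2_p1_high:
            pulse.klass = 3
        elif ratio >= cfg.p2_p1_low:
            pulse.klass = 2
        else:
            p3 = sp.get("P3", (None, 0.0))[1]
            if (
                n_sub == 3
                and p1 > p2 > p3
                and notch_frac is not None
                and notch_frac >= cfg.notch_min_frac
            ):
                pulse.klass = 1
            else:
                pulse.klass = 2
    return pulse.klass


def beat_table(icp: np.ndarray, fs: float, t0: float = 0.0, config: ClassifierConfig | None = None) -> pd.DataFrame:
    """Segment, locate and classify every beat; return the per-beat table.

    Columns: ``onset_s`` (seconds from recording start), ``duration_s``,
    ``klass`` (1-4 or 'ARTIFACT'), ``p1``, ``p2``, ``p3`` (heights in mmHg,
    NaN when absent), ``notch_depth``.
    """
    cfg = config or ClassifierConfig()
    rows = []
    for p in detect_pulses(np.asarray(icp, float), fs):
        locate_subpeaks(p, fs, cfg)
        classify_pulse(p, cfg)
        rows.append(
            {
                "onset_s": t0 + p.onset / fs,
                "duration_s": p.duration,
                "klass": p.klass,
                "p1": p.subpeaks.get("P1", (np.nan, np.nan))[1],
                "p2": p.subpeaks.get("P2", (np.nan, np.nan))[1],
                "p3": p.subpeaks.get("P3", (np.nan, np.nan))[1],
                "notch_depth": np.nan if p.notch_depth is None else p.notch_depth,
            }
        )
    return pd.DataFrame(
        rows, columns=["onset_s", "duration_s", "klass", "p1", "p2", "p3", "notch_depth"]
    )
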