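"""Seedable simulator of ICP/ABP neuromonitoring recordings and cohorts.

The generator is a *surrogate*: it reproduces the signal features the
downstream analysis relies on -- three cardiac sub-peaks (P1 systolic, P2
tidal, P3 dicrotic) whose ordering inverts as intracranial compliance is
exhausted, slow mean-ICP dynamics on an exponential pressure-volume curve
``P = P0 * exp(k * V)``, B-wave-band slow oscillations of ABP coupled into ICP
with a sign controlled by the state of cerebrovascular autoregulation, and
sensor artifacts (spikes, flat-line dropouts) -- without claiming validated
cardiovascular physiology.

Single knobs:

``c`` (compliance impairment, 0..1)
    0 is a normal pulse (P1 > P2 > P3, crisp dicrotic notch); 1 is exhausted
    compliance (sub-waves merged into one rounded peak, P2 dominant).
``a`` (autoregulation failure, 0..1)
    1 transmits slow ABP waves into ICP with positive sign (pressure-passive
    vasculature, PRx > 0); 0 produces counter-regulated negative coupling
    (PRx < 0); 0.5 is neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SimConfig",
    "CohortSpec",
    "RawRecording",
    "simulate_pulse",
    "simulate_recording",
    "simulate_cohort",
    "simulate_hourly_cohort",
    "simulate_minute_cohort",
]

# Sub-wave template constants: fractional latencies of P1/P2/P3 within a beat
# and the laws mapping compliance impairment c to kernel heights and width.
# Calibrated so that c=0 yields three distinct peaks with P1 > P2 > P3 and a
# clear notch, while at c=1 the kernels merge into a single rounded peak.
_SUBWAVE_LATENCIES = (0.15, 0.35, 0.55)


def _subwave_heights(c: float) -> tuple[float, float, float]:
    h1 = 1.0 - 0.35 * c
    h2 = 0.65 + 0.55 * c
    h3 = 0.45 + 0.35 * c
    return h1, h2, h3


def _subwave_sigma(c: float) -> float:
    return 0.05 + 0.04 * c


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated patient-recording.

    Attributes
    ----------
    seed : int
        RNG seed; identical configs produce identical recordings.
    duration : float
        Recording length in seconds (> 0).
    fs : float
        Sampling frequency in Hz; the supported acquisition range is
        50-250 Hz.
    heart_rate : float
        Mean heart rate, beats/min.
    compliance_impairment : float
        ``c`` in [0, 1]; drives pulse morphology (see module docstring).
    pv_elastance : float
        ``k`` of the pressure-volume curve, 1/mL.
    pv_baseline : float
        ``P0`` of the pressure-volume curve, mmHg (ICP at zero volume load).
    volume_load : float | sequence | callable
        Added intracranial volume V(t) in mL: a constant, an array sampled on
        the recording grid, or a callable of time in seconds.
    autoreg_failure : float
        ``a`` in [0, 1]; slow ABP-to-ICP coupling sign (see module docstring).
    slow_wave_amplitude : float
        Peak amplitude of slow (B-wave band, 0.5-2 cycles/min) ABP waves, mmHg.
    artifact_rate : float
        Expected artifact events per hour (spikes and dropouts, half each).
    abp_mean, abp_pulse_amp : float
        Mean ABP and arterial pulse amplitude, mmHg.
    noise_sd : float
        White measurement noise s.d. added to both channels, mmHg.
    """

    seed: int = 0
    duration: float = 600.0
    fs: float = 100.0
    heart_rate: float = 70.0
    compliance_impairment: float = 0.0
    pv_elastance: float = 0.11
    pv_baseline: float = 10.0
    volume_load: float | Sequence[float] | Callable[[np.ndarray], np.ndarray] = 0.0
    autoreg_failure: float = 0.5
    slow_wave_amplitude: float = 4.0
    artifact_rate: float = 0.0
    abp_mean: float = 90.0
    abp_pulse_amp: float = 40.0
    noise_sd: float = 0.2

    def validate(self) -> None:
        if not (50.0 <= self.fs <= 250.0):
            raise ValueError(f"fs must lie in [50, 250] Hz, got {self.fs}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (0.0 <= self.compliance_impairment <= 1.0):
            raise ValueError("compliance_impairment must lie in [0, 1]")
        if not (0.0 <= self.autoreg_failure <= 1.0):
            raise ValueError("autoreg_failure must lie in [0, 1]")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")


@dataclass
class RawRecording:
    """Two-channel fixed-rate recording plus simulator ground truth.

    ``truth`` holds per-sample/per-beat channels populated by the simulator:
    ``artifact`` (bool per sample), ``compliance`` (c per sample),
    ``beat_onsets`` (sample indices), ``beat_class`` (nominal class per beat).
    """

    fs: float
    icp: np.ndarray
    abp: np.ndarray
    t0: float = 0.0
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.icp = np.asarray(self.icp, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if self.icp.shape != self.abp.shape:
            raise ValueError("icp and abp must have equal length")

    @property
    def duration(self) -> float:
        return len(self.icp) / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.icp)) / self.fs


def simulate_pulse(
    c: float,
    heart_rate: float = 70.0,
    fs: float = 100.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One cardiac ICP pulse, normalised to [0, 1], for impairment ``c``.

    The beat is a superposition of three positive Gaussian sub-waves at fixed
    fractional latencies.  At ``c = 0`` the heights obey P1 > P2 > P3 with a
    distinct dicrotic notch; as ``c`` grows P2 (and P3) rise while P1 falls
    and the kernels widen until the waveform becomes a single rounded peak.
    The P2/P1 height ratio is a continuous, monotone-increasing function of c.

    ``rng``, when given, jitters sub-wave latencies slightly (beat-to-beat
    variability); omitted, the pulse is deterministic.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"compliance impairment c must lie in [0, 1], got {c}")
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    n = max(int(round(fs * 60.0 / heart_rate)), 8)
    tau = np.arange(n) / n
    lat = np.asarray(_SUBWAVE_LATENCIES, dtype=float)
    if rng is not None:
        lat = lat + rng.normal(0.0, 0.005, size=3)
    heights = _subwave_heights(c)
    sigma = _subwave_sigma(c)
    w = np.zeros(n)
    for h, mu in zip(heights, lat):
        w += h * np.exp(-0.5 * ((tau - mu) / sigma) ** 2)
    w -= w.min()
    peak = w.max()
    if peak > 0:
        w /= peak
    return w


def _volume_trajectory(cfg: SimConfig, t: np.ndarray) -> np.ndarray:
    v = cfg.volume_load
    if callable(v):
        return np.asarray(v(t), dtype=float)
    v = np.asarray(v, dtype=float)
    if v.ndim == 0:
        return np.full_like(t, float(v))
    if len(v) != len(t):
        # trajectory given on its own grid: linear interpolation onto samples
        src = np.linspace(t[0], t[-1], len(v))
        return np.interp(t, src, v)
    return v


def _slow_wave(t: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """B-wave-band (0.5-2 cycles/min) quasi-periodic slow wave, peak ~amplitude."""
    if amplitude == 0:
        return np.zeros_like(t)
    freqs = rng.uniform(0.5 / 60.0, 2.0 / 60.0, size=2)
    phases = rng.uniform(0, 2 * np.pi, size=2)
    w = sum(np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases))
    return amplitude * w / 2.0


def _nominal_class(c: float) -> int:
    """Ground-truth morphology class implied by impairment c."""
    return int(min(4, 1 + np.floor(c * 4)))


_ABP_LATENCIES = (0.18, 0.45)
_ABP_HEIGHTS = (1.0, 0.45)


def _abp_pulse(n: int) -> np.ndarray:
    tau = np.arange(n) / n
    w = np.zeros(n)
    for h, mu, s in zip(_ABP_HEIGHTS, _ABP_LATENCIES, (0.07, 0.09)):
        w += h * np.exp(-0.5 * ((tau - mu) / s) ** 2)
    w -= w.min()
    return w / w.max()


# ABP-to-ICP transmission gain for the slow waves when autoregulation has
# fully failed (a=1); at a=0 the same gain appears with negative sign.
_COUPLING_GAIN = 0.5
# Pulse amplitude per unit of local PV-curve slope k*P (mmHg per mmHg/mL).
_PULSE_GAIN = 5.0


def simulate_recording(cfg: SimConfig) -> RawRecording:
    """Synthesise one two-channel recording from ``cfg``.

    Mean ICP follows ``P(t) = P0 * exp(k * V(t))`` plus the coupled slow wave;
    the cardiac pulse amplitude scales with the local pressure-volume slope
    ``k * P(t)`` so that volume loading steepens both mean and pulse pressure.
    A fraction controlled by ``autoreg_failure`` of the slow ABP variation is
    transmitted into ICP with positive sign (net gain ``(2a - 1)``), spikes and
    flat-line dropouts are injected at ``artifact_rate`` events/hour, and all
    ground-truth channels are populated.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs

    v = _volume_trajectory(cfg, t)
    p_curve = cfg.pv_baseline * np.exp(cfg.pv_elastance * v)

    abp_slow = _slow_wave(t, cfg.slow_wave_amplitude, rng)
    a = cfg.autoreg_failure
    icp_slow = (2.0 * a - 1.0) * _COUPLING_GAIN * abp_slow
    icp_mean = p_curve + icp_slow

    # beat train with small inter-beat jitter
    mean_ibi = 60.0 / cfg.heart_rate
    n_beats = int(np.ceil(cfg.duration / mean_ibi)) + 2
    ibis = mean_ibi * np.clip(1.0 + 0.03 * rng.standard_normal(n_beats), 0.7, 1.3)
    onsets_s = np.concatenate([[0.0], np.cumsum(ibis)])

    icp = icp_mean.copy()
    abp = cfg.abp_mean + abp_slow
    c = cfg.compliance_impairment
    beat_onsets: list[int] = []
    beat_class: list[int] = []
    for b in range(len(onsets_s) - 1):
        i0 = int(round(onsets_s[b] * cfg.fs))
        i1 = int(round(onsets_s[b + 1] * cfg.fs))
        if i0 >= n:
            break
        i1 = min(i1, n)
        m = i1 - i0
        if m < 4:
            continue
        hr_b = 60.0 / (m / cfg.fs)
        shape = simulate_pulse(c, heart_rate=hr_b, fs=cfg.fs, rng=rng)[:m]
        shape_c = shape - shape.mean()
        local_amp = _PULSE_GAIN * cfg.pv_elastance * icp_mean[i0]
        icp[i0:i1] += local_amp * shape_c
        abp_shape = _abp_pulse(m)
        abp[i0:i1] += cfg.abp_pulse_amp * (abp_shape - abp_shape.mean())
        beat_onsets.append(i0)
        beat_class.append(_nominal_class(c))

    if cfg.noise_sd > 0:
        icp += rng.normal(0.0, cfg.noise_sd, n)
        abp += rng.normal(0.0, cfg.noise_sd, n)

    artifact = np.zeros(n, dtype=bool)
    n_events = rng.poisson(cfg.artifact_rate * cfg.duration / 3600.0)
    for _ in range(n_events):
        start = rng.integers(0, n)
        if rng.random() < 0.5:  # spike above the physiological range
            width = int(rng.integers(1, 4))
            stop = min(start + width, n)
            icp[start:stop] = rng.uniform(210.0, 260.0)
        else:  # flat-line dropout, 5-60 s at zero
            width = int(rng.uniform(5.0, 60.0) * cfg.fs)
            stop = min(start + width, n)
            icp[start:stop] = 0.0
        artifact[start:stop] = True

    truth = {
        "artifact": artifact,
        "compliance": np.full(n, c),
        "beat_onsets": np.asarray(beat_onsets, dtype=int),
        "beat_class": np.asarray(beat_class, dtype=int),
        "mean_icp": icp_mean,
    }
    return RawRecording(fs=cfg.fs, icp=icp, abp=abp, t0=0.0, truth=truth)


@dataclass(frozen=True)
class CohortSpec:
    """Sampler for a multi-patient synthetic cohort.

    Per-patient compliance impairment, autoregulation failure, age, GCS and
    duration are drawn from simple parametric distributions; the 6-month GOS
    is then sampled from an ordinal (proportional-odds) logistic model whose
    linear predictor rises with preserved compliance and falls with mean-ICP
    burden, so worse physiology begets worse outcome on average.  A fraction
    of patients is flagged as decompressive-craniectomy (DC) treated or as
    missing outcome to exercise cohort screening.
    """

    n_patients: int = 20
    seed: int = 0
    duration: float = 1800.0
    fs: float = 100.0
    base_config: SimConfig = field(default_factory=SimConfig)
    beta_compliance: float = 2.0
    beta_icp_burden: float = -0.15
    gos_cutpoints: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5)
    p_dc: float = 0.2
    p_missing_outcome: float = 0.15
    p_dc_unknown: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")


def _ordinal_gos(eta: float, cutpoints: Sequence[float], rng: np.random.Generator) -> int:
    """Sample GOS 1..5 from a proportional-odds model with linear predictor eta."""
    cut = np.asarray(cutpoints, dtype=float)
    cum = 1.0 / (1.0 + np.exp(-(cut - eta)))  # P(GOS <= j), j = 1..4
    probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    return int(rng.choice(5, p=probs)) + 1


def simulate_cohort(spec: CohortSpec) -> list[tuple[RawRecording, dict]]:
    """Generate ``spec.n_patients`` recordings with per-patient metadata.

    One root seed spawns independent per-patient child streams so each
    patient's recording is reproducible regardless of cohort size.  Metadata
    keys: ``patient``, ``age``, ``gcs``, ``gos`` (may be None), ``dc_status``
    (performed | not_performed | unknown), ``monitored_hours``, plus the
    generating ``compliance_impairment`` and ``autoreg_failure``.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_patients)
    out: list[tuple[RawRecording, dict]] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        c = float(np.clip(rng.beta(2.0, 2.5), 0.0, 1.0))
        a = float(rng.uniform(0.0, 1.0))
        age = float(np.clip(rng.normal(45.0, 16.0), 16.0, 90.0))
        gcs = int(rng.integers(3, 13))
        vload = float(rng.uniform(0.0, 6.0))
        cfg = replace(
            spec.base_config,
            seed=int(rng.integers(0, 2**31 - 1)),
            duration=spec.duration,
            fs=spec.fs,
            compliance_impairment=c,
            autoreg_failure=a,
            volume_load=vload,
        )
        rec = simulate_recording(cfg)
        mean_icp = float(np.mean(rec.truth["mean_icp"]))
        eta = spec.beta_compliance * (1.0 - c) + spec.beta_icp_burden * (mean_icp - 15.0)
        gos = _ordinal_gos(eta, spec.gos_cutpoints, rng)
        u = rng.random()
        if u < spec.p_dc:
            dc = "performed"
        elif u < spec.p_dc + spec.p_dc_unknown:
            dc = "unknown"
        else:
            dc = "not_performed"
        missing = rng.random() < spec.p_missing_outcome
        meta = {
            "patient": f"P{i:03d}",
            "age": age,
            "gcs": gcs,
            "gos": None if missing else gos,
            "dc_status": dc,
            "monitored_hours": rec.duration / 3600.0,
            "compliance_impairment": c,
            "autoreg_failure": a,
        }
        out.append((rec, meta))
    return out


def simulate_hourly_cohort(
    n_patients: int = 50,
    n_hours: int = 48,
    seed: int = 0,
    lag_hours: int = 1,
    beta_psi: float = 6.0,
    icp_base: float = 12.0,
    intercept_sd: float = 2.0,
    noise_sd: float = 1.5,
    minute_sd: float = 4.0,
):
    """Hourly-resolution cohort in which PSI elevation *precedes* ICP elevation.

    Each patient carries a latent slowly varying PSI trajectory (bounded AR(1)
    on [1, 4]); hourly mean ICP at hour ``t`` responds to PSI at hour
    ``t - lag_hours`` through ``icp_mean = icp_base + beta_psi*(psi - 1) +
    patient intercept + noise``.  Within each hour, 60 minute-level ICP values
    are drawn around the hourly mean (s.d. ``minute_sd``) so that burden
    metrics (%GMT > threshold, dose, insults) can be computed exactly as for
    real minute data.  Returns a tidy DataFrame with one row per
    patient-minute: columns ``patient``, ``hour``, ``minute``, ``icp``,
    ``psi``.
    """
    import pandas as pd

    root = np.random.SeedSequence(seed)
    rows = []
    for i, child in enumerate(root.spawn(n_patients)):
        rng = np.random.default_rng(child)
        b0 = rng.normal(0.0, intercept_sd)
        psi = np.empty(n_hours)
        psi[0] = rng.uniform(1.2, 3.0)
        for h in range(1, n_hours):
            psi[h] = np.clip(
                1.0 + 0.85 * (psi[h - 1] - 1.0) + rng.normal(0.0, 0.35), 1.0, 4.0
            )
        icp_mean = np.full(n_hours, np.nan)
        for h in range(n_hours):
            src = psi[h - lag_hours] if h >= lag_hours else psi[0]
            icp_mean[h] = icp_base + beta_psi * (src - 1.0) + b0 + rng.normal(0, noise_sd)
        for h in range(n_hours):
            icp_min = icp_mean[h] + rng.normal(0.0, minute_sd, 60)
            psi_min = np.clip(psi[h] + rng.normal(0.0, 0.1, 60), 1.0, 4.0)
            rows.append(
                pd.DataFrame(
                    {
                        "patient": f"P{i:03d}",
                        "hour": h,
                        "minute": h * 60 + np.arange(60),
                        "icp": icp_min,
                        "psi": psi_min,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_minute_cohort(
    n_patients: int = 60,
    n_minutes: int = 720,
    seed: int = 0,
    outcome_beta: float = -4.0,
    psi_threshold: float = 2.5,
    gos_cutpoints: Sequence[float] = (-2.0, -1.0, 0.0, 1.0),
):
    """Minute-level PSI/ICP/PRx/CPP cohort with outcome tied to PSI exposure.

    Per patient, minute PSI follows a bounded random walk on [1, 4]; ICP, PRx
    and CPP are generated as noisy monotone functions of PSI.  The GOS is
    drawn from an ordinal model whose linear predictor is
    ``outcome_beta * (fraction of minutes with PSI > psi_threshold) + z`` so
    that, with ``outcome_beta < 0``, time spent at high PSI worsens outcome.
    Returns ``(minute_frames, metadata)`` where ``minute_frames`` maps patient
    id to a DataFrame with columns ``minute, icp, abp, cpp, amp_icp, rap,
    prx, psi`` and ``metadata`` is a DataFrame with ``patient, gos, age,
    gcs``.
    """
    import pandas as pd

    root = np.random.SeedSequence(seed)
    frames: dict[str, "pd.DataFrame"] = {}
    meta_rows = []
    for i, child in enumerate(root.spawn(n_patients)):
        rng = np.random.default_rng(child)
        level = rng.uniform(1.1, 3.4)
        psi = np.clip(level + np.cumsum(rng.normal(0, 0.05, n_minutes)), 1.0, 4.0)
        icp = np.clip(6.0 + 7.0 * (psi - 1.0) + rng.normal(0, 2.0, n_minutes), 0.0, 60.0)
        prx = np.clip(-0.3 + 0.35 * (psi - 1.0) + rng.normal(0, 0.15, n_minutes), -1, 1)
        abp = 90.0 + rng.normal(0, 5.0, n_minutes)
        cpp = abp - icp
        amp = np.clip(3.0 + 2.0 * (psi - 1.0) + rng.normal(0, 0.8, n_minutes), 0.1, 39.0)
        rap = np.clip(0.3 + 0.2 * (psi - 1.0) + rng.normal(0, 0.1, n_minutes), -1, 1)
        frac_high = float(np.mean(psi > psi_threshold))
        eta = outcome_beta * frac_high + rng.normal(0, 0.5) + 2.0
        gos = _ordinal_gos(eta, gos_cutpoints, rng)
        pid = f"P{i:03d}"
        frames[pid] = pd.DataFrame(
            {
                "minute": np.arange(n_minutes),
                "icp": icp,
                "abp": abp,
                "cpp": cpp,
                "amp_icp": amp,
                "rap": rap,
                "prx": prx,
                "psi": psi,
            }
        )
        meta_rows.append(
            {
                "patient": pid,
                "gos": gos,
                "age": float(np.clip(rng.normal(45, 16), 16, 90)),
                "gcs": int(rng.integers(3, 13)),
            }
        )
    return frames, pd.DataFrame(meta_rows)
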