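import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rec_normal():
    """600-s normal-compliance (c=0) recording at 100 Hz, 70 bpm."""
    from icpsi.simulate import SimConfig, simulate_recording

    return simulate_recording(SimConfig(seed=11, duration=600.0, fs=100.0))


@pytest.fixture(scope="session")
def beats_normal(rec_normal):
    from icpsi.pulses import beat_table

    return beat_table(rec_normal.icp, rec_normal.fs)


@pytest.fixture(scope="session")
def exclusion_metadata():
    """781-patient metadata table realising the published exclusion cascade:
    205 missing outcome, then 213 DC-treated/unknown, then 42 under 12 h."""
    import pandas as pd

    rng = np.random.default_rng(7)
    gos = np.concatenate([np.full(205, np.nan), rng.integers(1, 6, 576).astype(float)])
    dc = np.array(["not_performed"] * 781, dtype=object)
    dc[205:340] = "performed"  # 135 performed among outcome-known
    dc[340:418] = "unknown"  # 78 unknown -> 213 excluded at step 2
    hours = np.full(781, 48.0)
    hours[418:460] = rng.uniform(0.5, 11.9, 42)  # 42 short among survivors of step 2
    # overlap on purpose: some missing-outcome patients also DC'd / short,
    # exercising the precedence rule
    dc[:30] = "performed"
    hours[:10] = 2.0
    return pd.DataFrame(
        {
            "patient": [f"P{i:04d}" for i in range(781)],
            "gos": gos,
            "dc_status": dc,
            "monitored_hours": hours,
        }
    )
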