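"""Windowing, validity and resampling rules of the bedside index battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import pearsonr

from icpsi import indices as ind
from icpsi.simulate import SimConfig, simulate_recording


class TestRejectIcpRange:
    def test_bounds_are_strict(self):
        mask = ind.reject_icp_range(np.array([10.0, 250.0, 15.0, -30.0, 200.0, -31.0]))
        np.testing.assert_array_equal(mask, [True, False, True, True, True, False])

    def test_all_valid_is_identity(self):
        x = np.random.default_rng(0).uniform(0, 40, 100)
        assert ind.reject_icp_range(x).all()


class TestPsi:
    @pytest.mark.parametrize(
        "classes,expected",
        [
            ([1] * 50, 1.0),
            ([1] * 25 + [3] * 25, 2.0),
            ([1] * 30 + [2] * 30 + [3] * 30 + [4] * 10, 2.2),
        ],
    )
    def test_weighted_average_examples(self, classes, expected):
        assert ind.psi_5min(classes) == pytest.approx(expected, abs=1e-12)

    def test_artifact_beats_excluded_and_quorum_enforced(self):
        assert ind.psi_5min([1] * 40 + ["ARTIFACT"] * 20) == 1.0
        assert np.isnan(ind.psi_5min([2] * 29))

    @given(st.lists(st.integers(1, 4), min_size=30, max_size=200))
    def test_matches_direct_weighted_mean(self, classes):
        counts = {c: classes.count(c) for c in (1, 2, 3, 4)}
        expected = sum(c * n for c, n in counts.items()) / len(classes)
        assert ind.psi_5min(classes) == pytest.approx(expected)

    def test_series_assigns_beats_to_windows(self):
        beats = pd.DataFrame(
            {"onset_s": np.arange(0, 600, 1.0), "klass": [1] * 300 + [3] * 300}
        )
        s = ind.psi_series(beats, duration=600.0)
        assert list(s["psi"]) == [1.0, 3.0]


class TestAmpIcp:
    def test_sinusoid_amplitude(self):
        fs = 100.0
        t = np.arange(0, 300, 1 / fs)
        sig = 15 + 3 * np.sin(2 * np.pi * 1.0 * t)
        amps = ind._per_second_amplitudes(sig, fs, np.ones(len(t), bool))
        assert ind.amp_icp_5min(amps) == pytest.approx(6.0, rel=1e-6)

    def test_constant_signal_invalid(self):
        fs = 100.0
        sig = np.full(int(300 * fs), 12.0)
        amps = ind._per_second_amplitudes(sig, fs, np.ones(len(sig), bool))
        assert np.isnan(ind.amp_icp_5min(amps))

    def test_out_of_validity_range_excluded(self):
        assert np.isnan(ind.amp_icp_5min(np.full(60, 45.0)))
        assert np.isnan(ind.amp_icp_5min(np.full(60, 0.02)))

    def test_masked_sample_skips_window(self):
        fs = 100.0
        t = np.arange(0, 10, 1 / fs)
        sig = 15 + 3 * np.sin(2 * np.pi * 1.0 * t)
        valid = np.ones(len(t), bool)
        valid[50] = False  # poisons windows starting at seconds 0 (0-1.5s)
        amps = ind._per_second_amplitudes(sig, fs, valid)
        assert np.isnan(amps[0])
        assert np.isfinite(amps[3])


class TestDownsample:
    def test_constant(self):
        fs = 100.0
        d = ind.downsample_10s(np.full(int(60 * fs), 12.0), fs, np.ones(6000, bool))
        assert (d["mean"] == 12.0).all()

    def test_majority_invalid_bin_absent(self):
        fs = 100.0
        x = np.full(int(10 * fs), 5.0)
        valid = np.zeros(len(x), bool)
        valid[: int(0.4 * len(x))] = True
        assert np.isnan(ind.downsample_10s(x, fs, valid)["mean"].iloc[0])

    def test_linear_ramp_mean(self):
        fs = 100.0
        x = np.linspace(0, 10, int(10 * fs), endpoint=False)
        d = ind.downsample_10s(x, fs, np.ones(len(x), bool))
        assert d["mean"].iloc[0] == pytest.approx(5.0, abs=0.01)


class TestFundamentalAmplitude:
    def test_sinusoid_in_cardiac_band(self):
        fs = 100.0
        seg = 2 * np.sin(2 * np.pi * 1.2 * np.arange(0, 10, 1 / fs))
        assert ind.fundamental_amplitude(seg, fs) == pytest.approx(2.0, rel=0.05)

    def test_constant_absent(self):
        assert np.isnan(ind.fundamental_amplitude(np.full(1000, 9.0), 100.0))

    def test_out_of_band_tone_absent(self):
        fs = 100.0
        seg = 2 * np.sin(2 * np.pi * 0.3 * np.arange(0, 10, 1 / fs))
        assert np.isnan(ind.fundamental_amplitude(seg, fs))


def _ten_frame(icp, amp=None, abp=None):
    n = len(icp)
    return pd.DataFrame(
        {
            "t": 10.0 * np.arange(n),
            "mean_icp": icp,
            "mean_abp": abp if abp is not None else np.full(n, 90.0),
            "fund_amp": amp if amp is not None else np.full(n, 3.0),
        }
    )


class TestMovingCorrelations:
    def test_affine_channels_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        icp = 15 + rng.normal(0, 2, 60)
        up = ind.rap(_ten_frame(icp, amp=0.5 * icp + 3.0))
        dn = ind.rap(_ten_frame(icp, amp=-0.5 * icp + 20.0))
        assert np.allclose(up["rap"].dropna(), 1.0)
        assert np.allclose(dn["rap"].dropna(), -1.0)

    def test_null_channels_average_near_zero(self):
        rng = np.random.default_rng(1)
        n = 6 * 1005 + 30  # > 1000 emitted windows
        icp = rng.normal(15, 2, n)
        amp = rng.normal(3, 1, n)
        out = ind.rap(_ten_frame(icp, amp=amp))
        vals = out["rap"].dropna()
        assert len(vals) >= 1000
        assert abs(vals.mean()) < 0.1

    def test_zero_variance_window_absent(self):
        icp = np.full(60, 15.0)
        out = ind.prx(_ten_frame(icp, abp=np.random.default_rng(2).normal(90, 5, 60)))
        assert out["prx"].dropna().empty

    def test_matches_bruteforce_pearson_per_window(self):
        rng = np.random.default_rng(3)
        n = 6 * 205 + 30
        icp = rng.normal(15, 3, n)
        abp = rng.normal(90, 6, n)
        icp[rng.choice(n, 40, replace=False)] = np.nan  # sprinkle invalid bins
        ten = _ten_frame(icp, abp=abp)
        out = ind.prx(ten).set_index("minute")
        checked = 0
        for m in out.index:
            end = int(m * 60 / 10)
            start = end - 30
            if start < 0:
                continue
            xs = abp[start:end]
            ys = icp[start:end]
            ok = np.isfinite(xs) & np.isfinite(ys)
            if ok.sum() < 15 or np.std(xs[ok]) == 0 or np.std(ys[ok]) == 0:
                assert np.isnan(out.at[m, "prx"])
            else:
                expect = pearsonr(xs[ok], ys[ok]).statistic
                assert abs(out.at[m, "prx"] - expect) < 1e-10
                checked += 1
        assert checked >= 200

    def test_simulated_autoregulation_recovered_by_prx(self):
        medians = {}
        for a in (1.0, 0.0):
            cfg = SimConfig(seed=8, duration=2400.0, fs=50.0, autoreg_failure=a)
            rec = simulate_recording(cfg)
            valid = ind.reject_icp_range(rec.icp)
            ten = ind.ten_second_series(rec.icp, rec.abp, rec.fs, valid)
            medians[a] = np.nanmedian(ind.prx(ten)["prx"])
        assert medians[1.0] > 0.2
        assert medians[0.0] < 0.0


class TestMinuteSeries:
    def _assemble(self, psi_vals=(2.2,), n_min=5, abp_nan_minute=None):
        n_ten = n_min * 6
        icp = np.full(n_ten, 14.0)
        abp = np.full(n_ten, 90.0)
        if abp_nan_minute is not None:
            abp[abp_nan_minute * 6 : (abp_nan_minute + 1) * 6] = np.nan
        ten = pd.DataFrame(
            {"t": 10.0 * np.arange(n_ten), "mean_icp": icp, "mean_abp": abp,
             "fund_amp": np.full(n_ten, 3.0)}
        )
        n5 = max(int(np.ceil(n_min / 5)), 1)
        psi5 = pd.DataFrame({"t": 300.0 * np.arange(n5), "psi": list(psi_vals) * n5})
        amp5 = pd.DataFrame({"t": 300.0 * np.arange(n5), "amp_icp": [6.0] * n5})
        empty = pd.DataFrame({"minute": [], "rap": []})
        empty2 = pd.DataFrame({"minute": [], "prx": []})
        return ind.assemble_minute_series(ten, psi5, amp5, empty.rename(columns={"rap": "rap"}), empty2, duration=n_min * 60.0)

    def test_psi_value_held_over_five_minutes(self):
        out = self._assemble(psi_vals=(2.2,), n_min=5)
        assert (out["psi"] == 2.2).all()
        assert len(out) == 5

    def test_cpp_identity(self):
        out = self._assemble()
        assert np.allclose(out["cpp"], 90.0 - 14.0)

    def test_cpp_absent_without_abp(self):
        out = self._assemble(abp_nan_minute=2)
        assert np.isnan(out.loc[2, "cpp"])
        assert np.isfinite(out.loc[1, "cpp"])


class TestSummarize:
    def _minutes(self, psi):
        n = len(psi)
        return pd.DataFrame(
            {"minute": np.arange(n), "icp": 14.0, "abp": 90.0, "cpp": 76.0,
             "amp_icp": 6.0, "rap": 0.5, "prx": 0.1, "psi": psi}
        )

    def test_single_bin_occupancy(self):
        s = ind.summarize_patient(self._minutes([1.2] * 40))
        assert s.psi_bin_pct[0] == 100.0
        assert s.psi_bin_pct[1:].sum() == 0.0

    def test_split_bins(self):
        s = ind.summarize_patient(self._minutes([1.2] * 30 + [3.2] * 10))
        assert s.psi_bin_pct[0] == pytest.approx(75.0)
        assert s.psi_bin_pct[4] == pytest.approx(25.0)

    @given(st.lists(st.floats(1.0, 4.0), min_size=1, max_size=300))
    def test_bin_percentages_sum_to_100(self, psi):
        s = ind.summarize_patient(self._minutes(psi))
        assert s.psi_bin_pct.sum() == pytest.approx(100.0)

    def test_zero_gmt_channel_absent(self):
        df = self._minutes([np.nan] * 20)
        s = ind.summarize_patient(df)
        assert np.isnan(s.medians["psi"])
        assert s.gmt_hours["psi"] == 0.0
        assert np.all(s.psi_bin_pct == 0.0)


class TestProcessRecording:
    def test_end_to_end_minute_series(self, rec_normal, beats_normal):
        mins = ind.process_recording(rec_normal, beats_normal)
        assert list(mins.columns) == ind.MINUTE_COLUMNS
        assert len(mins) == 10
        assert np.nanmedian(mins["psi"]) == pytest.approx(1.0, abs=0.15)
        assert np.nanmedian(mins["icp"]) == pytest.approx(10.0, abs=1.0)
        assert np.allclose(
            mins["cpp"].dropna(), (mins["abp"] - mins["icp"]).dropna(), atol=1e-9
        )
        valid_amp = mins["amp_icp"].dropna()
        assert ((valid_amp > 0.04) & (valid_amp < 40)).all()
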