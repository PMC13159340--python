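"""Cohort screening, group comparisons, logistic models and GAM curves."""

import numpy as np
import pandas as pd
import pytest

from icpsi.stats import (
    GAM_X_RANGES,
    cohort_filter,
    compare_groups,
    fit_outcome_logistic,
    gam_curves,
)


class TestCohortFilter:
    def test_published_exclusion_cascade(self, exclusion_metadata):
        included, tally = cohort_filter(exclusion_metadata)
        assert tally == {
            "input": 781,
            "missing_outcome": 205,
            "dc_or_unknown": 213,
            "short_monitoring": 42,
            "included": 321,
        }
        assert len(included) == 321

    def test_tally_sums_to_input(self, exclusion_metadata):
        _, tally = cohort_filter(exclusion_metadata)
        assert (
            tally["missing_outcome"] + tally["dc_or_unknown"]
            + tally["short_monitoring"] + tally["included"]
        ) == tally["input"]

    def test_empty_input(self):
        df = pd.DataFrame(columns=["gos", "dc_status", "monitored_hours"])
        included, tally = cohort_filter(df)
        assert len(included) == 0
        assert tally["input"] == 0

    def test_precedence_counts_first_failure_only(self):
        df = pd.DataFrame(
            [{"gos": np.nan, "dc_status": "performed", "monitored_hours": 1.0}]
        )
        _, tally = cohort_filter(df)
        assert tally["missing_outcome"] == 1
        assert tally["dc_or_unknown"] == 0
        assert tally["short_monitoring"] == 0


def _summaries(rng, n_per_group=50, shift=0.0):
    """Two outcome groups with the event group's PSI shifted by `shift` SD."""
    sd = 0.5
    dead = pd.DataFrame(
        {"gos": 1.0, "psi_median": rng.normal(2.0 + shift * sd, sd, n_per_group)}
    )
    alive = pd.DataFrame({"gos": 4.0, "psi_median": rng.normal(2.0, sd, n_per_group)})
    return pd.concat([dead, alive], ignore_index=True)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        df = pd.DataFrame(
            {"gos": [1.0] * 20 + [4.0] * 20, "psi_median": list(range(20)) * 2}
        )
        out = compare_groups(df, outcome="mortality", value_cols=["psi_median"])
        assert out["pvalue"].iloc[0] > 0.9

    def test_shifted_groups_detected_reliably(self):
        hits = 0
        for seed in range(100):
            df = _summaries(np.random.default_rng(seed), shift=2.0)
            out = compare_groups(df, outcome="mortality", value_cols=["psi_median"])
            hits += out["pvalue"].iloc[0] < 0.001
        assert hits >= 95

    def test_medians_match_quantile_oracle(self):
        df = _summaries(np.random.default_rng(5), shift=1.0)
        out = compare_groups(df, outcome="mortality", value_cols=["psi_median"]).iloc[0]
        event = df.loc[df["gos"] == 1.0, "psi_median"]
        assert out["median_event"] == pytest.approx(np.median(event))
        assert out["iqr_lo_event"] == pytest.approx(np.percentile(event, 25))
        assert out["iqr_hi_event"] == pytest.approx(np.percentile(event, 75))

    def test_tiny_group_flagged_undefined(self):
        df = pd.DataFrame({"gos": [1.0, 4.0, 4.0, 4.0], "psi_median": [2, 2, 3, 4.0]})
        out = compare_groups(df, outcome="mortality", value_cols=["psi_median"])
        assert not out["defined"].iloc[0]


def _logistic_cohort(rng, n=500, beta_psi=0.9):
    age = rng.normal(45, 15, n)
    gcs = rng.integers(3, 13, n).astype(float)
    psi = rng.normal(2.0, 0.5, n)
    eta = -1.0 + 0.03 * (age - 45) + beta_psi * (psi - 2.0)
    dead = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
    gos = np.where(dead, 1.0, rng.integers(2, 6, n).astype(float))
    return pd.DataFrame({"age": age, "gcs": gcs, "psi_median": psi, "gos": gos})


class TestOutcomeLogistic:
    def test_recovers_generative_odds_ratio(self):
        # median over replicates: a single n=500 fit has sampling error of
        # the same order as the recovery tolerance
        ests = []
        for seed in range(5):
            df = _logistic_cohort(np.random.default_rng(seed))
            out = fit_outcome_logistic(df, model="A", outcome="mortality")
            ests.append(out.set_index("covariate").at["psi_median", "or"])
        est = float(np.median(ests))
        assert abs(est - np.exp(0.9)) / np.exp(0.9) < 0.15

    def test_permuted_covariate_ci_covers_one(self):
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = _logistic_cohort(rng, n=300, beta_psi=0.9)
            df["psi_median"] = rng.permutation(df["psi_median"].to_numpy())
            out = fit_outcome_logistic(df, model="A", outcome="mortality")
            r = out.set_index("covariate")
            covered += r.at["psi_median", "ci_lo"] <= 1.0 <= r.at["psi_median", "ci_hi"]
        assert covered >= 90

    def test_degenerate_outcome_flagged(self):
        df = _logistic_cohort(np.random.default_rng(1))
        df["gos"] = 1.0
        out = fit_outcome_logistic(df, model="A", outcome="mortality")
        assert out["flagged"].all()
        assert "or" not in out.columns or out["or"].isna().all()

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            fit_outcome_logistic(pd.DataFrame(), model="C")


class TestGamCurves:
    def test_noiseless_monotone_input_gives_monotone_curve(self):
        rng = np.random.default_rng(2)
        icp = rng.uniform(0, 40, 3000)
        df = pd.DataFrame({"icp": icp, "psi": np.clip(1.0 + 3.0 * icp / 40.0, 1, 4)})
        c = gam_curves(df, "icp")
        assert np.all(np.diff(c.fit) > -1e-6)

    def test_independent_response_gives_flat_curve(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"icp": rng.uniform(0, 40, 10_000),
             "psi": np.clip(rng.normal(2.0, 0.3, 10_000), 1, 4)}
        )
        c = gam_curves(df, "icp")
        assert c.fit.max() - c.fit.min() < 0.1

    def test_range_filter_drops_exactly_out_of_bounds_points(self):
        df = pd.DataFrame(
            {"rap": np.concatenate([np.linspace(0, 1, 200), [-0.5, 1.5] * 10]),
             "psi": np.full(220, 2.0) + np.random.default_rng(4).normal(0, 0.1, 220)}
        )
        c = gam_curves(df, "rap", min_points=100)
        assert c.n_points == 200
        lo, hi = GAM_X_RANGES["rap"]
        assert c.grid.min() >= lo and c.grid.max() <= hi

    def test_too_few_points_refused(self):
        df = pd.DataFrame({"icp": np.linspace(0, 40, 50), "psi": np.full(50, 2.0)})
        with pytest.raises(ValueError, match="at least"):
            gam_curves(df, "icp")

    def test_sensitivity_exclusion_of_extreme_icp(self):
        rng = np.random.default_rng(5)
        n = 2000
        df = pd.DataFrame(
            {"rap": rng.uniform(0, 1, n), "icp": rng.uniform(0, 60, n),
             "psi": np.clip(rng.normal(2, 0.3, n), 1, 4)}
        )
        c_all = gam_curves(df, "rap")
        c_excl = gam_curves(df, "rap", exclude_icp_above=40.0)
        assert c_excl.n_points < c_all.n_points
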