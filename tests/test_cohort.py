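"""Synthetic cohort generator: calibration, structure, determinism, IO."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit, logit
from scipy.stats import norm, pearsonr

from moodhorizon.cohort import (
    DAILY_VARIABLES,
    CohortDataset,
    ConfigurationError,
    CohortParseError,
    SyntheticConfig,
    calibrate_prevalence,
    generate_cohort,
    read_cohort,
    write_cohort,
)


class TestCalibratePrevalence:
    def test_zero_effect_closed_form(self):
        assert calibrate_prevalence(0.5, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert calibrate_prevalence(0.068, 0.0) == pytest.approx(
            float(logit(0.068)), abs=1e-10
        )

    @pytest.mark.parametrize(
        "target,effect", [(0.185, 1.0), (0.068, 1.4), (0.5, 2.0), (0.9, 0.7)]
    )
    def test_matches_quadrature_oracle(self, target, effect):
        """E[expit(a + b U)] under the returned intercept equals the target.

        Independent oracle: adaptive quadrature of expit(a+b*u)*phi(u).
        """
        a = calibrate_prevalence(target, effect)
        oracle, _ = quad(
            lambda u: expit(a + effect * u) * norm.pdf(u), -12, 12, limit=200
        )
        assert oracle == pytest.approx(target, abs=1e-4)

    def test_invalid_target(self):
        with pytest.raises(ConfigurationError):
            calibrate_prevalence(0.0, 1.0)
        with pytest.raises(ConfigurationError):
            calibrate_prevalence(1.0, 1.0)


class TestConfigValidation:
    def test_nonfinite_parameter_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(mood_effect=float("nan"))

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(depression_prevalence_target=0.0)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(si_prevalence_target=1.0)

    def test_probability_bounds(self):
        with pytest.raises(ConfigurationError):
            SyntheticConfig(missingness_base=1.5)
        with pytest.raises(ConfigurationError):
            SyntheticConfig(adherence_decay=-0.1)


class TestGenerateCohort:
    def test_deterministic_given_config(self):
        cfg = SyntheticConfig(n_participants=50, horizon_days=10, seed=3)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.daily, b.daily)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)

    def test_shape_and_value_ranges(self, small_cohort):
        c = small_cohort
        assert len(c.daily) == c.n_participants * c.horizon_days
        mood = c.daily["mood"].dropna()
        assert ((mood >= 1) & (mood <= 10)).all()
        assert (mood % 1 == 0).all()
        eff = c.daily["sleep_efficiency"].dropna()
        assert ((eff >= 0) & (eff <= 100)).all()
        for col in ("total_steps", "sedentary_minutes", "very_active_minutes"):
            assert (c.daily[col].dropna() >= 0).all()
        assert set(c.daily["day"]) == set(range(1, c.horizon_days + 1))

    def test_prevalence_hits_targets(self):
        cfg = SyntheticConfig(n_participants=5000, horizon_days=2, seed=11)
        c = generate_cohort(cfg)
        assert c.outcomes["depression"].mean() == pytest.approx(0.185, abs=0.02)
        assert c.outcomes["si"].mean() == pytest.approx(0.068, abs=0.02)

    def test_null_config_no_mood_outcome_association(self):
        cfg = SyntheticConfig(
            n_participants=2000,
            horizon_days=10,
            mood_effect=0.0,
            mood_volatility_effect=0.0,
            missingness_severity_link=0.0,
            depression_severity_effect=0.0,
            seed=5,
        )
        c = generate_cohort(cfg)
        mean_mood = c.daily.groupby("participant_id", sort=False)["mood"].mean()
        mean_mood = mean_mood.reindex(c.participant_ids).fillna(5.0)
        r, _ = pearsonr(mean_mood.to_numpy(), c.labels("depression"))
        assert abs(r) < 0.06

    def test_missingness_nondecreasing_over_time(self):
        cfg = SyntheticConfig(
            n_participants=2000, horizon_days=60, adherence_decay=0.03, seed=9
        )
        c = generate_cohort(cfg)
        rate = c.daily.groupby("day")["mood"].apply(lambda s: s.isna().mean())
        binned = rate.groupby((rate.index - 1) // 10).mean()
        assert (np.diff(binned.to_numpy()) > -0.01).all()

    def test_cases_miss_more_when_severity_linked(self):
        cfg = SyntheticConfig(
            n_participants=2000,
            horizon_days=30,
            missingness_severity_link=0.5,
            seed=13,
        )
        c = generate_cohort(cfg)
        miss = (
            c.daily.groupby("participant_id", sort=False)["mood"]
            .apply(lambda s: s.isna().mean())
            .reindex(c.participant_ids)
        )
        dep = c.labels("depression").astype(bool)
        assert miss[dep].mean() > miss[~dep].mean()

    def test_wearable_signal_flag_controls_severity_loading(self):
        base = dict(n_participants=3000, horizon_days=5, seed=21)
        on = generate_cohort(SyntheticConfig(wearable_signal=True, **base))
        off = generate_cohort(SyntheticConfig(wearable_signal=False, **base))

        def corr_with_severity(c):
            hr = c.daily.groupby("participant_id", sort=False)["resting_hr"].mean()
            hr = hr.reindex(c.participant_ids)
            u = c.outcomes["latent_severity"].to_numpy()
            keep = ~hr.isna().to_numpy()
            return pearsonr(hr.to_numpy()[keep], u[keep])[0]

        assert corr_with_severity(on) > 0.15
        assert abs(corr_with_severity(off)) < 0.07

    def test_mood_signal_cutoff(self):
        base = dict(
            n_participants=3000, horizon_days=20, mood_effect=2.0,
            missingness_base=0.0, wearable_missingness_base=1.0, seed=17,
        )
        c = generate_cohort(SyntheticConfig(mood_signal_until=10, **base))
        u = c.outcomes["latent_severity"].to_numpy()

        def corr(days):
            sub = c.daily[c.daily["day"].isin(days)]
            m = sub.groupby("participant_id", sort=False)["mood"].mean()
            return pearsonr(m.reindex(c.participant_ids).to_numpy(), u)[0]

        assert corr(range(1, 11)) < -0.5  # severity lowers mood early
        assert abs(corr(range(11, 21))) < 0.07  # no link after the cutoff


class TestCohortIO:
    def test_round_trip(self, tmp_path, small_cohort):
        write_cohort(small_cohort, tmp_path / "cohort")
        back = read_cohort(tmp_path / "cohort")
        assert back.horizon_days == small_cohort.horizon_days
        pd.testing.assert_series_equal(
            back.daily["mood"].astype(float), small_cohort.daily["mood"],
            check_names=False,
        )
        for col in ("depression", "si"):
            assert (back.outcomes[col] == small_cohort.outcomes[col]).all()
        np.testing.assert_allclose(
            back.daily["total_steps"], small_cohort.daily["total_steps"],
            rtol=1e-5,
        )

    def test_duplicate_participant_day_rejected(self, tmp_path, tiny_cohort):
        write_cohort(tiny_cohort, tmp_path / "c")
        daily = pd.read_csv(tmp_path / "c" / "daily.csv")
        pd.concat([daily, daily.iloc[[0]]]).to_csv(
            tmp_path / "c" / "daily.csv", index=False
        )
        with pytest.raises(CohortParseError, match="duplicate participant-day"):
            read_cohort(tmp_path / "c")

    def test_day_out_of_range_rejected(self, tmp_path, tiny_cohort):
        write_cohort(tiny_cohort, tmp_path / "c")
        daily = pd.read_csv(tmp_path / "c" / "daily.csv")
        daily.loc[0, "day"] = 0
        daily.to_csv(tmp_path / "c" / "daily.csv", index=False)
        with pytest.raises(CohortParseError, match="out of range"):
            read_cohort(tmp_path / "c")

    def test_non_integer_mood_rejected(self, tmp_path, tiny_cohort):
        write_cohort(tiny_cohort, tmp_path / "c")
        daily = pd.read_csv(tmp_path / "c" / "daily.csv")
        daily["mood"] = daily["mood"].astype(float)
        daily.loc[1, "mood"] = 5.5
        daily.to_csv(tmp_path / "c" / "daily.csv", index=False)
        with pytest.raises(CohortParseError, match="non-integer mood"):
            read_cohort(tmp_path / "c")

    def test_missing_file_error(self, tmp_path):
        with pytest.raises(CohortParseError, match="not found"):
            read_cohort(tmp_path)
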