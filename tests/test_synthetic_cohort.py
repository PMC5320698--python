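import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit, logit

from wmhtrial.exceptions import (
    CalibrationError,
    ConfigurationError,
    DataError,
    DomainError,
)
from wmhtrial.synthetic_cohort import (
    COHORT_COLUMNS,
    FAZEKAS_TARGET_PROPORTIONS,
    GeneratorConfig,
    apply_dropout,
    assign_fazekas,
    calibrate_cutpoints,
    expected_category_probs,
    generate_cohort,
    generate_full_cohort,
    lognormal_params_from_moments,
    read_cohort_csv,
    simulate_followup,
    validate_config,
    write_cohort_csv,
)
from conftest import manual_config


class TestConfig:
    def test_lognormal_moment_matching(self):
        mu, sigma = lognormal_params_from_moments(22.0, 24.8)
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(22.0)
        var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        assert math.sqrt(var) == pytest.approx(24.8)

    @pytest.mark.parametrize(
        "overrides,field",
        [
            (dict(age_sd=0.0), "age_sd"),
            (dict(prev_diabetes=1.5), "prev_diabetes"),
            (dict(map_pp_corr=2.0), "map_pp_corr"),
            (dict(faz_cutpoints=(1.0, 0.5, 2, 3, 4, 5)), "faz_cutpoints"),
            (dict(prog_coefs={"baseline_volume": 1.0}), "prog_coefs"),
        ],
    )
    def test_invalid_configs_name_offending_field(self, overrides, field):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            validate_config(GeneratorConfig(**overrides))

    def test_uncalibrated_config_rejected_for_generation(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(GeneratorConfig(n_patients=10))


class TestCutpointCalibration:
    def test_zero_slope_gives_logit_quantiles(self):
        targets = (0.1, 0.2, 0.3, 0.1, 0.1, 0.1, 0.1)
        cuts = calibrate_cutpoints(2.68, 0.91, 0.0, targets)
        expected = logit(np.cumsum(targets)[:-1])
        assert np.allclose(cuts, expected, atol=1e-8)

    def test_reference_targets_give_increasing_cutpoints(self):
        cuts = calibrate_cutpoints(2.681, 0.906, math.log(1.21), FAZEKAS_TARGET_PROPORTIONS)
        assert len(cuts) == 6
        assert np.all(np.diff(cuts) > 0)

    def test_calibrated_marginals_match_targets(self):
        # oracle: numerical integration of the ordered-logit probabilities
        # over the lognormal volume distribution
        cuts = calibrate_cutpoints(2.681, 0.906, math.log(1.21), FAZEKAS_TARGET_PROPORTIONS)
        probs = expected_category_probs(cuts, math.log(1.21), 2.681, 0.906)
        targets = np.asarray(FAZEKAS_TARGET_PROPORTIONS, dtype=float)
        assert np.allclose(probs, targets / targets.sum(), atol=1e-7)

    @given(
        raw=st.lists(st.floats(0.02, 1.0), min_size=7, max_size=7),
        slope=st.floats(0.0, 0.3),
    )
    def test_round_trip_for_random_targets(self, raw, slope):
        targets = np.asarray(raw) / sum(raw)
        cuts = calibrate_cutpoints(2.681, 0.906, slope, targets)
        probs = expected_category_probs(cuts, slope, 2.681, 0.906)
        assert np.allclose(probs, targets, atol=1e-6)

    def test_bad_targets_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_cutpoints(2.681, 0.906, 0.1, (0.5, 0.5, 0, 0, 0, 0, 0))


class TestAssignFazekas:
    def test_negative_volume_rejected(self):
        with pytest.raises(DomainError):
            assign_fazekas(-1.0, manual_config(), 0.5)

    def test_tiny_volume_with_high_cutpoints_gives_category_zero(self):
        config = manual_config(faz_cutpoints=(30.0, 31, 32, 33, 34, 35))
        cats = assign_fazekas(np.zeros(100), config, np.linspace(0.001, 0.999, 100))
        assert np.all(cats == 0)

    def test_monotone_in_volume_for_fixed_noise(self):
        config = manual_config()
        volumes = np.linspace(0, 120, 200)
        cats = assign_fazekas(volumes, config, np.full(200, 0.5))
        assert np.all(np.diff(cats) >= 0)

    def test_marginals_match_quadrature_oracle(self, calibrated_config, big_cohort):
        observed = (
            big_cohort["baseline"].data["fazekas_baseline"].value_counts(normalize=True)
            .reindex(range(7), fill_value=0.0)
            .to_numpy()
        )
        expected = expected_category_probs(
            calibrated_config.faz_cutpoints,
            calibrated_config.faz_slope,
            calibrated_config.vol_log_mean,
            calibrated_config.vol_log_sd,
        )
        assert np.all(np.abs(observed - expected) < 0.02)


class TestGenerateCohort:
    def test_empty_cohort(self):
        table = generate_cohort(manual_config(n_patients=0))
        assert len(table) == 0
        assert list(table.data.columns) == COHORT_COLUMNS

    def test_seeded_determinism_is_bitwise(self):
        config = manual_config(n_patients=500, seed=42)
        a = generate_full_cohort(config)
        b = generate_full_cohort(config)
        pd.testing.assert_frame_equal(a.data, b.data, check_exact=True)

    def test_different_seeds_differ(self):
        a = generate_cohort(manual_config(n_patients=100, seed=1))
        b = generate_cohort(manual_config(n_patients=100, seed=2))
        assert not a.data["wmh_baseline"].equals(b.data["wmh_baseline"])

    def test_baseline_volume_moments(self, big_cohort):
        vol = big_cohort["baseline"].data["wmh_baseline"]
        assert vol.mean() == pytest.approx(22.0, rel=0.02)
        assert vol.std() == pytest.approx(24.8, rel=0.02)
        assert (vol >= 0).all()

    def test_blood_pressure_identities(self, big_cohort):
        d = big_cohort["baseline"].data
        assert np.allclose(d["sbp"], d["map"] + 2 * d["pp"] / 3)
        assert np.allclose(d["dbp"], d["map"] - d["pp"] / 3)
        assert (d["sbp"] > d["dbp"]).all()  # pp forced positive

    def test_covariate_prevalences(self, big_cohort):
        d = big_cohort["baseline"].data
        for col, target in [
            ("hypertension", 0.747),
            ("subtype", 0.458),
            ("smoker", 0.384),
            ("diabetes", 0.111),
            ("hyperlipidaemia", 0.611),
        ]:
            assert d[col].mean() == pytest.approx(target, abs=0.01)


class TestFollowup:
    def test_degenerate_model_is_exact(self):
        config = manual_config(
            n_patients=50,
            prog_coefs={k: 0.0 for k in manual_config().prog_coefs},
            prog_intercept=5.0,
            resid_sd=0.0,
        )
        table = simulate_followup(generate_cohort(config))
        assert (table.data["wmh_followup"] == 5.0).all()

    def test_missing_baseline_rejected(self):
        table = generate_cohort(manual_config(n_patients=10))
        table.data.loc[3, "wmh_baseline"] = np.nan
        with pytest.raises(DataError, match="3"):
            simulate_followup(table)

    def test_followup_nonnegative(self, big_cohort):
        assert (big_cohort["pre_dropout"].data["wmh_followup"] >= 0).all()

    def test_scores_may_regress(self, big_cohort):
        d = big_cohort["pre_dropout"].data
        assert (d["fazekas_followup"] < d["fazekas_baseline"]).any()

    def test_calibrated_progression_and_variability(self, big_cohort):
        d = big_cohort["pre_dropout"].data
        change = d["wmh_followup"] - d["wmh_baseline"]
        assert change.mean() == pytest.approx(1.27, abs=0.12)
        assert d["wmh_followup"].std() == pytest.approx(23.3, rel=0.05)


class TestDropout:
    def test_plain_28_percent_rate(self):
        config = manual_config(n_patients=50_000, seed=9)  # coefs 0, logit(0.28)
        table = apply_dropout(simulate_followup(generate_cohort(config)))
        assert table.data["dropout"].mean() == pytest.approx(0.28, abs=0.01)

    def test_extreme_negative_intercept_gives_no_dropouts(self):
        config = manual_config(n_patients=2000, dropout_intercept=-50.0)
        table = apply_dropout(simulate_followup(generate_cohort(config)))
        assert table.data["dropout"].sum() == 0

    def test_dropout_blanks_exactly_the_followup_fields(self, big_cohort):
        d = big_cohort["final"].data
        dropped = d["dropout"] == 1
        assert d.loc[dropped, "wmh_followup"].isna().all()
        assert d.loc[dropped, "fazekas_followup"].isna().all()
        assert d.loc[~dropped, "wmh_followup"].notna().all()
        assert (d.loc[~dropped, "dropout_reason"] == "none").all()
        assert (d.loc[dropped, "dropout_reason"] != "none").all()
        assert d.loc[dropped, "wmh_baseline"].notna().all()

    def test_calibrated_rate_and_age_gap(self, big_cohort):
        table = big_cohort["final"]
        assert table.data["dropout"].mean() == pytest.approx(0.28, abs=0.015)
        gap = table.completers()["age"].mean() - table.non_completers()["age"].mean()
        assert gap == pytest.approx(-5.7, abs=0.5)

    def test_reason_frequencies(self, big_cohort):
        reasons = big_cohort["final"].non_completers()["dropout_reason"]
        freq = reasons.value_counts(normalize=True)
        assert freq["declined"] == pytest.approx(33 / 74, abs=0.02)
        assert freq["unwell"] == pytest.approx(24 / 74, abs=0.02)


def test_csv_round_trip(tmp_path):
    table = generate_full_cohort(manual_config(n_patients=200, seed=3))
    path = tmp_path / "cohort.csv"
    write_cohort_csv(table, path)
    back = read_cohort_csv(path)
    pd.testing.assert_frame_equal(
        back.data, table.data, check_exact=False, rtol=0, atol=1e-12
    )
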