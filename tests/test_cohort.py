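"""Synthetic-cohort generator: validation, determinism, moments, missingness."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import fabwork
from fabwork import tables
from fabwork.cohort import (
    CohortConfig,
    MissingnessParams,
    OutcomeParams,
    apply_missingness,
    generate_cohort,
    reduced_config,
    sample_fab_trajectory,
    sample_medical_counts,
)


class TestConfigValidation:
    def test_arm_probabilities_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="arm_probabilities"):
            CohortConfig(arm_probabilities=(0.5, 0.4, 0.2))

    def test_pattern_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="pattern_weights"):
            CohortConfig(
                missingness_params=MissingnessParams(
                    pattern_weights=(0.5, 0.2, 0.2, 0.2)
                )
            )

    def test_negative_participants_rejected(self):
        with pytest.raises(ValidationError):
            CohortConfig(n_participants=0)

    def test_sd_must_be_positive(self):
        bad = {
            name: dict(baseline=spec["baseline"], change=tuple(spec["change"]))
            for name, spec in tables.FAB_SCALES.items()
        }
        bad["mood_emotions"] = dict(baseline=(38.6, 0.0), change=bad["mood_emotions"]["change"])
        with pytest.raises(ValidationError, match="SD"):
            CohortConfig(scale_params=bad)

    def test_unknown_outcome_coefficient_rejected_at_generation(self):
        cfg = reduced_config(50, coefficients={"not_a_column": 1.0})
        with pytest.raises(ValueError, match="not_a_column"):
            generate_cohort(cfg)


class TestDeterminismAndShape:
    def test_same_seed_gives_identical_panel(self):
        a = generate_cohort(reduced_config(120, seed=5))
        b = generate_cohort(reduced_config(120, seed=5))
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self):
        a = generate_cohort(reduced_config(120, seed=5))
        b = generate_cohort(reduced_config(120, seed=6))
        assert not a.data.equals(b.data)

    def test_participant_count_and_rows(self, small_panel, small_config):
        assert small_panel.n_participants == small_config.n_participants
        assert len(small_panel.data) == small_config.n_participants * small_config.n_years
        # exactly one row per (participant, year)
        assert not small_panel.data.duplicated(["participant_id", "year"]).any()

    def test_demographics_constant_within_participant(self, small_panel):
        grouped = small_panel.data.groupby("participant_id")[
            list(small_panel.demographic_columns)
        ].nunique()
        assert (grouped == 1).all().all()

    def test_outcome_absent_at_baseline_only(self, small_panel):
        d = small_panel.data
        assert d.loc[d.year == 0, "steady_work"].isna().all()
        assert d.loc[d.year > 0, "steady_work"].isin([0.0, 1.0]).all()


class TestOutcomeMechanism:
    def test_zero_coefficients_zero_intercept_gives_half(self):
        cfg = reduced_config(
            800, seed=2, outcome_params=OutcomeParams(intercept=0.0, coefficients={})
        )
        panel = generate_cohort(cfg)
        rate = panel.data.query("year > 0").steady_work.mean()
        n = 3 * 800
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_intercept_logit_prevalence(self):
        from scipy.special import logit

        cfg = reduced_config(
            1500,
            seed=3,
            outcome_params=OutcomeParams(intercept=float(logit(0.173)), coefficients={}),
        )
        panel = generate_cohort(cfg)
        rate = panel.data.query("year > 0").steady_work.mean()
        n = 3 * 1500
        assert abs(rate - 0.173) < 3 * np.sqrt(0.173 * 0.827 / n)

    def test_calibrated_intercepts_hit_yearly_targets(self):
        # calibration is a deterministic function of the configuration
        cfg = reduced_config(2000, seed=4)
        i1 = fabwork.calibrated_intercepts(cfg)
        i2 = fabwork.calibrated_intercepts(reduced_config(2000, seed=99))
        np.testing.assert_allclose(i1, i2)  # seed-independent
        panel = generate_cohort(cfg)
        d = panel.data
        for t, target in zip((1, 2, 3), cfg.outcome_params.target_rates):
            rate = d[d.year == t].steady_work.mean()
            assert abs(rate - target) < 3 * np.sqrt(target * (1 - target) / 2000)


class TestTrajectoriesAndCounts:
    def test_zero_change_sd_is_deterministic_shift(self):
        params = {
            name: dict(
                baseline=spec["baseline"],
                change=tuple((m, 0.0) for m, _ in spec["change"]),
            )
            for name, spec in tables.FAB_SCALES.items()
        }
        cfg = reduced_config(40, seed=1, scale_params=params)
        rng = np.random.default_rng(0)
        fab = sample_fab_trajectory(cfg, rng, n=40)
        for j, name in enumerate(cfg.fab_scales):
            for t in range(1, cfg.n_years):
                mean_t = cfg.scale_params[name].change[t - 1][0]
                np.testing.assert_allclose(fab[:, t, j], fab[:, 0, j] + mean_t)

    def test_zero_mean_count_is_all_zero(self):
        mp = {"total_er_visits": dict(kind="count", by_year=((0.0, 0.0),) * 4)}
        cfg = reduced_config(60, seed=1, medical_subset=("total_er_visits",))
        cfg = cfg.model_copy(update={"medical_params": {
            "total_er_visits": cfg.medical_params["total_er_visits"].model_copy(
                update={"by_year": ((0.0, 0.0),) * 4})}})
        rng = np.random.default_rng(0)
        med = sample_medical_counts(cfg, rng, n=60)
        assert (med == 0).all()

    def test_underdispersed_count_falls_back_to_poisson(self, caplog):
        cfg = reduced_config(200, seed=1)
        cfg = cfg.model_copy(update={"medical_params": {
            "total_er_visits": cfg.medical_params["total_er_visits"].model_copy(
                update={"by_year": ((2.0, 1.0),) * 4})}})
        import logging

        with caplog.at_level(logging.WARNING, logger="fabwork.cohort"):
            med = sample_medical_counts(cfg, np.random.default_rng(0), n=200)
        assert "Poisson" in caplog.text
        assert abs(med[:, 0, 0].mean() - 2.0) < 3 * np.sqrt(2.0 / 200)

    def test_moment_calibration_large_sample(self):
        """Published-moment anchors at n=10,000 (3 SE bands)."""
        cfg = fabwork.default_config(n_participants=10_000, seed=12)
        panel = generate_cohort(cfg).unmask()
        d = panel.data
        base = d[d.year == 0]
        n = len(base)

        def band(target, sd):
            return 3 * sd / np.sqrt(n)

        assert abs(base.fab_mood_emotions.mean() - 38.6) < band(38.6, 12.0)
        assert abs(base.med_csi.mean() - 25.2) < band(25.2, 11.2)
        assert abs(base.med_bmi.mean() - 31.1) < band(31.1, 8.9)
        assert abs(base.med_total_er_visits.mean() - 1.2) < band(1.2, 1.9)
        # year-2 change in Communication & Cognition: mean 0.7 (SD 7.0)
        y2 = d[d.year == 2].set_index("participant_id")
        change = y2.fab_comm_cog - base.set_index("participant_id").fab_comm_cog
        assert abs(change.mean() - 0.7) < 3 * 7.0 / np.sqrt(len(change))
        # baseline Resilience SD within 5% of 9.6
        assert abs(base.fab_resilience.std(ddof=1) - 9.6) / 9.6 < 0.05
        # Drive-score presence pools to ~0.40
        assert abs(d.has_drive.mean() - 0.40) < 3 * np.sqrt(0.4 * 0.6 / len(d))


class TestMissingness:
    def test_no_missing_when_weight_on_zero_pattern(self):
        cfg = reduced_config(
            100, seed=2,
            missingness_params=MissingnessParams(pattern_weights=(1.0, 0.0, 0.0, 0.0)),
        )
        panel = generate_cohort(cfg)
        assert panel.data[list(panel.fab_columns)].notna().all().all()

    def test_missing_counts_are_multiples_of_seven(self, small_panel):
        counts = small_panel.missing_counts()
        assert set(counts.unique()) <= {0, 7, 14, 21}

    def test_pattern_fractions_match_weights(self):
        weights = (0.4, 0.3, 0.2, 0.1)
        cfg = reduced_config(
            4000, seed=9,
            missingness_params=MissingnessParams(pattern_weights=weights),
        )
        counts = generate_cohort(cfg).missing_counts()
        frac_21 = (counts > 14).mean()
        assert abs(frac_21 - weights[3]) < 3 * np.sqrt(weights[3] * 0.9 / 4000)
        for k, w in zip((0, 7, 14, 21), weights):
            assert abs((counts == k).mean() - w) < 3 * np.sqrt(w * (1 - w) / 4000) + 1e-9

    def test_blanking_is_whole_wave(self, small_panel):
        fab = small_panel.data[list(small_panel.fab_columns)]
        n_missing_per_row = fab.isna().sum(axis=1)
        assert set(n_missing_per_row.unique()) <= {0, len(small_panel.fab_columns)}
        # baseline rows never blanked
        assert n_missing_per_row[small_panel.data.year == 0].eq(0).all()

    def test_truth_channel_roundtrip(self, small_panel):
        restored = small_panel.unmask()
        assert restored.data[list(small_panel.fab_columns)].notna().all().all()
        masked_cells = small_panel.data[list(small_panel.fab_columns)].isna()
        assert masked_cells.to_numpy().sum() > 0
        np.testing.assert_array_equal(
            restored.data[list(small_panel.fab_columns)].to_numpy(),
            small_panel.truth[list(small_panel.fab_columns)].to_numpy(),
        )

    def test_apply_missingness_requires_weights_summing_to_one(self, small_panel):
        cfg = small_panel.config
        object.__setattr__  # noqa: B018 - frozen models need copies
        bad = cfg.model_copy(
            update={
                "missingness_params": MissingnessParams.model_construct(
                    pattern_weights=(0.5, 0.2, 0.2, 0.2),
                    presence_rates=dict(tables.PRESENCE_RATES_BY_YEAR),
                )
            }
        )
        with pytest.raises(ValueError, match="sum to 1"):
            apply_missingness(small_panel.unmask(), bad)


class TestPersistence:
    @pytest.mark.parametrize("fmt", ["parquet", "csv"])
    def test_save_load_roundtrip(self, small_panel, tmp_path, fmt):
        files = small_panel.save(tmp_path / f"panel.{fmt}", format=fmt)
        loaded = fabwork.PanelDataset.load(files["panel"])
        assert loaded.fab_columns == small_panel.fab_columns
        np.testing.assert_allclose(
            loaded.data[list(loaded.fab_columns)].to_numpy(),
            small_panel.data[list(small_panel.fab_columns)].to_numpy(),
        )
        assert loaded.config is not None
        assert loaded.config.n_participants == small_panel.config.n_participants
        assert files["mask"].exists() and files["truth"].exists()
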