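"""Generator contracts: counts, determinism, noiseless limits, regimes."""

import numpy as np
import pandas as pd
import pytest

from ppsbayes import (
    DELAY_LOOKUP_S,
    DesignConfig,
    EffectConfig,
    bell_profile,
    distance_to_delay,
    generate_dataset,
    generate_under_hypothesis,
    read_trials_csv,
    step_profile,
    write_trials_csv,
)
from ppsbayes.synthetic_data import ConfigurationError, draw_subject_effects


class TestDistanceToDelay:
    @pytest.mark.parametrize(
        "cm,expected",
        [(147, 1.531), (98, 3.063), (196, 0.0)],
    )
    def test_kinematic_delays(self, cm, expected):
        # printed to three decimals, so agreement to half a millisecond
        assert distance_to_delay(cm, 32, 196) == pytest.approx(expected, abs=5.01e-4)

    def test_invalid_speed_and_range(self):
        with pytest.raises(ValueError):
            distance_to_delay(50, 0)
        with pytest.raises(ValueError):
            distance_to_delay(-1, 32)
        with pytest.raises(ValueError):
            distance_to_delay(500, 32, 196)

    def test_canonical_lookup_kept_verbatim(self):
        # the apparatus table is authoritative even where it deviates from
        # the kinematic formula (D1, D2)
        assert DELAY_LOOKUP_S["D1"] == 6.125
        assert DELAY_LOOKUP_S["D2"] == 4.564
        assert DELAY_LOOKUP_S["D4"] == pytest.approx(distance_to_delay(147, 32, 196), abs=5e-4)


class TestCounts:
    def test_default_design_trial_count(self, default_design, clean_effects):
        trials = generate_dataset(default_design, clean_effects, seed=0)
        assert len(trials) == 40 * 9 * 48
        per_cond = trials.groupby(
            ["participant", "light_location", "tactile_location"]
        ).size()
        assert (per_cond == 48).all()
        by_type = trials.groupby("trial_type").size()
        assert by_type["VT"] == 40 * 9 * 30
        assert by_type["TO"] == 40 * 9 * 15
        assert by_type["catch"] == 40 * 9 * 3

    def test_degenerate_design_is_empty(self):
        design = DesignConfig(
            n_participants=3, reps_vt_per_distance=0, reps_to_per_distance=0, n_catch=0
        )
        trials = generate_dataset(design, EffectConfig(), seed=0)
        assert trials.empty
        assert list(trials.columns) == [
            "participant",
            "light_location",
            "tactile_location",
            "trial_type",
            "distance",
            "rt_ms",
            "responded",
        ]

    def test_count_conservation_property(self, rng):
        design = DesignConfig(n_participants=2, reps_vt_per_distance=4, reps_to_per_distance=2, n_catch=1)
        trials = generate_dataset(design, EffectConfig(), seed=5)
        per_cond = trials.groupby(["participant", "light_location", "tactile_location"]).size()
        assert (per_cond == 5 * 4 + 5 * 2 + 1).all()


class TestDeterminismAndNoise:
    def test_identical_seed_identical_table(self, small_design, default_effects):
        a = generate_dataset(small_design, default_effects, seed=42)
        b = generate_dataset(small_design, default_effects, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, small_design, default_effects):
        a = generate_dataset(small_design, default_effects, seed=1)
        b = generate_dataset(small_design, default_effects, seed=2)
        assert not a["rt_ms"].equals(b["rt_ms"])

    def test_noiseless_limit_exact(self):
        effects = EffectConfig(
            grand_mean=300.0,
            delay_profile={},
            distance_profile={},
            subject_sd=0.0,
            random_effect_sd=0.0,
            residual_sd=0.0,
            outlier_rate=0.0,
            miss_rate=0.0,
            catch_fa_rate=0.0,
        )
        trials = generate_dataset(DesignConfig(n_participants=2), effects, seed=0)
        rt = trials.loc[trials["trial_type"] != "catch", "rt_ms"]
        assert (rt == 300.0).all()

    def test_noiseless_profiles_reproduced_exactly(self):
        prof = step_profile(("face", "hand", "foot"), boundary_after="D2", step=30.0)
        bell = bell_profile(amplitude=20.0)
        effects = EffectConfig(
            grand_mean=350.0,
            delay_profile=bell,
            distance_profile=prof,
            subject_sd=0.0,
            random_effect_sd=0.0,
            residual_sd=0.0,
            outlier_rate=0.0,
            miss_rate=0.0,
        )
        trials = generate_dataset(DesignConfig(n_participants=1), effects, seed=0)
        vt = trials[trials["trial_type"] == "VT"]
        for (light, d), grp in vt.groupby(["light_location", "distance"]):
            assert (grp["rt_ms"] == 350.0 + prof[(light, d)]).all()
        to = trials[trials["trial_type"] == "TO"]
        for d, grp in to.groupby("distance"):
            assert grp["rt_ms"].to_numpy() == pytest.approx(350.0 + bell[d])


class TestHypothesisRegimes:
    def test_h1_tactile_only_means_flat_across_delays(self, default_design):
        effects = EffectConfig(outlier_rate=0.0, miss_rate=0.0)
        trials = generate_under_hypothesis("H1", default_design, effects, seed=9)
        to = trials[(trials["trial_type"] == "TO") & trials["responded"]]
        means = to.groupby("distance")["rt_ms"].mean()
        sem = to.groupby("distance")["rt_ms"].sem()
        grand = to["rt_ms"].mean()
        assert (np.abs(means - grand) < 2.5 * sem).all()

    def test_h2_reproduces_configured_bell(self, default_design, clean_effects):
        trials = generate_under_hypothesis("H2", default_design, clean_effects, seed=11)
        to = trials[trials["trial_type"] == "TO"]
        bell = clean_effects.delay_profile
        # subject effects are shared across delays, so compare within-subject
        # demeaned values to the demeaned configured profile
        per = to.groupby(["participant", "distance"])["rt_ms"].mean().unstack()
        demeaned = per.sub(per.mean(axis=1), axis=0)
        target = pd.Series(bell) - np.mean(list(bell.values()))
        for d in per.columns:
            se = demeaned[d].std() / np.sqrt(len(demeaned))
            assert abs(demeaned[d].mean() - target[d]) < 2 * se + 0.5

    def test_h0_tactile_only_matches_visuotactile_cells(self, clean_effects):
        design = DesignConfig(n_participants=40)
        trials = generate_under_hypothesis("H0", design, clean_effects, seed=12)
        rt = trials[trials["trial_type"] != "catch"]
        cell = rt.groupby(["trial_type", "light_location", "distance"])["rt_ms"].agg(["mean", "sem"])
        vt, to = cell.loc["VT"], cell.loc["TO"]
        z = (vt["mean"] - to["mean"]) / np.sqrt(vt["sem"] ** 2 + to["sem"] ** 2)
        assert (z.abs() < 3).all()

    def test_unknown_hypothesis_rejected(self, small_design, default_effects):
        with pytest.raises(ValueError, match="unknown hypothesis"):
            generate_under_hypothesis("H3", small_design, default_effects, seed=0)


class TestSubjectEffectCovariance:
    def test_empirical_covariance_converges(self, default_design, default_effects, rng):
        raw, _ = draw_subject_effects(2000, default_design, default_effects, rng)
        emp = np.cov(raw.T)
        expected = np.eye(5) * default_effects.random_effect_sd**2
        expected[0, 0] = default_effects.subject_sd**2
        rel = np.abs(np.diag(emp) - np.diag(expected)) / np.diag(expected)
        assert rel.max() < 0.15
        corr = emp / np.sqrt(np.outer(np.diag(emp), np.diag(emp)))
        off = corr - np.eye(5)
        assert np.abs(off).max() < 0.1  # generated uncorrelated


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            DesignConfig(n_participants=-1)
        with pytest.raises(ConfigurationError):
            DesignConfig(distances=("D1", "DX"))
        with pytest.raises(ConfigurationError):
            EffectConfig(outlier_rate=1.5)
        with pytest.raises(ConfigurationError):
            EffectConfig(residual_sd=-1)
        with pytest.raises(ConfigurationError):
            generate_dataset(DesignConfig(n_participants=0), EffectConfig(), seed=0)
        with pytest.raises(ConfigurationError):
            generate_dataset(
                DesignConfig(n_participants=1),
                EffectConfig(delay_profile={"D9": 1.0}),
                seed=0,
            )

    def test_asymmetric_covariance_rejected(self):
        bad = np.eye(5)
        bad[0, 1] = 3.0
        with pytest.raises(ConfigurationError, match="symmetric"):
            EffectConfig(random_effect_cov=bad)


class TestRoundTrip:
    def test_csv_round_trip(self, tmp_path, small_design, default_effects):
        trials = generate_dataset(small_design, default_effects, seed=3)
        path = tmp_path / "trials.csv"
        write_trials_csv(trials, path, seed=3)
        back = read_trials_csv(path)
        assert len(back) == len(trials)
        assert back["responded"].equals(trials["responded"])
        np.testing.assert_allclose(
            back["rt_ms"].to_numpy(), trials["rt_ms"].to_numpy(), rtol=0, atol=1e-9
        )
        assert (path.parent / "trials.csv.meta.json").exists()
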