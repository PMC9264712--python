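"""Synthetic survey generator: determinism, calibration, closed forms."""

import numpy as np
import pandas as pd
import pytest

from equicost.pipeline import cost_summary, stratified_equity_table
from equicost.synthetic import (GeneratorConfig, OutcomeSpec, closed_form_ci,
                                closed_form_gap, default_config,
                                generate_survey)
from equicost.wealth import RankedSample, fractional_ranks
from equicost.inequality import concentration_index


class TestClosedForms:
    def test_travel_time_defaults(self):
        assert closed_form_ci(40.0, -20.0) == pytest.approx(-1 / 9)

    def test_no_gradient_is_zero(self):
        assert closed_form_ci(12.9, 0.0) == 0.0

    def test_sign_symmetry(self):
        assert closed_form_ci(20.0, 20.0) == pytest.approx(1 / 9)
        assert closed_form_ci(20.0, 20.0) == pytest.approx(
            -closed_form_ci(40.0, -20.0))

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError, match="positive"):
            closed_form_ci(10.0, -20.0)

    def test_extreme_quintile_gap(self):
        assert closed_form_gap(-20.0) == pytest.approx(16.0)

    def test_closed_form_matches_direct_evaluation(self):
        """Oracle: evaluate CI = 2 cov(a + bR, R)/mu on a dense rank grid."""
        a, b = 40.0, -20.0
        r = (np.arange(200000) + 0.5) / 200000
        y = a + b * r
        ci = concentration_index(RankedSample(values=y, ranks=r))
        assert ci == pytest.approx(closed_form_ci(a, b), abs=1e-6)


class TestValidation:
    def test_invalid_configs_fail_before_draws(self):
        with pytest.raises(ValueError, match="10 patients"):
            generate_survey(default_config(1, n_patients=2000,
                                           n_facilities=100))
        with pytest.raises(ValueError, match="outside"):
            generate_survey(default_config(1, public_share=1.5))
        bad = default_config(1)
        bad = GeneratorConfig(seed=1, outcomes={
            **bad.outcomes,
            "travel_time_min": OutcomeSpec(10.0, -20.0),  # mean hits zero
        })
        with pytest.raises(ValueError, match="positive"):
            generate_survey(bad)


class TestGeneration:
    def test_same_seed_is_byte_identical(self):
        cfg = default_config(99, n_patients=300, n_facilities=40)
        a = generate_survey(cfg)
        b = generate_survey(cfg)
        assert a.df.to_csv(index=False) == b.df.to_csv(index=False)

    def test_different_seed_differs(self):
        a = generate_survey(default_config(1, n_patients=300, n_facilities=40))
        b = generate_survey(default_config(2, n_patients=300, n_facilities=40))
        assert not a.df["travel_time_min"].equals(b.df["travel_time_min"])

    def test_all_foot_forces_zero_transport(self):
        cfg = default_config(7, n_patients=400, n_facilities=50,
                             mode_targets=(1.0, 0.0, 0.0))
        ds = generate_survey(cfg)
        assert (ds.df["travel_mode"] == "foot").all()
        paid = ds.df["transport_cost_tzs"].dropna()
        assert (paid == 0).all()

    def test_foot_share_hits_configured_target(self):
        ds = generate_survey(default_config(3, n_patients=10000,
                                            n_facilities=1000))
        share = (ds.df["travel_mode"] == "foot").mean()
        target = 0.711 / (0.711 + 0.085 + 0.205)
        assert share == pytest.approx(target,
                                      abs=4 * np.sqrt(target * (1 - target)
                                                      / 10000))

    def test_marginal_shares_and_placement(self, synth_dataset):
        df = synth_dataset.df
        n = len(df)
        assert df.groupby("facility_id").size().max() <= 10
        rural = (df["residence"] == "rural").mean()
        assert rural == pytest.approx(0.828, abs=4 * np.sqrt(0.828 * 0.172 / n))
        pay_med = (df["medical_cost_tzs"].dropna() > 0).mean()
        assert pay_med == pytest.approx(0.178,
                                        abs=4 * np.sqrt(0.178 * 0.822 / n))

    def test_outcome_means_match_a_plus_half_b(self, synth_dataset):
        for outcome, a, b in [("travel_time_min", 40.0, -20.0),
                              ("waiting_time_min", 56.2, -19.0),
                              ("consultation_time_min", 12.9, 0.0)]:
            s = cost_summary(synth_dataset, outcome)
            expected = a + b / 2
            # gamma k=2: sd = mean/sqrt(2); conservative 4-sigma band
            assert s.mean == pytest.approx(
                expected, abs=4 * expected / np.sqrt(2 * s.n))

    def test_missing_rates_within_binomial_error(self, synth_dataset):
        df = synth_dataset.df
        n = len(df)
        for col, rate in [("travel_time_min", 0.188),
                          ("transport_cost_tzs", 0.077),
                          ("medical_cost_tzs", 0.006)]:
            observed = df[col].isna().mean()
            assert observed == pytest.approx(
                rate, abs=4 * np.sqrt(rate * (1 - rate) / n) + 1e-9)

    def test_ground_truth_sidecar(self, synth):
        ds, truth, params = synth
        assert list(truth.columns) == ["patient_id", "latent_wealth",
                                       "true_rank"]
        assert truth["true_rank"].mean() == pytest.approx(0.5, abs=1e-12)
        pd.testing.assert_series_equal(truth["patient_id"],
                                       ds.df["patient_id"],
                                       check_names=False)
        travel = params.set_index("outcome").loc["travel_time_min"]
        assert travel["ci_infinity"] == pytest.approx(-1 / 9)
        assert travel["gap_infinity"] == pytest.approx(16.0)

    def test_medical_ci_unbiased_against_true_rank_oracle(self):
        """Zero-inflated medical cost: CI over seeds centres on the closed
        form when evaluated with the generator's own (true) ranks."""
        devs = []
        for seed in range(8):
            ds, truth, _ = generate_survey(
                default_config(seed, n_patients=6000, n_facilities=600),
                return_truth=True)
            mask = ds.df["medical_cost_tzs"].notna().to_numpy()
            vals = ds.df["medical_cost_tzs"].to_numpy(float)[mask]
            ranks = fractional_ranks(truth["latent_wealth"].to_numpy()[mask])
            ci = concentration_index(RankedSample(values=vals, ranks=ranks))
            devs.append(ci - closed_form_ci(280.0, 3560.0))
        assert abs(float(np.mean(devs))) < 0.02
        assert all(ci_dev + closed_form_ci(280.0, 3560.0) > 0.15
                   for ci_dev in devs)  # clearly pro-rich in every draw

    def test_transport_ci_pro_rich_via_mode_zeros(self, synth_dataset):
        row = stratified_equity_table(synth_dataset, "transport_cost_usd",
                                      "ses_quintile_extremes").iloc[0]
        assert row["ci"] > 0.1
        assert row["gap"] < 0  # poorest pay less in absolute terms
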