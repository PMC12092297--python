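"""Synthetic cohort generator: determinism, planted structure, fixtures."""

import numpy as np
import pandas as pd
import pytest

from langmark.lexicon import build_feature_matrix, builtin_category_lexicons
from langmark.simulate import (
    SimConfig,
    read_fixture,
    simulate_bivariate_panel,
    simulate_cohort,
    simulate_items,
    write_fixture,
)

SMALL = dict(n_participants=25, seed=7)


class TestConfig:
    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SimConfig(n_participants=0).validate()

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            SimConfig(timepoints=(7, 7, 30)).validate()

    def test_non_pd_planted_structure_rejected(self):
        # one feature perfectly correlated with two domains is impossible
        cfg = SimConfig(
            planted_pairs=(
                ("negemo", "depression", 0.99, 0.1),
                ("negemo", "pain", 0.99, 0.1),
            )
        )
        with pytest.raises(ValueError, match="positive-definite"):
            cfg.validate()

    def test_out_of_range_rho_rejected(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            SimConfig(planted_pairs=(("negemo", "depression", 1.5, 0.1),)).validate()


class TestBivariatePanel:
    def test_determinism(self):
        a = simulate_bivariate_panel(20, 4, 0.3, 0.1, seed=7)
        b = simulate_bivariate_panel(20, 4, 0.3, 0.1, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_perfect_within_correlation_limit(self):
        # rho_w = 1, equal residual scales: person-centered deviations match
        panel = simulate_bivariate_panel(50, 6, 0.0, 1.0, seed=1)
        g = panel.groupby("participant_id")
        cs = panel["symptom"] - g["symptom"].transform("mean")
        cf = panel["marker"] - g["marker"].transform("mean")
        assert np.corrcoef(cs, cf)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_sample_correlations_converge_to_planted(self):
        panel = simulate_bivariate_panel(2000, 6, 0.30, 0.15, seed=3)
        g = panel.groupby("participant_id")
        means = g[["symptom", "marker"]].mean()
        # between-person correlation of participant means (noise-inflated
        # denominator is (1 + 1/J)-ish; correct for it analytically)
        r_b_raw = np.corrcoef(means["symptom"], means["marker"])[0, 1]
        J = 6
        atten = 1.0 / (1.0 + 1.0 / J)
        r_b = r_b_raw / atten  # both variables share the same inflation
        cs = panel["symptom"] - g["symptom"].transform("mean")
        cf = panel["marker"] - g["marker"].transform("mean")
        r_w = np.corrcoef(cs, cf)[0, 1]
        assert r_w == pytest.approx(0.15, abs=0.03)
        assert r_b == pytest.approx(0.30, abs=0.03)

    def test_missing_rate_applied(self):
        panel = simulate_bivariate_panel(500, 5, 0.2, 0.1, missing_rate=0.2, seed=5)
        assert panel["symptom"].isna().mean() == pytest.approx(0.2, abs=0.02)

    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError):
            simulate_bivariate_panel(0, 5, 0.2, 0.1, seed=1)


class TestCohort:
    def test_seed_determinism_byte_identical(self):
        t1 = simulate_cohort(SimConfig(**SMALL))
        t2 = simulate_cohort(SimConfig(**SMALL))
        for name in ("word_bags", "survey_items", "schedule", "completion"):
            assert getattr(t1, name).to_csv() == getattr(t2, name).to_csv()

    def test_word_bag_schema_invariants(self):
        bags = simulate_cohort(SimConfig(**SMALL)).word_bags
        assert (bags["count"] > 0).all()
        assert bags["count"].dtype.kind == "i"
        assert not bags.duplicated(["participant_id", "date", "word"]).any()
        assert (bags["word"].str.lower() == bags["word"]).all()

    def test_item_covariance_matches_one_factor_model(self):
        # items are loading * eta + noise, so their correlation matrix is
        # lambda lambda' V / sqrt(...) with V the pooled severity variance
        cfg = SimConfig(
            n_participants=700,
            missing_rate_survey=0.0,
            missing_rate_words=1.0,  # skip word generation for speed
            seed=11,
        )
        t = simulate_cohort(cfg)
        items = t.survey_items
        dom = items[items["item_id"].str.startswith("pain_")]
        wide = dom.pivot_table(
            index=["participant_id", "timepoint_day"],
            columns="item_id",
            values="value",
        ).dropna()
        R = wide.corr().to_numpy()
        lam = np.array(cfg.item_loadings)
        V = 2.0 + np.var(cfg.trend)  # intercept + occasion + spread of trend
        sd = np.sqrt(lam**2 * V + (1 - lam**2))
        expected = np.outer(lam, lam) * V / np.outer(sd, sd)
        np.fill_diagonal(expected, 1.0)
        assert np.abs(R - expected).max() < 0.05

    def test_planned_missingness_alternates_item_administration(self):
        t = simulate_cohort(SimConfig(n_participants=30, missing_rate_survey=0.0, seed=2))
        items = t.survey_items
        third = items[items["item_id"] == "pain_it3"]
        tps = np.asarray(SimConfig().timepoints)
        assert set(third["timepoint_day"]) == set(tps[::2])

    def test_mar_mode_links_missingness_to_severity(self):
        from langmark.preprocess import missingness_diagnostic
        from langmark.measurement import fit_domains, score_domains

        cfg = SimConfig(
            n_participants=300,
            missing_mode="mar",
            mar_strength=1.5,
            missing_rate_words=1.0,
            n_domains=2,
            planted_pairs=(("negemo", "depression", 0.3, 0.15),),
            seed=4,
        )
        t = simulate_cohort(cfg)
        models = fit_domains(t.survey_items)
        scores = score_domains(models, t.survey_items)
        table, flag = missingness_diagnostic(scores, t.completion)
        flash = table[table["activity"] == "flash_survey"]
        assert not flag
        assert (flash["r"] < -0.1).any()  # higher severity -> lower completion

    def test_truth_not_among_pipeline_inputs(self, tmp_path):
        t = simulate_cohort(SimConfig(**SMALL))
        paths = write_fixture(t, tmp_path)
        tables = read_fixture(tmp_path)
        assert "truth" not in tables
        assert all("truth" not in k for k in tables)


class TestFixtureIO:
    def test_round_trip_equality(self, tmp_path):
        t = simulate_cohort(SimConfig(**SMALL))
        write_fixture(t, tmp_path)
        back = read_fixture(tmp_path)
        for name in ("word_bags", "survey_items", "schedule", "device_log"):
            want = getattr(t, name).reset_index(drop=True)
            got = back[name]
            pd.testing.assert_frame_equal(got, want, check_dtype=False)

    def test_three_participants_distinct_ids(self, tmp_path):
        t = simulate_cohort(SimConfig(n_participants=3, seed=1))
        write_fixture(t, tmp_path)
        back = read_fixture(tmp_path)
        assert back["survey_items"]["participant_id"].nunique() == 3

    def test_empty_table_round_trips_with_header(self, tmp_path):
        t = simulate_cohort(SimConfig(n_participants=2, missing_rate_words=1.0, seed=1))
        assert len(t.word_bags) == 0
        write_fixture(t, tmp_path)
        back = read_fixture(tmp_path)
        assert list(back["word_bags"].columns) == [
            "participant_id", "date", "word", "count",
        ]
        assert len(back["word_bags"]) == 0

    def test_extraction_identical_from_memory_and_disk(self, tmp_path):
        t = simulate_cohort(SimConfig(**SMALL))
        write_fixture(t, tmp_path)
        back = read_fixture(tmp_path)
        lexes = builtin_category_lexicons()
        fm_mem = build_feature_matrix(t.word_bags, lexes)
        fm_disk = build_feature_matrix(back["word_bags"], lexes)
        pd.testing.assert_frame_equal(fm_mem, fm_disk)


class TestSimulateItems:
    def test_item_correlations_match_loadings(self):
        X, eta = simulate_items(4000, (0.8, 0.7, 0.6), seed=9)
        R = np.corrcoef(X.T)
        lam = np.array([0.8, 0.7, 0.6])
        expected = np.outer(lam, lam)
        np.fill_diagonal(expected, 1.0)
        assert np.abs(R - expected).max() < 0.04
        assert np.corrcoef(X @ lam, eta)[0, 1] > 0.8
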