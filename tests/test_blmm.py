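"""Bivariate mixed model: oracle equivalence, recovery, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from langmark.blmm import (
    BlmmParameters,
    PanelError,
    blmm_loglik,
    fit_blmm,
    fit_blmm_pairs,
    loglik_direct,
    lrt_rho,
)
from langmark.simulate import simulate_bivariate_panel


def random_params(seed):
    r = np.random.default_rng(seed)
    A = r.random((2, 2))
    B = r.random((2, 2))
    return BlmmParameters(
        mu_s=r.normal(),
        mu_f=r.normal(),
        D=A @ A.T + 0.3 * np.eye(2),
        Sigma=B @ B.T + 0.3 * np.eye(2),
    )


class TestLikelihood:
    def test_matches_dense_oracle_at_random_points(self):
        panel = simulate_bivariate_panel(30, 5, 0.3, 0.15, missing_rate=0.25, seed=1)
        for k in range(20):
            p = random_params(100 + k)
            assert blmm_loglik(p, panel) == pytest.approx(
                loglik_direct(p, panel), abs=1e-8
            )

    def test_single_row_closed_form(self):
        p = random_params(0)
        panel = pd.DataFrame(
            {
                "participant_id": ["a"],
                "timepoint_day": [0],
                "symptom": [0.4],
                "marker": [-0.3],
            }
        )
        expected = stats.multivariate_normal.logpdf(
            [0.4, -0.3], [p.mu_s, p.mu_f], p.D + p.Sigma
        )
        assert loglik_direct(p, panel) == pytest.approx(expected, abs=1e-12)
        assert blmm_loglik(p, panel) == pytest.approx(expected, abs=1e-10)

    def test_empty_panel_loglik_zero(self):
        p = random_params(1)
        empty = pd.DataFrame(
            columns=["participant_id", "timepoint_day", "symptom", "marker"]
        )
        assert loglik_direct(p, empty) == 0.0
        assert blmm_loglik(p, empty) == 0.0

    def test_invariance_to_relabeling_and_reordering(self):
        panel = simulate_bivariate_panel(20, 4, 0.2, 0.1, missing_rate=0.2, seed=2)
        p = random_params(3)
        base = blmm_loglik(p, panel)
        shuffled = panel.sample(frac=1, random_state=5)
        relabeled = shuffled.assign(
            participant_id=shuffled["participant_id"].map(lambda i: f"Z{i}")
        )
        assert blmm_loglik(p, relabeled) == pytest.approx(base, abs=1e-9)


class TestFit:
    def test_recovers_planted_correlations(self):
        panel = simulate_bivariate_panel(400, 8, 0.30, 0.15, missing_rate=0.2, seed=7)
        fit = fit_blmm(panel, n_starts=2)
        assert fit.converged
        assert fit.rho_b == pytest.approx(0.30, abs=0.08)
        assert fit.rho_w == pytest.approx(0.15, abs=0.05)
        assert fit.p_rho_w < 0.01

    def test_null_pair_small_estimates(self, null_panel):
        fit = fit_blmm(null_panel, n_starts=2)
        assert abs(fit.rho_b) < 0.35  # se ~ 0.13 at n=60
        assert abs(fit.rho_w) < 0.15

    def test_identical_series_hits_boundary(self):
        panel = simulate_bivariate_panel(30, 5, 0.3, 0.3, seed=4)
        panel["marker"] = panel["symptom"]
        fit = fit_blmm(panel, n_starts=1)
        assert fit.boundary
        assert fit.rho_w > 0.99
        assert np.isnan(fit.se_rho_w)

    def test_complete_balanced_matches_person_centered_correlations(self):
        # on complete balanced data the FIML within-correlation agrees with
        # the Pearson correlation of person-mean-centered values
        panel = simulate_bivariate_panel(2000, 6, 0.3, 0.2, seed=9)
        fit = fit_blmm(panel, n_starts=1)
        g = panel.groupby("participant_id")
        cs = panel["symptom"] - g["symptom"].transform("mean")
        cf = panel["marker"] - g["marker"].transform("mean")
        r_centered = np.corrcoef(cs, cf)[0, 1]
        assert fit.rho_w == pytest.approx(r_centered, abs=0.01)

    def test_timepoint_means_absorb_shared_trend(self):
        trend = np.linspace(1.0, -1.0, 6)
        panel = simulate_bivariate_panel(
            300, 6, 0.3, 0.3, trend=trend, seed=10
        )
        plain = fit_blmm(panel, n_starts=1)
        adjusted = fit_blmm(panel, n_starts=1, timepoint_means=True)
        # the shared trend inflates the plain within-residual variance
        assert adjusted.params.Sigma[0, 0] < plain.params.Sigma[0, 0]
        assert adjusted.rho_w == pytest.approx(0.3, abs=0.1)

    @pytest.mark.parametrize(
        "bad_panel",
        [
            # single participant
            pd.DataFrame(
                {
                    "participant_id": ["a"] * 3,
                    "timepoint_day": [0, 1, 2],
                    "symptom": [0.1, 0.2, 0.4],
                    "marker": [1.0, 0.9, 1.2],
                }
            ),
            # nobody with repeated measures
            pd.DataFrame(
                {
                    "participant_id": ["a", "b", "c"],
                    "timepoint_day": [0, 0, 0],
                    "symptom": [0.1, 0.2, 0.4],
                    "marker": [1.0, 0.9, 1.2],
                }
            ),
            # degenerate symptom series
            pd.DataFrame(
                {
                    "participant_id": ["a", "a", "b", "b"],
                    "timepoint_day": [0, 1, 0, 1],
                    "symptom": [1.0, 1.0, 1.0, 1.0],
                    "marker": [1.0, 0.9, 1.2, 0.8],
                }
            ),
        ],
    )
    def test_unidentified_panels_rejected(self, bad_panel):
        with pytest.raises(PanelError):
            fit_blmm(bad_panel)


class TestBatched:
    def test_matches_single_panel_fits(self):
        frames = []
        for k, (rb, rw, miss) in enumerate(
            [(0.0, 0.0, 0.0), (0.4, 0.2, 0.0), (0.3, 0.1, 0.25)]
        ):
            p = simulate_bivariate_panel(80, 5, rb, rw, missing_rate=miss, seed=20 + k)
            p["feature"] = f"f{k}"
            p["domain"] = "d"
            frames.append(p)
        res = fit_blmm_pairs(pd.concat(frames))
        for k, p in enumerate(frames):
            single = fit_blmm(
                p.drop(columns=["feature", "domain"]), n_starts=1
            )
            row = res[res["feature"] == f"f{k}"].iloc[0]
            assert row["rho_b"] == pytest.approx(single.rho_b, abs=1e-4)
            assert row["rho_w"] == pytest.approx(single.rho_w, abs=1e-4)
            assert row["se_rho_w"] == pytest.approx(single.se_rho_w, rel=1e-3)
            assert row["loglik"] == pytest.approx(single.loglik, abs=1e-5)

    def test_degenerate_pair_reported_unconverged(self):
        good = simulate_bivariate_panel(30, 4, 0.2, 0.1, seed=5)
        good["feature"], good["domain"] = "ok", "d"
        bad = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "timepoint_day": [0, 0],
                "symptom": [0.0, 1.0],
                "marker": [1.0, 0.0],
                "feature": "bad",
                "domain": "d",
            }
        )
        res = fit_blmm_pairs(pd.concat([good, bad])).set_index("feature")
        assert bool(res.loc["ok", "converged"])
        assert not bool(res.loc["bad", "converged"])
        assert np.isnan(res.loc["bad", "rho_b"])


class TestLrt:
    def test_invalid_which_rejected(self, null_panel):
        with pytest.raises(ValueError, match="between|within"):
            lrt_rho(null_panel, "sideways")

    def test_null_statistic_roughly_chisquare(self):
        rng = np.random.default_rng(0)
        stats_w = []
        for k in range(60):
            p = simulate_bivariate_panel(40, 4, 0.0, 0.0, rng=rng)
            stat, _ = lrt_rho(p, "within", seed=1)
            stats_w.append(stat)
        ks = stats.kstest(stats_w, stats.chi2(df=1).cdf)
        assert ks.pvalue > 0.005

    def test_agrees_with_wald_for_strong_effect(self):
        panel = simulate_bivariate_panel(150, 6, 0.2, 0.5, seed=6)
        fit = fit_blmm(panel, n_starts=1)
        stat, p_lrt = lrt_rho(panel, "within", seed=1)
        assert p_lrt < 1e-6 and fit.p_rho_w < 1e-6
        # both deep in the tail; log10 magnitudes within a factor of two
        # (Wald and LRT diverge quantitatively far from the null)
        la, lb = np.log10(max(p_lrt, 1e-300)), np.log10(max(fit.p_rho_w, 1e-300))
        assert 0.5 <= la / lb <= 2.0
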