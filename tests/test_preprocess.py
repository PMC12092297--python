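"""Deterministic preprocessing rules: filters, pruning, alignment."""

import numpy as np
import pandas as pd
import pytest

from langmark.preprocess import (
    align_observations,
    cap_word_count,
    drop_os_switchers,
    filter_zero_features,
    missingness_diagnostic,
    prune_redundant,
)


def fm_from(dict_of_cols, pids=None, dates=None):
    n = len(next(iter(dict_of_cols.values())))
    pids = pids or [f"P{i}" for i in range(n)]
    dates = dates or ["2024-01-01"] * n
    idx = pd.MultiIndex.from_arrays(
        [pids, dates], names=["participant_id", "date"]
    )
    return pd.DataFrame(dict_of_cols, index=idx)


class TestZeroFilter:
    def test_boundaries(self):
        cols = {
            "drop95": [0.0] * 95 + [1.0] * 5,
            "keep90": [0.0] * 90 + [1.0] * 10,  # exactly 90%: strict rule keeps
            "dense": list(np.arange(1.0, 101.0)),
        }
        out, dropped = filter_zero_features(fm_from(cols))
        assert dropped == ["drop95"]
        assert set(out.columns) == {"keep90", "dense"}

    def test_zero_share_over_nonmissing_cells_only(self):
        # 9 zeros of 10 non-missing = 90% -> kept; missing cells don't count
        col = [0.0] * 9 + [1.0] + [np.nan] * 90
        out, dropped = filter_zero_features(fm_from({"x": col}))
        assert dropped == []


class TestWordCountCap:
    def test_strict_threshold(self):
        fm = fm_from({"word_count": [10000.0, 10001.0], "pct": [5.0, 6.0]})
        out, n = cap_word_count(fm)
        assert n == 1
        assert out["word_count"].iloc[0] == 10000.0
        assert np.isnan(out["word_count"].iloc[1])

    def test_percent_features_untouched(self):
        fm = fm_from({"word_count": [20000.0], "pct": [5.0]})
        out, _ = cap_word_count(fm)
        assert out["pct"].iloc[0] == 5.0

    def test_missing_count_column_rejected(self):
        with pytest.raises(KeyError):
            cap_word_count(fm_from({"pct": [1.0]}))


class TestOsSwitchers:
    def log(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "date", "os"])

    def test_stable_participant_kept(self):
        fm = fm_from({"x": [1.0, 2.0]}, pids=["A", "A"], dates=["2024-01-01", "2024-02-01"])
        log = self.log([("A", "2024-01-01", "android"), ("A", "2024-03-01", "android")])
        out, removed = drop_os_switchers(fm, log)
        assert removed == [] and len(out) == 2

    def test_switcher_removed_entirely(self):
        fm = fm_from(
            {"x": [1.0, 2.0, 3.0]},
            pids=["A", "A", "B"],
            dates=["2024-01-01", "2024-02-01", "2024-01-01"],
        )
        log = self.log(
            [
                ("A", "2024-01-01", "android"),
                ("A", "2024-03-01", "ios"),
                ("B", "2024-01-01", "android"),
            ]
        )
        out, removed = drop_os_switchers(fm, log)
        assert removed == ["A"]
        assert set(out.index.get_level_values(0)) == {"B"}

    def test_empty_log_warns_and_keeps(self):
        fm = fm_from({"x": [1.0]})
        with pytest.warns(UserWarning, match="empty device log"):
            out, removed = drop_os_switchers(fm, self.log([]))
        assert removed == [] and len(out) == 1

    def test_commutes_with_zero_filter(self):
        fm = fm_from(
            {"sparse": [0.0, 0.0, 0.0, 1.0] + [0.0] * 96, "x": list(range(100))},
            pids=[f"P{i}" for i in range(100)],
        )
        log = self.log(
            [("P0", "2024-01-01", "android"), ("P0", "2024-02-01", "ios")]
        )
        a = drop_os_switchers(filter_zero_features(fm)[0], log)[0]
        b = filter_zero_features(drop_os_switchers(fm, log)[0])[0]
        pd.testing.assert_frame_equal(a, b)


def _simple_scores(pids, vals, domain="pain", day=7):
    return pd.DataFrame(
        {
            "participant_id": pids,
            "timepoint_day": day,
            "domain": domain,
            "score": vals,
        }
    )


def _simple_schedule(pids, day=7, date="2024-01-01"):
    return pd.DataFrame(
        {"participant_id": pids, "timepoint_day": day, "date": date}
    )


class TestPruneRedundant:
    def setup_method(self):
        rng = np.random.default_rng(0)
        n = 60
        self.pids = [f"P{i}" for i in range(n)]
        base = rng.standard_normal(n)
        self.fm = fm_from(
            {
                "a": base + rng.normal(0, 0.1, n),  # strong proxy of the score
                "b": base + rng.normal(0, 0.4, n),  # correlated but weaker
                "c": rng.standard_normal(n),  # independent
            },
            pids=self.pids,
        )
        self.scores = _simple_scores(self.pids, base)
        self.schedule = _simple_schedule(self.pids)

    def test_weaker_member_dropped(self):
        out, pruned = prune_redundant(
            self.fm, self.scores, self.schedule, threshold=0.7
        )
        assert pruned == {"b": "a"}
        assert list(out.columns) == ["a", "c"]

    def test_three_way_component_single_survivor(self):
        rng = np.random.default_rng(1)
        n = 50
        base = rng.standard_normal(n)
        fm = fm_from(
            {k: base + rng.normal(0, 0.05, n) for k in ("x", "y", "z")},
            pids=[f"P{i}" for i in range(n)],
        )
        scores = _simple_scores([f"P{i}" for i in range(n)], base)
        out, pruned = prune_redundant(
            fm, scores, _simple_schedule([f"P{i}" for i in range(n)])
        )
        assert out.shape[1] == 1
        assert len(pruned) == 2

    def test_threshold_is_strict(self):
        # exact correlation 0.85 must not create an edge
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        fm = fm_from({"x": list(x), "y": [0.0, 2.0, 1.0, 3.0, 5.0, 4.0]},
                     pids=[f"P{i}" for i in range(6)])
        corr = fm.corr(method="spearman").loc["x", "y"]
        assert corr == pytest.approx(0.8857, abs=0.01)  # just above: edge
        out, pruned = prune_redundant(
            fm,
            _simple_scores([f"P{i}" for i in range(6)], x),
            _simple_schedule([f"P{i}" for i in range(6)]),
            threshold=corr,  # equality -> no edge
        )
        assert pruned == {}

    def test_priority_list_overrides_strength(self):
        out, pruned = prune_redundant(
            self.fm, self.scores, self.schedule, threshold=0.7, priority=["b"]
        )
        assert pruned == {"a": "b"}


class TestAlign:
    def build(self, prior, day0):
        fm_rows = {}
        pids, dates, vals = [], [], []
        if prior is not None:
            pids.append("A"); dates.append("2024-01-06"); vals.append(prior)
        if day0 is not None:
            pids.append("A"); dates.append("2024-01-07"); vals.append(day0)
        if not pids:  # keep the frame non-empty for the index
            pids, dates, vals = ["B"], ["2024-01-01"], [0.0]
        fm = fm_from({"feat": vals}, pids=pids, dates=dates)
        scores = _simple_scores(["A"], [1.0])
        schedule = _simple_schedule(["A"], date="2024-01-07")
        return align_observations(fm, scores, schedule)

    def test_mean_of_two_days(self):
        panel = self.build(2.0, 4.0)
        assert panel["marker"].iloc[0] == pytest.approx(3.0)

    def test_single_available_day_used(self):
        panel = self.build(2.0, None)
        assert panel["marker"].iloc[0] == pytest.approx(2.0)

    def test_both_missing_is_missing(self):
        panel = self.build(None, None)
        row = panel[panel["participant_id"] == "A"]
        assert np.isnan(row["marker"]).all() and (row["symptom"] == 1.0).all()

    def test_duplicate_survey_rows_rejected(self):
        fm = fm_from({"feat": [1.0]}, pids=["A"], dates=["2024-01-07"])
        scores = pd.concat([_simple_scores(["A"], [1.0])] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            align_observations(fm, scores, _simple_schedule(["A"], date="2024-01-07"))

    def test_row_count_bound(self):
        # output rows <= (#survey rows) x (#features)
        rng = np.random.default_rng(4)
        pids = [f"P{i}" for i in range(10)]
        fm = fm_from(
            {"f1": rng.standard_normal(10), "f2": rng.standard_normal(10)},
            pids=pids, dates=["2024-01-07"] * 10,
        )
        scores = _simple_scores(pids, rng.standard_normal(10))
        panel = align_observations(fm, scores, _simple_schedule(pids, date="2024-01-07"))
        assert len(panel) <= len(scores) * 2


class TestMissingnessDiagnostic:
    def test_independent_completion_flags_mar(self):
        rng = np.random.default_rng(0)
        n = 400
        pids = [f"P{i}" for i in range(n)]
        scores = _simple_scores(pids, rng.standard_normal(n))
        completion = pd.DataFrame(
            {"participant_id": pids, "survey": rng.random(n), "watch": rng.random(n)}
        )
        table, flag = missingness_diagnostic(scores, completion)
        assert flag and (table["r"].abs() < 0.1).all()

    def test_severity_linked_completion_unflags(self):
        rng = np.random.default_rng(1)
        n = 200
        pids = [f"P{i}" for i in range(n)]
        sev = rng.standard_normal(n)
        scores = _simple_scores(pids, sev)
        completion = pd.DataFrame(
            {"participant_id": pids, "survey": 1 / (1 + np.exp(sev))}
        )
        table, flag = missingness_diagnostic(scores, completion)
        assert not flag and (table["r"].abs() >= 0.1).any()

    def test_single_participant_rejected(self):
        scores = _simple_scores(["A"], [1.0])
        completion = pd.DataFrame({"participant_id": ["A"], "survey": [0.5]})
        with pytest.raises(ValueError):
            missingness_diagnostic(scores, completion)

    def test_constant_completion_reported_missing(self):
        rng = np.random.default_rng(2)
        pids = [f"P{i}" for i in range(50)]
        scores = _simple_scores(pids, rng.standard_normal(50))
        completion = pd.DataFrame({"participant_id": pids, "survey": 1.0})
        table, _ = missingness_diagnostic(scores, completion)
        assert table["r"].isna().all()
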