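"""Filters, redundancy pruning, alignment, and the missingness diagnostic.

These are the deterministic data-hygiene rules applied between feature
extraction and model fitting:

* drop features that are zero on more than 90% of their non-missing
  participant-days (limited variability);
* set daily word counts above 10,000 to missing (collection artifacts /
  atypical use; derived percentage features are untouched);
* remove participants who switched smartphone operating system during
  the study window;
* collapse clusters of highly redundant features (pairwise Spearman
  correlation > 0.85), keeping the member most strongly associated with
  the symptom scores;
* align each survey timepoint with the mean of the day-prior and day-of
  feature values to form the candidate marker observations;
* check that symptom severity is (weakly) unrelated to study-activity
  completion rates, the diagnostic supporting a missing-at-random
  treatment of the gaps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterReport",
    "filter_zero_features",
    "cap_word_count",
    "drop_os_switchers",
    "prune_redundant",
    "align_observations",
    "missingness_diagnostic",
]


@dataclass
class FilterReport:
    """Audit trail of what each rule removed."""

    zero_dropped: list = field(default_factory=list)
    wordcount_masked: int = 0
    os_removed: list = field(default_factory=list)
    pruned: dict = field(default_factory=dict)  # dropped -> retained

    def to_json(self, path=None):
        payload = json.dumps(
            {
                "zero_dropped": list(self.zero_dropped),
                "wordcount_masked": int(self.wordcount_masked),
                "os_removed": list(self.os_removed),
                "pruned": dict(self.pruned),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def filter_zero_features(fm: pd.DataFrame, threshold: float = 90.0):
    """Drop features whose zero percentage (among non-missing cells)
    strictly exceeds ``threshold`` percent. Returns (frame, dropped)."""
    dropped = []
    for col in fm.columns:
        vals = fm[col].dropna()
        if len(vals) == 0:
            dropped.append(col)
            continue
        if 100.0 * (vals == 0).mean() > threshold:
            dropped.append(col)
    return fm.drop(columns=dropped), dropped


def cap_word_count(
    fm: pd.DataFrame, cap: int = 10_000, column: str = "word_count"
):
    """Mask word counts strictly greater than ``cap`` (set to missing).

    Only the count itself is masked; percentage features computed from
    the same day are retained. Returns (frame, n_cells_masked).
    """
    if column not in fm.columns:
        raise KeyError(f"raw word-count column {column!r} not present")
    out = fm.copy()
    mask = out[column] > cap
    out.loc[mask, column] = np.nan
    return out, int(mask.sum())


def drop_os_switchers(
    fm: pd.DataFrame, device_log: pd.DataFrame, window_days: int = 180
):
    """Remove participants with >=2 distinct operating systems early on.

    The window is the first ``window_days`` days from each participant's
    first device-log entry. Participants absent from the log are kept
    with a warning. Returns (frame, removed participant list).
    """
    pids = fm.index.get_level_values("participant_id").unique()
    removed = []
    if len(device_log) == 0:
        warnings.warn("empty device log: no participants removed")
        log_pids = set()
    else:
        log = device_log.copy()
        log["date"] = pd.to_datetime(log["date"])
        first = log.groupby("participant_id")["date"].transform("min")
        log = log[log["date"] <= first + pd.Timedelta(days=window_days)]
        n_os = log.groupby("participant_id")["os"].nunique()
        removed = sorted(set(n_os.index[n_os >= 2]) & set(pids))
        log_pids = set(device_log["participant_id"])
    unknown = sorted(set(pids) - log_pids)
    if unknown and len(device_log):
        warnings.warn(
            f"{len(unknown)} participant(s) absent from device log; kept"
        )
    out = fm[~fm.index.get_level_values("participant_id").isin(removed)]
    return out, removed


def _feature_vs_score_frame(fm, scores, schedule):
    """Join features (day-of survey date) with domain scores, wide."""
    sched = schedule.copy()
    sched["date"] = pd.to_datetime(sched["date"]).dt.strftime("%Y-%m-%d")
    feats = fm.reset_index()
    feats["date"] = pd.to_datetime(feats["date"]).dt.strftime("%Y-%m-%d")
    merged = sched.merge(feats, on=["participant_id", "date"], how="left")
    wide_scores = scores.pivot_table(
        index=["participant_id", "timepoint_day"],
        columns="domain",
        values="score",
        aggfunc="first",
    )
    merged = merged.set_index(["participant_id", "timepoint_day"])
    return merged, wide_scores


def prune_redundant(
    fm: pd.DataFrame,
    scores: pd.DataFrame,
    schedule: pd.DataFrame,
    *,
    threshold: float = 0.85,
    priority=None,
):
    """Collapse clusters of redundant features.

    Builds a graph joining features whose pairwise Spearman correlation
    (pairwise-complete observations) strictly exceeds ``threshold``;
    within each connected component the survivor is the feature with the
    largest mean |Spearman correlation| against the domain scores
    (features listed in ``priority`` win first; remaining ties break
    lexicographically, keeping the pipeline deterministic). Returns
    (frame, {dropped: survivor}).
    """
    cols = list(fm.columns)
    if len(cols) < 2:
        return fm, {}
    corr = fm.corr(method="spearman", min_periods=3)
    G = nx.Graph()
    G.add_nodes_from(cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            c = corr.loc[a, b]
            if np.isfinite(c) and abs(c) > threshold:
                G.add_edge(a, b)

    merged, wide_scores = _feature_vs_score_frame(fm, scores, schedule)
    strength = {}
    for col in cols:
        x = merged[col] if col in merged.columns else pd.Series(dtype=float)
        rs = []
        for dom in wide_scores.columns:
            y = wide_scores[dom].reindex(x.index)
            ok = x.notna() & y.notna()
            if ok.sum() < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                continue
            r, _ = stats.spearmanr(x[ok], y[ok])
            if np.isfinite(r):
                rs.append(abs(r))
        if not rs:
            warnings.warn(
                f"feature {col!r}: association with scores undefined; treated as 0"
            )
        strength[col] = float(np.mean(rs)) if rs else 0.0

    priority = list(priority or [])
    pruned = {}
    for comp in nx.connected_components(G):
        comp = sorted(comp)
        if len(comp) == 1:
            continue
        prioritized = [c for c in priority if c in comp]
        if prioritized:
            keep = prioritized[0]
        else:
            # strongest association wins; ties break lexicographically
            keep = min(comp, key=lambda c: (-strength[c], c))
        for c in comp:
            if c != keep:
                pruned[c] = keep
    return fm.drop(columns=list(pruned)), pruned


def align_observations(
    fm: pd.DataFrame, scores: pd.DataFrame, schedule: pd.DataFrame
) -> pd.DataFrame:
    """Pair each survey timepoint with its two-day window of features.

    For every (participant, survey timepoint) the marker value of each
    feature is the mean of the day-prior and day-of values over those
    available (one-day windows use the single available day; both days
    missing gives a missing marker). Returns the long aligned panel with
    columns participant_id, timepoint_day, domain, feature, symptom,
    marker — the input to the bivariate mixed model. Rows where both the
    symptom and the marker are missing are dropped.
    """
    if scores.duplicated(["participant_id", "timepoint_day", "domain"]).any():
        raise ValueError("duplicate survey score rows per (participant, timepoint, domain)")
    sched = schedule.copy()
    sched["date0"] = pd.to_datetime(sched["date"])
    feats = fm.copy()
    feats.index = feats.index.set_levels(
        pd.to_datetime(feats.index.levels[1]), level=1
    )

    day0 = sched.merge(
        feats.reset_index().rename(columns={"date": "date0"}),
        on=["participant_id", "date0"],
        how="left",
    ).set_index(["participant_id", "timepoint_day"])[list(fm.columns)]
    sched["date_prior"] = sched["date0"] - pd.Timedelta(days=1)
    day1 = sched.merge(
        feats.reset_index().rename(columns={"date": "date_prior"}),
        on=["participant_id", "date_prior"],
        how="left",
    ).set_index(["participant_id", "timepoint_day"])[list(fm.columns)]

    marker = pd.concat([day0, day1]).groupby(level=[0, 1]).mean()
    marker_long = (
        marker.stack(future_stack=True)
        .rename("marker")
        .reset_index()
    )
    marker_long = marker_long.rename(columns={marker_long.columns[2]: "feature"})

    # complete (participant, timepoint) x domain grid so that feature-only
    # observations (survey skipped, words typed) still enter the likelihood
    domains = pd.DataFrame({"domain": sorted(scores["domain"].unique())})
    grid = (
        sched[["participant_id", "timepoint_day"]]
        .drop_duplicates()
        .merge(domains, how="cross")
        .merge(
            scores.rename(columns={"score": "symptom"}),
            on=["participant_id", "timepoint_day", "domain"],
            how="left",
        )
    )
    panel = grid.merge(
        marker_long, on=["participant_id", "timepoint_day"], how="left"
    )
    panel = panel.dropna(subset=["feature"])
    panel = panel.dropna(subset=["symptom", "marker"], how="all")
    return panel[
        ["participant_id", "timepoint_day", "domain", "feature", "symptom", "marker"]
    ].sort_values(
        ["feature", "domain", "participant_id", "timepoint_day"], kind="stable"
    ).reset_index(drop=True)


def missingness_diagnostic(
    scores: pd.DataFrame, completion: pd.DataFrame, *, threshold: float = 0.1
):
    """Correlate symptom severity with study-activity completion rates.

    Computes the Pearson correlation between each participant's mean
    domain score and their completion rate for each study activity. If
    every |r| stays below ``threshold`` the missingness is flagged
    MAR-plausible (weak dependence of nonresponse on severity), which is
    what licenses handling it inside the likelihood. Returns
    (correlation table, flag).
    """
    per_part = (
        scores.groupby(["participant_id", "domain"])["score"].mean().unstack()
    )
    comp = completion.set_index("participant_id")
    activities = [c for c in comp.columns]
    common = per_part.index.intersection(comp.index)
    if len(common) < 2:
        raise ValueError("need >=2 participants for the missingness diagnostic")
    rows = []
    for dom in per_part.columns:
        for act in activities:
            x = per_part.loc[common, dom]
            y = comp.loc[common, act]
            ok = x.notna() & y.notna()
            if ok.sum() < 2 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                r = np.nan
            else:
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            rows.append({"domain": dom, "activity": act, "r": r})
    table = pd.DataFrame(rows)
    flag = bool((table["r"].abs() < threshold).all() and table["r"].notna().any())
    return table, flag
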