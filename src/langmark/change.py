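"""Sign-of-change evaluation of validated longitudinal markers.

A validated longitudinal marker tracks occasion-to-occasion change in
its symptom domain, so a natural (deliberately simple) screening rule
predicts the *direction* of symptom change over the study from the
direction of marker change over the same window:

* worsening:   score(last endpoint) - score(first endpoint) > 0
* improvement: the difference < 0
* a difference of exactly 0, or a missing endpoint, is excluded
  (the definitions are strict inequalities).

For a marker with a negative validated correlation the prediction is
inverted — an increase in such a marker predicts improvement. The rule
is scored with the usual confusion-matrix quantities (sensitivity,
specificity, PPV, NPV), with worsening as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ChangeRecords",
    "ConfusionMetrics",
    "compute_changes",
    "confusion",
    "evaluate_markers",
]

WORSENING = "worsening"
IMPROVEMENT = "improvement"
EXCLUDED = "excluded"


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str = WORSENING

    @property
    def sensitivity(self):
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self):
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def ppv(self):
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else np.nan

    @property
    def npv(self):
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else np.nan

    @property
    def n_scored(self):
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self):
        n = self.n_scored
        return (self.tp + self.fn) / n if n else np.nan

    def as_dict(self):
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "n_scored": self.n_scored,
            "prevalence": self.prevalence,
        }


def _classify(delta):
    if not np.isfinite(delta):
        return EXCLUDED
    if delta > 0:
        return WORSENING
    if delta < 0:
        return IMPROVEMENT
    return EXCLUDED


def compute_changes(
    scores: pd.DataFrame,
    panel: pd.DataFrame,
    endpoints=None,
) -> pd.DataFrame:
    """Per-participant symptom and marker changes between two endpoints.

    ``scores`` is the long factor-score table; ``panel`` the aligned
    feature panel (for the marker values at the same timepoints).
    ``endpoints`` names two scheduled timepoint days, defaulting to the
    first and last scheduled survey (the "one week" and "six months"
    assessments). Returns one row per (participant, domain, feature)
    with delta_symptom, delta_marker, and true / raw-predicted classes;
    deltas with a missing endpoint are excluded.
    """
    days = np.sort(scores["timepoint_day"].unique())
    if endpoints is None:
        endpoints = (days[0], days[-1])
    t0, t1 = endpoints
    if t0 not in days or t1 not in days:
        raise ValueError(
            f"endpoints {endpoints} not among scheduled timepoints {list(days)}"
        )

    def pick(df, col):
        sub = df[df["timepoint_day"].isin([t0, t1])]
        idx = [c for c in ("participant_id", "domain", "feature") if c in df.columns]
        wide = sub.pivot_table(
            index=idx, columns="timepoint_day", values=col, aggfunc="first"
        )
        for t in (t0, t1):
            if t not in wide.columns:
                wide[t] = np.nan
        return (wide[t1] - wide[t0]).rename(f"delta_{col}")

    d_sym = pick(scores, "score").reset_index()
    d_sym = d_sym.rename(columns={"delta_score": "delta_symptom"})
    pm = panel.drop_duplicates(["participant_id", "feature", "timepoint_day"])[
        ["participant_id", "feature", "timepoint_day", "marker"]
    ]
    d_mark = pick(pm, "marker").reset_index()

    rec = d_sym.merge(d_mark, on="participant_id", how="inner")
    rec["true_class"] = rec["delta_symptom"].map(_classify)
    rec["predicted_raw"] = rec["delta_marker"].map(_classify)
    return rec[
        [
            "participant_id",
            "domain",
            "feature",
            "delta_symptom",
            "delta_marker",
            "true_class",
            "predicted_raw",
        ]
    ]


ChangeRecords = pd.DataFrame  # alias documenting the record-table contract


def confusion(records: pd.DataFrame, *, positive: str = WORSENING) -> ConfusionMetrics:
    """Confusion metrics over scored records (both classes defined).

    Records with an excluded truth or prediction are ignored. Metrics
    with zero denominators are reported missing, never zero.
    """
    scored = records[
        (records["true_class"] != EXCLUDED)
        & (records["predicted_class"] != EXCLUDED)
    ]
    if len(scored) == 0:
        raise ValueError("no scored records (all excluded)")
    truth_pos = scored["true_class"] == positive
    pred_pos = scored["predicted_class"] == positive
    return ConfusionMetrics(
        tp=int((truth_pos & pred_pos).sum()),
        fp=int((~truth_pos & pred_pos).sum()),
        fn=int((truth_pos & ~pred_pos).sum()),
        tn=int((~truth_pos & ~pred_pos).sum()),
        positive_class=positive,
    )


def evaluate_markers(
    marker_table: pd.DataFrame,
    records: pd.DataFrame,
    *,
    both_conventions: bool = False,
) -> pd.DataFrame:
    """Confusion metrics per validated longitudinal marker.

    The predicted class uses the sign of (validated correlation x
    delta_marker), so negatively associated markers are inverted. With
    ``both_conventions=True`` each marker also reports the metrics with
    improvement as the positive class (the printed-table convention for
    such screens is ambiguous, so both are available).
    """
    from .selection import LONGITUDINAL

    sel = marker_table[
        (marker_table["association_type"] == LONGITUDINAL)
        & marker_table["is_validated"]
    ]
    rows = []
    for _, mk in sel.iterrows():
        rec = records[
            (records["feature"] == mk["feature"])
            & (records["domain"] == mk["domain"])
        ].copy()
        if len(rec) == 0:
            continue
        sign = np.sign(mk["rho_valid"])
        rec["predicted_class"] = (sign * rec["delta_marker"]).map(_classify)
        try:
            cm = confusion(rec)
        except ValueError:
            continue
        row = {
            "feature": mk["feature"],
            "domain": mk["domain"],
            "rho_valid": mk["rho_valid"],
            "n_worsening": cm.tp + cm.fn,
            "pct_worsening": 100.0 * cm.prevalence,
        }
        row.update(
            {
                k: cm.as_dict()[k]
                for k in ("sensitivity", "specificity", "ppv", "npv", "n_scored")
            }
        )
        if both_conventions:
            cmi = confusion(rec, positive=IMPROVEMENT)
            row.update(
                {
                    "sensitivity_improvement": cmi.sensitivity,
                    "specificity_improvement": cmi.specificity,
                    "ppv_improvement": cmi.ppv,
                    "npv_improvement": cmi.npv,
                }
            )
        rows.append(row)
    cols = [
        "feature",
        "domain",
        "rho_valid",
        "n_worsening",
        "pct_worsening",
        "sensitivity",
        "specificity",
        "ppv",
        "npv",
        "n_scored",
    ]
    if both_conventions:
        cols += [
            "sensitivity_improvement",
            "specificity_improvement",
            "ppv_improvement",
            "npv_improvement",
        ]
    return pd.DataFrame(rows, columns=cols)
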