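"""Simulation studies of the pipeline's statistical operating characteristics.

Each function generates data from the package's own synthetic-cohort
model with known ground truth, runs the corresponding estimator, and
summarizes recovery/calibration. They are used by the test suite and
the reproduction script, and are equally usable interactively for
power or sensitivity analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blmm import fit_blmm_pairs
from .change import compute_changes, confusion
from .measurement import factor_scores, fit_measurement
from .selection import run_selection, split_participants
from .simulate import simulate_bivariate_panel, simulate_items

__all__ = [
    "recovery_study",
    "type1_study",
    "delta_correlation_check",
    "measurement_recovery",
    "selection_study",
    "change_prediction_study",
]


def _many_panels(specs, rng, n, J, missing_rate):
    """Long frame with one simulated bivariate panel per (key, rho_b, rho_w)."""
    frames = []
    for key, rho_b, rho_w in specs:
        p = simulate_bivariate_panel(
            n, J, rho_b, rho_w, missing_rate=missing_rate, rng=rng
        )
        p["feature"] = key
        p["domain"] = "d"
        frames.append(p)
    return pd.concat(frames, ignore_index=True)


def recovery_study(
    n_reps: int = 100,
    n_participants: int = 400,
    n_timepoints: int = 8,
    rho_b: float = 0.30,
    rho_w: float = 0.15,
    missing_rate: float = 0.20,
    seed: int = 0,
    conf_level: float = 0.95,
) -> dict:
    """FIML recovery of planted correlations over simulated replicates.

    Fits every replicate and reports the mean estimates, mean bias, and
    the coverage of nominal Wald confidence intervals for both
    correlations.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    specs = [(f"rep{r:04d}", rho_b, rho_w) for r in range(n_reps)]
    panel = _many_panels(specs, rng, n_participants, n_timepoints, missing_rate)
    fits = fit_blmm_pairs(panel)
    z = sps.norm.ppf(0.5 + conf_level / 2.0)
    out = {"n_reps": n_reps, "n_converged": int(fits["converged"].sum())}
    for name, truth in (("rho_b", rho_b), ("rho_w", rho_w)):
        est = fits[name].to_numpy()
        se = fits[f"se_{name}"].to_numpy()
        cover = (est - z * se <= truth) & (truth <= est + z * se)
        out[f"mean_{name}"] = float(np.mean(est))
        out[f"bias_{name}"] = float(np.mean(est) - truth)
        out[f"coverage_{name}"] = float(np.mean(cover))
    return out


def type1_study(
    n_reps: int = 1000,
    n_participants: int = 200,
    n_timepoints: int = 6,
    alpha: float = 0.05,
    seed: int = 0,
    chunk: int = 250,
) -> dict:
    """Type-I error of the Wald tests under independence (rho = 0)."""
    rng = np.random.default_rng(seed)
    rej_b = rej_w = total = 0
    for start in range(0, n_reps, chunk):
        b = min(chunk, n_reps - start)
        specs = [(f"rep{start + r:05d}", 0.0, 0.0) for r in range(b)]
        panel = _many_panels(specs, rng, n_participants, n_timepoints, 0.0)
        fits = fit_blmm_pairs(panel)
        fits = fits[fits["converged"]]
        rej_b += int((fits["p_rho_b"] < alpha).sum())
        rej_w += int((fits["p_rho_w"] < alpha).sum())
        total += len(fits)
    return {
        "n_reps": total,
        "reject_rate_rho_b": rej_b / total,
        "reject_rate_rho_w": rej_w / total,
    }


def delta_correlation_check(
    n_participants: int = 2000,
    n_timepoints: int = 6,
    rho_w: float = 0.15,
    seed: int = 0,
) -> dict:
    """Within-subject correlation equals the endpoint-change correlation.

    Under the random-intercept model, intercepts cancel in differences,
    so corr(delta symptom, delta feature) between any two timepoints is
    exactly rho_w; this computes the sample version on complete data.
    """
    panel = simulate_bivariate_panel(
        n_participants, n_timepoints, 0.3, rho_w, seed=seed
    )
    t0, t1 = 0, n_timepoints - 1
    wide_s = panel.pivot(index="participant_id", columns="timepoint_day", values="symptom")
    wide_f = panel.pivot(index="participant_id", columns="timepoint_day", values="marker")
    ds = wide_s[t1] - wide_s[t0]
    df_ = wide_f[t1] - wide_f[t0]
    r = float(np.corrcoef(ds, df_)[0, 1])
    return {"planted_rho_w": rho_w, "change_correlation": r, "gap": abs(r - rho_w)}


def measurement_recovery(
    n_rows: int = 2000,
    loadings=(0.8, 0.7, 0.6),
    noise_sd: float = 0.4,
    missing_rate: float = 0.25,
    seed: int = 0,
) -> dict:
    """One-factor model recovery with planned-missing items.

    Reports the maximum loading error and the correlation between
    regression factor scores and the generating latent on complete rows.
    """
    X, eta = simulate_items(
        n_rows, loadings, noise_sd=noise_sd, missing_rate=missing_rate, seed=seed
    )
    # keep only rows observing at least one item
    keep = np.isfinite(X).any(axis=1)
    X, eta = X[keep], eta[keep]
    rows = []
    for r in range(len(X)):
        for k in range(X.shape[1]):
            if np.isfinite(X[r, k]):
                rows.append((f"P{r:05d}", 7, f"dom_it{k + 1}", X[r, k]))
    tab = pd.DataFrame(
        rows, columns=["participant_id", "timepoint_day", "item_id", "value"]
    )
    model = fit_measurement(tab, "dom")
    scores = factor_scores(model, tab)
    scores["row"] = scores["participant_id"].str[1:].astype(int)
    scores = scores.sort_values("row")
    complete = np.isfinite(X).all(axis=1)
    est = scores.set_index("row")["score"].reindex(np.arange(len(X))).to_numpy()
    r_complete = float(np.corrcoef(est[complete], eta[complete])[0, 1])
    return {
        "loadings_est": model.loadings.tolist(),
        "max_loading_error": float(
            np.max(np.abs(model.loadings - np.asarray(loadings)))
        ),
        "score_truth_corr_complete": r_complete,
        "converged": model.converged,
        "score_variance": float(np.nanvar(est)),
    }


def _selection_replicate(
    rng,
    n_features: int,
    n_domains: int,
    planted,
    n_participants: int,
    n_timepoints: int,
    alpha: float,
):
    """One split-half screen over a feature x domain grid of panels."""
    frames = []
    planted_keys = {(f, d): (rb, rw) for f, d, rb, rw in planted}
    for fi in range(n_features):
        for di in range(n_domains):
            rb, rw = planted_keys.get((fi, di), (0.0, 0.0))
            p = simulate_bivariate_panel(
                n_participants, n_timepoints, rb, rw, rng=rng
            )
            p["feature"] = f"f{fi:02d}"
            p["domain"] = f"d{di:02d}"
            frames.append(p)
    panel = pd.concat(frames, ignore_index=True)
    split = split_participants(
        panel["participant_id"].unique(), seed=int(rng.integers(2**31))
    )
    half1 = panel[panel["participant_id"].isin(split.index[split == "identification"])]
    half2 = panel[panel["participant_id"].isin(split.index[split == "validation"])]
    fits1 = fit_blmm_pairs(half1)
    fits2 = fit_blmm_pairs(half2)
    markers = run_selection(fits1, fits2, alpha=alpha)
    validated = markers[markers["is_validated"]]
    planted_names = {(f"f{f:02d}", f"d{d:02d}") for f, d, _, _ in planted}
    val_pairs = set(zip(validated["feature"], validated["domain"]))
    return {
        "n_validated_planted": len(val_pairs & planted_names),
        "n_validated_false": len(val_pairs - planted_names),
        "n_validated_tests": int(markers["is_validated"].sum()),
    }


def selection_study(
    n_reps: int = 200,
    n_features: int = 40,
    n_domains: int = 10,
    planted=((0, 0, 0.6, 0.4), (1, 1, 0.6, 0.4), (2, 2, 0.6, 0.4)),
    n_participants: int = 100,
    n_timepoints: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Operating characteristics of the split-half FDR/Bonferroni screen.

    ``planted`` pairs carry real between- and within-subject
    correlations; every other (feature, domain) pair is null. Reports
    how often all planted pairs validate and the proportion of
    validated pairs that are false.
    """
    rng = np.random.default_rng(seed)
    n_all = n_false = n_val = 0
    all_planted = 0
    for _ in range(n_reps):
        res = _selection_replicate(
            rng, n_features, n_domains, planted, n_participants, n_timepoints, alpha
        )
        n_all += res["n_validated_planted"]
        n_false += res["n_validated_false"]
        n_val += res["n_validated_planted"] + res["n_validated_false"]
        all_planted += res["n_validated_planted"] == len(planted)
    return {
        "n_reps": n_reps,
        "mean_planted_validated": n_all / n_reps,
        "frac_reps_all_planted_validated": all_planted / n_reps,
        "false_validation_proportion": (n_false / n_val) if n_val else 0.0,
    }


def change_prediction_study(
    n_participants: int = 1000,
    n_timepoints: int = 6,
    rho_w: float = 0.5,
    rho_b: float = 0.3,
    seed: int = 0,
) -> dict:
    """PPV of the sign-of-change rule for a marker with planted rho_w.

    A positive within-subject correlation should push the worsening PPV
    above the worsening prevalence; under rho_w = 0 the rule is
    uninformative and PPV ~ prevalence.
    """
    panel = simulate_bivariate_panel(
        n_participants, n_timepoints, rho_b, rho_w, seed=seed
    )
    panel["feature"] = "f"
    panel["domain"] = "d"
    scores = panel.rename(columns={"symptom": "score"})[
        ["participant_id", "timepoint_day", "domain", "score"]
    ]
    records = compute_changes(scores, panel)
    records["predicted_class"] = records["predicted_raw"]
    cm = confusion(records)
    return {
        "planted_rho_w": rho_w,
        "ppv": cm.ppv,
        "prevalence": cm.prevalence,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
    }
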