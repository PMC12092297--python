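"""Per-domain symptom factor scores from planned-missing survey items.

Each symptom domain is measured by a small set of survey items observed
at scheduled timepoints, with item-level planned missingness. A single
one-factor confirmatory model is fitted per domain, pooling rows across
all timepoints so the loadings are invariant over the study::

    x_k = nu_k + lambda_k * eta + eps_k,   eta ~ N(0, 1),
    eps_k ~ N(0, theta_k)

Identification fixes the factor variance at 1 (scores share a
standardized scale across domains) with the first loading constrained
positive. Estimation is maximum likelihood with casewise
marginalization over each row's observed-item subset (FIML), so rows
missing items still contribute exactly their observed information.

Factor scores use the regression method restricted to each row's
observed items:

    eta_hat = lambda_o' (lambda_o lambda_o' + Theta_o)^{-1} (x_o - nu_o)

Regression scores are shrunken toward zero, so var(eta_hat) <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MeasurementModel",
    "fit_measurement",
    "factor_scores",
    "measurement_loglik",
    "fit_domains",
    "score_domains",
    "infer_domain_spec",
]


class IdentificationError(ValueError):
    pass


@dataclass
class MeasurementModel:
    domain: str
    items: list
    loadings: np.ndarray
    intercepts: np.ndarray
    uniquenesses: np.ndarray
    loglik: float
    converged: bool
    n_rows: int

    @property
    def implied_cov(self) -> np.ndarray:
        lam = self.loadings
        return np.outer(lam, lam) + np.diag(self.uniquenesses)


def _pivot_items(item_table: pd.DataFrame, items):
    wide = item_table.pivot_table(
        index=["participant_id", "timepoint_day"],
        columns="item_id",
        values="value",
        aggfunc="first",
    )
    missing_items = [it for it in items if it not in wide.columns]
    for it in missing_items:
        wide[it] = np.nan
    return wide[list(items)]


def _pattern_stats(X):
    """Group rows by observed-item pattern; per-pattern mean and scatter."""
    obs = np.isfinite(X)
    keep = obs.any(axis=1)
    X, obs = X[keep], obs[keep]
    pats, inv = np.unique(obs, axis=0, return_inverse=True)
    out = []
    for p_idx in range(len(pats)):
        rows = X[inv == p_idx][:, pats[p_idx]]
        n = len(rows)
        m = rows.mean(axis=0)
        dev = rows - m
        S = dev.T @ dev / n
        out.append((pats[p_idx], n, m, S))
    return out, int(keep.sum())


def _nll_patterns(params, pstats, K):
    nu = params[:K]
    lam = params[K : 2 * K]
    log_th = np.clip(params[2 * K :], -30.0, 30.0)
    th = np.exp(log_th)
    total = 0.0
    for pat, n, m, S in pstats:
        lo = lam[pat]
        no = nu[pat]
        to = th[pat]
        k = pat.sum()
        Sig = np.outer(lo, lo) + np.diag(to)
        try:
            L = np.linalg.cholesky(Sig)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.log(np.diag(L)).sum()
        d = m - no
        sol_d = np.linalg.solve(L, d)
        sol_S = np.linalg.solve(L, np.linalg.solve(L, S).T)
        total += 0.5 * n * (
            k * np.log(2 * np.pi)
            + logdet
            + np.trace(sol_S)
            + sol_d @ sol_d
        )
    return total if np.isfinite(total) else 1e12


def fit_measurement(
    item_table: pd.DataFrame,
    domain: str,
    items=None,
    *,
    n_starts: int = 5,
    gtol: float = 1e-8,
    seed: int = 0,
) -> MeasurementModel:
    """ML fit of the pooled one-factor model for one domain.

    ``item_table`` is long format (participant_id, timepoint_day,
    item_id, value); absent rows encode missing items. ``items``
    restricts/orders the indicator set (default: every item_id present).
    Multi-start quasi-Newton with jittered restarts; the best
    log-likelihood is retained, with the sign convention that the first
    loading is positive.
    """
    if items is None:
        items = sorted(item_table["item_id"].unique())
    if len(items) < 2:
        raise IdentificationError(
            f"domain {domain!r} needs >=2 items, got {list(items)}"
        )
    X = _pivot_items(item_table, items).to_numpy(dtype=float)
    pstats, n_rows = _pattern_stats(X)
    K = len(items)

    # start values from pairwise-complete moments
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(X, axis=0)
        col_var = np.nanvar(X, axis=0)
    Xc = pd.DataFrame(X)
    R = Xc.corr(min_periods=2).to_numpy()
    R[~np.isfinite(R)] = 0.0
    np.fill_diagonal(R, 1.0)
    w, v = np.linalg.eigh(R)
    lam0 = v[:, -1] * np.sqrt(max(w[-1], 1e-3))
    if lam0[0] < 0:
        lam0 = -lam0
    lam0 = lam0 * np.sqrt(np.maximum(col_var, 1e-6))
    th0 = np.maximum(col_var - lam0**2, 0.05 * np.maximum(col_var, 1e-6))
    x0 = np.concatenate([col_mean, lam0, np.log(th0)])

    rng = np.random.default_rng(seed)
    best = None
    for s in range(n_starts):
        xs = x0 if s == 0 else x0 + rng.normal(scale=0.1, size=x0.size)
        res = optimize.minimize(
            _nll_patterns,
            xs,
            args=(pstats, K),
            method="BFGS",
            jac="3-point",
            options={"gtol": 1e-10, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res

    params = best.x
    g = optimize.approx_fprime(params, _nll_patterns, 1e-6, pstats, K)
    converged = np.max(np.abs(g)) <= max(
        gtol * max(1.0, abs(best.fun)), 1e-4 * max(1.0, abs(best.fun)) ** 0.5
    )
    nu = params[:K]
    lam = params[K : 2 * K]
    th = np.exp(np.clip(params[2 * K :], -30, 30))
    if lam[0] < 0:  # sign convention
        lam = -lam
    return MeasurementModel(
        domain=domain,
        items=list(items),
        loadings=lam,
        intercepts=nu,
        uniquenesses=th,
        loglik=-best.fun,
        converged=bool(converged),
        n_rows=n_rows,
    )


def measurement_loglik(model: MeasurementModel, item_table: pd.DataFrame) -> float:
    """Log-likelihood of an item table under a fitted model (FIML path)."""
    X = _pivot_items(item_table, model.items).to_numpy(dtype=float)
    pstats, _ = _pattern_stats(X)
    K = len(model.items)
    params = np.concatenate(
        [model.intercepts, model.loadings, np.log(model.uniquenesses)]
    )
    return -float(_nll_patterns(params, pstats, K))


def factor_scores(model: MeasurementModel, item_table: pd.DataFrame) -> pd.DataFrame:
    """Regression-method factor scores per (participant, timepoint) row.

    Rows observing no item of the domain get a missing score.
    """
    wide = _pivot_items(item_table, model.items)
    X = wide.to_numpy(dtype=float)
    obs = np.isfinite(X)
    scores = np.full(len(X), np.nan)
    pats, inv = np.unique(obs, axis=0, return_inverse=True)
    lam, nu, th = model.loadings, model.intercepts, model.uniquenesses
    for p_idx, pat in enumerate(pats):
        if not pat.any():
            continue
        lo, no, to = lam[pat], nu[pat], th[pat]
        Sig = np.outer(lo, lo) + np.diag(to)
        a = np.linalg.solve(Sig, lo)  # lambda_o' Sigma_o^{-1}
        rows = inv == p_idx
        scores[rows] = (X[rows][:, pat] - no) @ a
    out = wide.index.to_frame(index=False)
    out["domain"] = model.domain
    out["score"] = scores
    return out


# ---------------------------------------------------------------------------
# multi-domain convenience


def infer_domain_spec(item_table: pd.DataFrame) -> dict:
    """Recover domain -> items from ``<domain>_it<k>`` item identifiers."""
    spec = {}
    for item in sorted(item_table["item_id"].unique()):
        if "_it" not in item:
            raise ValueError(
                f"cannot infer domain from item_id {item!r}; provide a domain_spec"
            )
        dom = item.rsplit("_it", 1)[0]
        spec.setdefault(dom, []).append(item)
    return spec


def fit_domains(item_table: pd.DataFrame, domain_spec=None, **kw) -> dict:
    """Fit one measurement model per domain; returns {domain: model}."""
    if domain_spec is None:
        domain_spec = infer_domain_spec(item_table)
    models = {}
    for dom, items in domain_spec.items():
        sub = item_table[item_table["item_id"].isin(items)]
        models[dom] = fit_measurement(sub, dom, items=items, **kw)
    return models


def score_domains(models: dict, item_table: pd.DataFrame) -> pd.DataFrame:
    """Stack factor scores for all domains into one long table."""
    frames = []
    for dom, model in models.items():
        sub = item_table[item_table["item_id"].isin(model.items)]
        frames.append(factor_scores(model, sub))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["participant_id", "timepoint_day", "domain"], kind="stable"
    ).reset_index(drop=True)
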