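"""Bivariate linear mixed model for paired longitudinal observations.

For one (language feature, symptom domain) pair, observations are modeled
with correlated random intercepts and correlated occasion residuals::

    symptom_ij = mu_s + b_si + e_sij
    feature_ij = mu_f + b_fi + e_fij

    (b_si, b_fi) ~ N(0, D),   (e_sij, e_fij) ~ N(0, Sigma)

The off-diagonal elements of ``D`` and ``Sigma`` carry the two quantities
of interest:

* ``rho_b = D_sf / sqrt(D_ss * D_ff)`` — the between-subject
  (cross-sectional) correlation of stable levels, and
* ``rho_w = Sigma_sf / sqrt(Sigma_ss * Sigma_ff)`` — the within-subject
  (longitudinal) correlation of occasion-to-occasion deviations.

Estimation is full-information maximum likelihood (FIML): each
participant contributes the Gaussian density of whatever components were
observed (symptom only, feature only, or both, per timepoint), which is
valid under missing-at-random. Covariances are parameterized through
their log-Cholesky factors so the optimization is unconstrained.

The likelihood is evaluated in closed form. Within a participant the
marginal covariance of the stacked observed vector is
``Z D Z' + blockdiag(Sigma_obs)``; the Woodbury identity reduces every
participant to a 2x2 core, and participants sharing the same counts of
(both / symptom-only / feature-only) timepoints collapse onto shared
sufficient statistics, so one likelihood evaluation costs O(#groups)
regardless of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BlmmParameters",
    "BlmmFit",
    "fit_blmm",
    "fit_blmm_pairs",
    "blmm_loglik",
    "loglik_direct",
    "lrt_rho",
]

_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e12


# ---------------------------------------------------------------------------
# parameters


@dataclass
class BlmmParameters:
    """Means plus random-intercept and residual covariance matrices."""

    mu_s: float
    mu_f: float
    D: np.ndarray  # 2x2 random-intercept covariance
    Sigma: np.ndarray  # 2x2 occasion-residual covariance

    @property
    def rho_b(self) -> float:
        return self.D[0, 1] / np.sqrt(self.D[0, 0] * self.D[1, 1])

    @property
    def rho_w(self) -> float:
        return self.Sigma[0, 1] / np.sqrt(self.Sigma[0, 0] * self.Sigma[1, 1])

    def to_theta(self) -> np.ndarray:
        """Pack into the unconstrained log-Cholesky vector (length 8)."""
        ld = np.linalg.cholesky(self.D)
        ls = np.linalg.cholesky(self.Sigma)
        return np.array(
            [
                self.mu_s,
                self.mu_f,
                np.log(ld[0, 0]),
                ld[1, 0],
                np.log(ld[1, 1]),
                np.log(ls[0, 0]),
                ls[1, 0],
                np.log(ls[1, 1]),
            ]
        )

    @classmethod
    def from_theta(cls, theta: np.ndarray) -> "BlmmParameters":
        t = np.asarray(theta, dtype=float)
        ed1, d21, ed2 = np.exp(t[2]), t[3], np.exp(t[4])
        es1, s21, es2 = np.exp(t[5]), t[6], np.exp(t[7])
        D = np.array([[ed1**2, ed1 * d21], [ed1 * d21, d21**2 + ed2**2]])
        S = np.array([[es1**2, es1 * s21], [es1 * s21, s21**2 + es2**2]])
        return cls(mu_s=t[0], mu_f=t[1], D=D, Sigma=S)


@dataclass
class BlmmFit:
    """Result of a bivariate mixed-model fit."""

    params: BlmmParameters
    rho_b: float
    rho_w: float
    se_rho_b: float
    se_rho_w: float
    p_rho_b: float
    p_rho_w: float
    loglik: float
    n_participants: int
    n_obs: int
    converged: bool
    n_starts_used: int
    boundary: bool = False
    theta: np.ndarray = field(default=None, repr=False)

    def as_record(self) -> dict:
        return {
            "rho_b": self.rho_b,
            "rho_w": self.rho_w,
            "se_rho_b": self.se_rho_b,
            "se_rho_w": self.se_rho_w,
            "p_rho_b": self.p_rho_b,
            "p_rho_w": self.p_rho_w,
            "loglik": self.loglik,
            "n_participants": self.n_participants,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "boundary": self.boundary,
        }


# ---------------------------------------------------------------------------
# panel preparation and sufficient statistics


class PanelError(ValueError):
    """Raised when a panel cannot identify the model."""


def _prepare_panel(
    panel: pd.DataFrame,
    symptom: str = "symptom",
    feature: str = "marker",
    participant: str = "participant_id",
    timepoint: str = "timepoint_day",
    for_fit: bool = True,
):
    """Validate a long panel and return (pid codes, s, f) arrays.

    Identification checks (>=2 participants, a participant with repeated
    measures, non-degenerate series) apply only when preparing a fit;
    plain likelihood evaluation accepts any non-empty panel.
    """
    for col in (participant, timepoint, symptom, feature):
        if col not in panel.columns:
            raise PanelError(f"panel is missing required column {col!r}")
    if panel.duplicated([participant, timepoint]).any():
        raise PanelError("panel has duplicate (participant, timepoint) rows")
    s = panel[symptom].to_numpy(dtype=float)
    f = panel[feature].to_numpy(dtype=float)
    keep = np.isfinite(s) | np.isfinite(f)
    s, f = s[keep], f[keep]
    pid, _ = pd.factorize(panel.loc[keep, participant])
    return _validate_arrays(pid, s, f, for_fit=for_fit)


def _validate_arrays(pid, s, f, for_fit=True):
    pid = np.asarray(pid)
    if len(pid) == 0:
        raise PanelError("panel has no observed rows")
    if not for_fit:
        return pid, s, f
    n = int(pid.max()) + 1
    if n < 2:
        raise PanelError("at least 2 participants are required")
    counts = np.bincount(pid, minlength=n)
    if counts.max() < 2:
        raise PanelError(
            "no participant has >=2 timepoints; D and Sigma are not "
            "separately identified"
        )
    for name, x in (("symptom", s), ("feature", f)):
        obs = x[np.isfinite(x)]
        if obs.size == 0 or np.ptp(obs) == 0.0:
            raise PanelError(f"{name} series has zero variance (or no data)")
    return pid, s, f


def _panel_stats(pid, s, f):
    """Collapse a panel to per-(n_both, n_sonly, n_fonly) group statistics.

    Returns a dict of arrays keyed per group g:
      nb, ns, nf  - timepoint counts shared by every participant in g
      N           - number of participants in g
      sumA (G,4)  - sum over participants of a_i = (Ss, Sf, Ts, Tf)
                    (sums of s and f over both-observed rows, then over
                    single-observed rows)
      Saa (G,4,4) - sum of outer(a_i, a_i)
      sq (G,5)    - sums of squares/cross-products:
                    (ss², s·f, ff²) on both rows, s² on s-only, f² on f-only
    """
    obs_s = np.isfinite(s)
    obs_f = np.isfinite(f)
    both = obs_s & obs_f
    so = obs_s & ~obs_f
    fo = obs_f & ~obs_s
    n = int(pid.max()) + 1

    def agg(mask, w=None):
        if w is None:
            return np.bincount(pid[mask], minlength=n).astype(float)
        return np.bincount(pid[mask], weights=w[mask], minlength=n)

    nb = agg(both)
    ns = agg(so)
    nf = agg(fo)
    a = np.column_stack(
        [agg(both, s), agg(both, f), agg(so, s), agg(fo, f)]
    )  # (n, 4)
    sq = np.column_stack(
        [
            agg(both, s * s),
            agg(both, s * f),
            agg(both, f * f),
            agg(so, s * s),
            agg(fo, f * f),
        ]
    )  # (n, 5)

    key = np.stack([nb, ns, nf], axis=1)
    ukey, inv = np.unique(key, axis=0, return_inverse=True)
    G = len(ukey)
    N = np.bincount(inv, minlength=G).astype(float)
    sumA = np.zeros((G, 4))
    np.add.at(sumA, inv, a)
    Saa = np.zeros((G, 4, 4))
    np.add.at(Saa, inv, a[:, :, None] * a[:, None, :])
    sqg = np.zeros((G, 5))
    np.add.at(sqg, inv, sq)
    return {
        "nb": ukey[:, 0],
        "ns": ukey[:, 1],
        "nf": ukey[:, 2],
        "N": N,
        "sumA": sumA,
        "Saa": Saa,
        "sq": sqg,
        "n_participants": n,
        "n_obs": int(2 * nb.sum() + ns.sum() + nf.sum()),
    }


def _stack_stats(stats_list):
    """Pad per-panel group statistics into (B, G, ...) arrays.

    Zero-padding is exact: an all-zero group contributes 0 to the
    log-likelihood, so no mask is needed.
    """
    B = len(stats_list)
    G = max(len(st["N"]) for st in stats_list)
    out = {
        "nb": np.zeros((B, G)),
        "ns": np.zeros((B, G)),
        "nf": np.zeros((B, G)),
        "N": np.zeros((B, G)),
        "sumA": np.zeros((B, G, 4)),
        "Saa": np.zeros((B, G, 4, 4)),
        "sq": np.zeros((B, G, 5)),
    }
    for b, st in enumerate(stats_list):
        g = len(st["N"])
        for k in ("nb", "ns", "nf", "N"):
            out[k][b, :g] = st[k]
        out["sumA"][b, :g] = st["sumA"]
        out["Saa"][b, :g] = st["Saa"]
        out["sq"][b, :g] = st["sq"]
    return out


# ---------------------------------------------------------------------------
# likelihood


def _negloglik_batch(theta, st):
    """Negative log-likelihood for B panels at B parameter vectors.

    theta: (B, 8); st: stacked stats with (B, G, ...) arrays. Returns (B,).
    """
    theta = np.atleast_2d(theta)
    with np.errstate(all="ignore"):
        mu_s = theta[:, 0:1]
        mu_f = theta[:, 1:2]
        ed1 = np.exp(theta[:, 2])
        d21 = theta[:, 3]
        ed2 = np.exp(theta[:, 4])
        es1 = np.exp(theta[:, 5])
        s21 = theta[:, 6]
        es2 = np.exp(theta[:, 7])

        D11 = ed1**2
        D12 = ed1 * d21
        D22 = d21**2 + ed2**2
        S11 = es1**2
        S12 = es1 * s21
        S22 = s21**2 + es2**2
        detS = (es1 * es2) ** 2
        ldS = 2.0 * (theta[:, 5] + theta[:, 7])
        Si11 = S22 / detS
        Si12 = -S12 / detS
        Si22 = S11 / detS

        nb, ns, nf, N = st["nb"], st["ns"], st["nf"], st["N"]
        sumA, Saa, sq = st["sumA"], st["Saa"], st["sq"]

        c = lambda x: x[:, None]  # (B,) -> (B,1) for group broadcasting

        M11 = nb * c(Si11) + ns / c(S11)
        M12 = nb * c(Si12)
        M22 = nb * c(Si22) + nf / c(S22)

        A11 = 1.0 + c(D11) * M11 + c(D12) * M12
        A12 = c(D11) * M12 + c(D12) * M22
        A21 = c(D12) * M11 + c(D22) * M12
        A22 = 1.0 + c(D12) * M12 + c(D22) * M22
        detA = A11 * A22 - A12 * A21

        # K = A^{-1} D (2x2 per (B,G))
        K11 = (A22 * c(D11) - A12 * c(D12)) / detA
        K12 = (A22 * c(D12) - A12 * c(D22)) / detA
        K21 = (A11 * c(D12) - A21 * c(D11)) / detA
        K22 = (A11 * c(D22) - A21 * c(D12)) / detA

        # centered first/second moments of per-participant sum vectors
        m = np.stack([nb * mu_s, nb * mu_f, ns * mu_s, nf * mu_f], axis=-1)
        Shh = (
            Saa
            - m[..., :, None] * sumA[..., None, :]
            - sumA[..., :, None] * m[..., None, :]
            + N[..., None, None] * m[..., :, None] * m[..., None, :]
        )
        Grow = np.zeros(theta.shape[:1] + (2, 4))
        Grow[:, 0, 0] = Si11
        Grow[:, 0, 1] = Si12
        Grow[:, 0, 2] = 1.0 / S11
        Grow[:, 1, 0] = Si12
        Grow[:, 1, 1] = Si22
        Grow[:, 1, 3] = 1.0 / S22
        Suu = np.einsum("bri,bgij,bsj->bgrs", Grow, Shh, Grow)

        quad_red = (
            K11 * Suu[..., 0, 0]
            + K12 * Suu[..., 1, 0]
            + K21 * Suu[..., 0, 1]
            + K22 * Suu[..., 1, 1]
        )

        Qb11 = sq[..., 0] - 2.0 * mu_s * sumA[..., 0] + N * nb * mu_s**2
        Qb12 = (
            sq[..., 1]
            - mu_s * sumA[..., 1]
            - mu_f * sumA[..., 0]
            + N * nb * mu_s * mu_f
        )
        Qb22 = sq[..., 2] - 2.0 * mu_f * sumA[..., 1] + N * nb * mu_f**2
        qs = sq[..., 3] - 2.0 * mu_s * sumA[..., 2] + N * ns * mu_s**2
        qf = sq[..., 4] - 2.0 * mu_f * sumA[..., 3] + N * nf * mu_f**2
        q = (
            c(Si11) * Qb11
            + 2.0 * c(Si12) * Qb12
            + c(Si22) * Qb22
            + qs / c(S11)
            + qf / c(S22)
        )

        n_obs = N * (2.0 * nb + ns + nf)
        logdet = N * (
            nb * c(ldS) + ns * c(np.log(S11)) + nf * np.log(S22)[:, None]
        ) + N * np.log(detA)
        nll = 0.5 * np.sum(
            n_obs * _LOG2PI + logdet + q - quad_red, axis=-1
        )
    return np.where(np.isfinite(nll), nll, _BIG)


def _panel_is_empty(panel, cols):
    s = panel.get(cols.get("symptom", "symptom"))
    f = panel.get(cols.get("feature", "marker"))
    if s is None or f is None or len(panel) == 0:
        return True
    return not (np.isfinite(s.to_numpy(float)) | np.isfinite(f.to_numpy(float))).any()


def blmm_loglik(params: BlmmParameters, panel: pd.DataFrame, **cols) -> float:
    """Log-likelihood of a panel at given parameters (the fitter's own path)."""
    if _panel_is_empty(panel, cols):
        return 0.0  # an empty product of densities
    pid, s, f = _prepare_panel(panel, for_fit=False, **cols)
    st = _stack_stats([_panel_stats(pid, s, f)])
    return -float(_negloglik_batch(params.to_theta()[None, :], st)[0])


def loglik_direct(params: BlmmParameters, panel: pd.DataFrame, **cols) -> float:
    """Brute-force likelihood: dense per-participant covariance matrices.

    Builds, for every participant, the full 2T x 2T joint covariance
    ``ones(T,T) (x) D + I_T (x) Sigma``, drops unobserved entries, and sums
    multivariate-normal log-densities. No structure is exploited; this is
    the independent oracle used in tests.
    """
    if _panel_is_empty(panel, cols):
        return 0.0
    pid, s, f = _prepare_panel(panel, for_fit=False, **cols)
    mu = np.array([params.mu_s, params.mu_f])
    total = 0.0
    for i in np.unique(pid):
        rows = np.where(pid == i)[0]
        T = len(rows)
        cov = np.kron(np.ones((T, T)), params.D) + np.kron(
            np.eye(T), params.Sigma
        )
        y = np.empty(2 * T)
        y[0::2] = s[rows]
        y[1::2] = f[rows]
        obs = np.isfinite(y)
        mean = np.tile(mu, T)
        total += stats.multivariate_normal.logpdf(
            y[obs], mean=mean[obs], cov=cov[np.ix_(obs, obs)]
        )
    return float(total)


# ---------------------------------------------------------------------------
# initialization


def _chol_theta(mu_s, mu_f, D, S):
    D = _nearest_pd(D)
    S = _nearest_pd(S)
    ld = np.linalg.cholesky(D)
    ls = np.linalg.cholesky(S)
    return np.array(
        [
            mu_s,
            mu_f,
            np.log(ld[0, 0]),
            ld[1, 0],
            np.log(ld[1, 1]),
            np.log(ls[0, 0]),
            ls[1, 0],
            np.log(ls[1, 1]),
        ]
    )


def _nearest_pd(C, floor=1e-4, max_corr=0.95):
    """Clip a symmetric 2x2 toward positive definiteness."""
    C = np.asarray(C, dtype=float).copy()
    C[0, 0] = max(C[0, 0], floor)
    C[1, 1] = max(C[1, 1], floor)
    lim = max_corr * np.sqrt(C[0, 0] * C[1, 1])
    off = np.clip(C[0, 1], -lim, lim)
    C[0, 1] = C[1, 0] = off
    return C


def _moment_init(pid, s, f):
    """Method-of-moments start: between/within sample covariances."""
    n = int(pid.max()) + 1
    obs_s, obs_f = np.isfinite(s), np.isfinite(f)
    mu_s = s[obs_s].mean()
    mu_f = f[obs_f].mean()

    def within_var(x, obs):
        cnt = np.bincount(pid[obs], minlength=n)
        sm = np.bincount(pid[obs], weights=x[obs], minlength=n)
        with np.errstate(invalid="ignore"):
            pm = np.where(cnt > 0, sm / np.maximum(cnt, 1), 0.0)
        dev = x[obs] - pm[pid[obs]]
        dof = max(obs.sum() - (cnt > 0).sum(), 1)
        return float((dev**2).sum() / dof), pm, cnt

    vs, pm_s, cnt_s = within_var(s, obs_s)
    vf, pm_f, cnt_f = within_var(f, obs_f)

    both = obs_s & obs_f
    if both.sum() > n:
        cb = np.bincount(pid[both], minlength=n)
        ms = np.bincount(pid[both], weights=s[both], minlength=n) / np.maximum(
            cb, 1
        )
        mf = np.bincount(pid[both], weights=f[both], minlength=n) / np.maximum(
            cb, 1
        )
        dev = (s[both] - ms[pid[both]]) * (f[both] - mf[pid[both]])
        vsf = float(dev.sum() / max(both.sum() - (cb > 0).sum(), 1))
    else:
        vsf = 0.0
    Sigma = np.array([[vs, vsf], [vsf, vf]])

    ok_s, ok_f = cnt_s > 0, cnt_f > 0
    bs = float(np.var(pm_s[ok_s])) - vs * float(np.mean(1.0 / cnt_s[ok_s]))
    bf = float(np.var(pm_f[ok_f])) - vf * float(np.mean(1.0 / cnt_f[ok_f]))
    okb = ok_s & ok_f
    if okb.sum() > 1:
        bsf = float(
            np.mean(
                (pm_s[okb] - pm_s[okb].mean()) * (pm_f[okb] - pm_f[okb].mean())
            )
        )
    else:
        bsf = 0.0
    D = np.array([[bs, bsf], [bsf, bf]])
    return _chol_theta(mu_s, mu_f, D, Sigma)


def _balanced_mle(pid, s, f):
    """Exact MLE for complete balanced panels, or None if inapplicable.

    With every participant observing both variables at the same number of
    timepoints J, the likelihood factors into independent Wishart pieces:
    Sigma_hat = W/(n(J-1)) from within-person deviations and
    Sigma_hat + J*D_hat = J*B/n from person means. Valid when the implied
    D_hat is positive definite.
    """
    if not (np.isfinite(s).all() and np.isfinite(f).all()):
        return None
    n = int(pid.max()) + 1
    cnt = np.bincount(pid, minlength=n)
    J = cnt[0]
    if J < 2 or not (cnt == J).all():
        return None
    Y = np.column_stack([s, f])
    order = np.argsort(pid, kind="stable")
    Yg = Y[order].reshape(n, J, 2)
    ybar_i = Yg.mean(axis=1)
    mu = ybar_i.mean(axis=0)
    dev_w = Yg - ybar_i[:, None, :]
    W = np.einsum("ijk,ijl->kl", dev_w, dev_w)
    dev_b = ybar_i - mu
    Bm = dev_b.T @ dev_b
    Sigma = W / (n * (J - 1))
    D = (J * Bm / n - Sigma) / J
    if np.linalg.eigvalsh(D).min() <= 1e-8 or np.linalg.eigvalsh(Sigma).min() <= 1e-8:
        return None
    return _chol_theta(mu[0], mu[1], D, Sigma)


# ---------------------------------------------------------------------------
# derivatives (numeric) and inference helpers


def _grad_central(fun, x, rel_step=3e-6):
    x = np.asarray(x, dtype=float)
    h = rel_step * np.maximum(1.0, np.abs(x))
    g = np.empty_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        g[i] = (fun(xp) - fun(xm)) / (2.0 * h[i])
    return g


def _hessian_central(fun, x, rel_step=1e-4):
    x = np.asarray(x, dtype=float)
    p = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = fun(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (fun(x + ei) - 2.0 * f0 + fun(x - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej)
                - fun(x + ei - ej)
                - fun(x - ei + ej)
                + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def _rho_grad(t, u_log):
    """d rho / d (offdiag chol, log diag chol) for rho = t/sqrt(t^2+u^2)."""
    u = np.exp(u_log)
    den = (t**2 + u**2) ** 1.5
    return u**2 / den, -t * u**2 / den


def _rho_from_theta(theta):
    t = np.asarray(theta)
    rho_b = t[..., 3] / np.hypot(t[..., 3], np.exp(t[..., 4]))
    rho_w = t[..., 6] / np.hypot(t[..., 6], np.exp(t[..., 7]))
    return rho_b, rho_w


def _wald_from_cov(theta, cov):
    """Delta-method SEs and two-sided p-values for rho_b and rho_w."""
    rho_b, rho_w = _rho_from_theta(theta)
    out = {}
    for name, rho, idx in (
        ("rho_b", rho_b, (3, 4)),
        ("rho_w", rho_w, (6, 7)),
    ):
        g1, g2 = _rho_grad(theta[idx[0]], theta[idx[1]])
        sub = cov[np.ix_(idx, idx)]
        var = g1 * g1 * sub[0, 0] + 2 * g1 * g2 * sub[0, 1] + g2 * g2 * sub[1, 1]
        se = np.sqrt(var) if var > 0 else np.nan
        if abs(rho) >= 0.999 or not np.isfinite(se):
            se, p = np.nan, np.nan
        else:
            p = 2.0 * stats.norm.sf(abs(rho) / se)
        out[name] = (float(rho), float(se), float(p))
    return out


# ---------------------------------------------------------------------------
# single-panel fit


def fit_blmm(
    panel: pd.DataFrame,
    *,
    n_starts: int = 5,
    gtol: float = 1e-8,
    seed: int = 0,
    se: bool = True,
    timepoint_means: bool = False,
    **cols,
) -> BlmmFit:
    """Fit the bivariate mixed model to one (feature, domain) panel by FIML.

    ``panel`` is long format with one row per (participant, timepoint)
    and columns ``participant_id, timepoint_day, symptom, marker``
    (names overridable via keyword arguments). Either value may be
    missing on any row; rows missing both are ignored.

    Optimization runs quasi-Newton on the log-Cholesky scale from a
    method-of-moments start (the exact MLE for complete balanced data)
    plus ``n_starts - 1`` jittered restarts; the best log-likelihood is
    kept. ``gtol`` is relative to the magnitude of the log-likelihood.
    Standard errors for the two correlations come from the observed
    information matrix via the delta method; Wald p-values are two-sided.

    With ``timepoint_means=True`` the symptom mean is allowed to differ
    by timepoint (severity declines over a post-trauma study, so the
    shared trend otherwise inflates the residual variance slightly);
    the default keeps a single overall mean per variable, matching the
    plain bivariate-correlation formulation.
    """
    tp_col = cols.get("timepoint", "timepoint_day")
    sym_col = cols.get("symptom", "symptom")
    pid, s, f = _prepare_panel(panel, **cols)
    st = _panel_stats(pid, s, f)
    stk = _stack_stats([st])

    if timepoint_means:
        keep = (
            np.isfinite(panel[sym_col].to_numpy(dtype=float))
            | np.isfinite(panel[cols.get("feature", "marker")].to_numpy(dtype=float))
        )
        tp_codes, tp_levels = pd.factorize(
            panel.loc[keep, tp_col], sort=True
        )
        n_tau = len(tp_levels) - 1  # offsets relative to the first timepoint

        def nll(th):
            tau = np.concatenate([[0.0], th[8 : 8 + n_tau]])
            s_adj = s - tau[tp_codes]
            st_adj = _stack_stats([_panel_stats(pid, s_adj, f)])
            return float(_negloglik_batch(th[None, :8], st_adj)[0])

    else:
        n_tau = 0

        def nll(th):
            return float(_negloglik_batch(th[None, :8], stk)[0])

    theta0 = _balanced_mle(pid, s, f)
    exact_start = theta0 is not None and not timepoint_means
    if theta0 is None:
        theta0 = _moment_init(pid, s, f)
    theta0 = np.concatenate([theta0, np.zeros(n_tau)])

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(theta0 + rng.normal(scale=0.2, size=theta0.size))

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = optimize.minimize(
            nll, x0, method="BFGS", jac="3-point",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if exact_start and n_used == 1 and _gradient_ok(nll, best, gtol):
            break  # started at the closed-form MLE and it is stationary

    theta = best.x
    converged = _gradient_ok(nll, best, gtol)
    ll = -best.fun

    rho_b, rho_w = _rho_from_theta(theta[:8])
    boundary = abs(rho_b) >= 0.999 or abs(rho_w) >= 0.999
    if se and not boundary:
        H = _hessian_central(nll, theta)
        cov = _safe_inv(H)[:8, :8]
        wald = _wald_from_cov(theta[:8], cov)
    else:
        wald = {
            "rho_b": (float(rho_b), np.nan, np.nan),
            "rho_w": (float(rho_w), np.nan, np.nan),
        }
    return BlmmFit(
        params=BlmmParameters.from_theta(theta),
        rho_b=wald["rho_b"][0],
        rho_w=wald["rho_w"][0],
        se_rho_b=wald["rho_b"][1],
        se_rho_w=wald["rho_w"][1],
        p_rho_b=wald["rho_b"][2],
        p_rho_w=wald["rho_w"][2],
        loglik=ll,
        n_participants=st["n_participants"],
        n_obs=st["n_obs"],
        converged=bool(converged),
        n_starts_used=n_used,
        boundary=bool(boundary),
        theta=theta,
    )


def _gradient_ok(nll, res, gtol):
    # gtol is relative to the log-likelihood magnitude, floored at the
    # resolution of the central-difference gradient itself
    g = _grad_central(nll, res.x)
    tol = max(gtol * max(1.0, abs(res.fun)), 1e-6 * max(1.0, abs(res.fun)) ** 0.5)
    return np.max(np.abs(g)) <= tol


def _safe_inv(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# likelihood-ratio test


def lrt_rho(panel: pd.DataFrame, which: str, *, seed: int = 0, **cols):
    """Likelihood-ratio test of rho_b = 0 (between) or rho_w = 0 (within).

    Refits with the relevant covariance off-diagonal pinned to zero;
    the statistic 2*(ll_full - ll_constrained) is referred to chi2(1).
    Returns (statistic, p). Alternative to the Wald test.
    """
    if which not in ("between", "within"):
        raise ValueError("which must be 'between' or 'within'")
    fix = 3 if which == "between" else 6
    pid, s, f = _prepare_panel(panel, **cols)
    stk = _stack_stats([_panel_stats(pid, s, f)])

    def nll(th):
        return float(_negloglik_batch(th[None, :], stk)[0])

    full = fit_blmm(panel, seed=seed, se=False, **cols)
    free = [i for i in range(8) if i != fix]

    def nll_con(sub):
        th = np.zeros(8)
        th[free] = sub
        return nll(th)

    x0 = full.theta[free]
    res = optimize.minimize(
        nll_con, x0, method="BFGS", jac="3-point",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    if not np.isfinite(res.fun):
        return np.nan, np.nan
    stat = max(0.0, 2.0 * (full.loglik - (-res.fun)))
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# batched fitting across many (feature, domain) pairs


def _grad_batch(theta, st, rel_step=3e-6):
    """Central-difference gradient for a batch: (B, 8)."""
    B, P = theta.shape
    g = np.empty((B, P))
    h = rel_step * np.maximum(1.0, np.abs(theta))
    for i in range(P):
        tp = theta.copy()
        tm = theta.copy()
        tp[:, i] += h[:, i]
        tm[:, i] -= h[:, i]
        g[:, i] = (_negloglik_batch(tp, st) - _negloglik_batch(tm, st)) / (
            2.0 * h[:, i]
        )
    return g


def _minimize_batch(st, x0, gtol=1e-6, maxiter=60):
    """Vectorized BFGS across B independent 8-parameter problems."""
    x = x0.copy()
    B, P = x.shape
    I = np.eye(P)[None, :, :]
    Hinv = np.repeat(I, B, axis=0)
    fx = _negloglik_batch(x, st)
    g = _grad_batch(x, st)
    active = np.ones(B, dtype=bool)
    for _ in range(maxiter):
        scale = np.maximum(1.0, np.abs(fx))
        active &= np.max(np.abs(g), axis=1) > gtol * scale
        if not active.any():
            break
        d = -np.einsum("bij,bj->bi", Hinv, g)
        # backtracking line search (vectorized, Armijo)
        gd = np.einsum("bi,bi->b", g, d)
        t = np.ones(B)
        xn = x + t[:, None] * d
        fn = _negloglik_batch(xn, st)
        for _ in range(25):
            bad = active & ~(fn <= fx + 1e-4 * t * gd)
            if not bad.any():
                break
            t[bad] *= 0.5
            xn[bad] = x[bad] + t[bad, None] * d[bad]
            fn_bad = _negloglik_batch(xn[bad], st_subset(st, bad))
            fn[bad] = fn_bad
        gn = _grad_batch(xn, st)
        svec = xn - x
        yvec = gn - g
        sy = np.einsum("bi,bi->b", svec, yvec)
        upd = active & (sy > 1e-12)
        if upd.any():
            rhoq = np.zeros(B)
            rhoq[upd] = 1.0 / sy[upd]
            sy_outer = svec[:, :, None] * yvec[:, None, :]
            V = I - rhoq[:, None, None] * sy_outer
            Hn = (
                np.einsum("bij,bjk,blk->bil", V, Hinv, V)
                + rhoq[:, None, None] * svec[:, :, None] * svec[:, None, :]
            )
            Hinv[upd] = Hn[upd]
        move = active
        x[move] = xn[move]
        fx[move] = fn[move]
        g[move] = gn[move]
    scale = np.maximum(1.0, np.abs(fx))
    converged = np.max(np.abs(g), axis=1) <= gtol * scale
    return x, fx, converged


def st_subset(st, mask):
    return {k: v[mask] for k, v in st.items()}


def _hessian_batch(st, theta, rel_step=1e-4):
    B, P = theta.shape
    H = np.empty((B, P, P))
    h = rel_step * np.maximum(1.0, np.abs(theta))
    f0 = _negloglik_batch(theta, st)

    def ev(dx):
        return _negloglik_batch(theta + dx, st)

    for i in range(P):
        ei = np.zeros((B, P))
        ei[:, i] = h[:, i]
        H[:, i, i] = (ev(ei) - 2 * f0 + ev(-ei)) / h[:, i] ** 2
        for j in range(i):
            ej = np.zeros((B, P))
            ej[:, j] = h[:, j]
            H[:, i, j] = H[:, j, i] = (
                ev(ei + ej) - ev(ei - ej) - ev(-ei + ej) + ev(-ei - ej)
            ) / (4 * h[:, i] * h[:, j])
    return H


def fit_blmm_pairs(
    panel: pd.DataFrame,
    *,
    feature_col: str = "feature",
    domain_col: str = "domain",
    symptom: str = "symptom",
    marker: str = "marker",
    participant: str = "participant_id",
    timepoint: str = "timepoint_day",
    gtol: float = 1e-6,
    hessian_step: float = 1e-4,
) -> pd.DataFrame:
    """Fit the bivariate mixed model for every (feature, domain) pair.

    Same model and inference as :func:`fit_blmm`, but all pairs are
    optimized simultaneously with a vectorized quasi-Newton loop, which
    is what makes genome-scan-sized marker screens tractable. Returns
    one row per pair with estimates, SEs, Wald p-values, and metadata.
    Pairs whose panel cannot identify the model are returned with
    ``converged=False`` and NaN estimates.
    """
    keys = []
    stats_list = []
    inits = []
    meta = []
    bad = []
    for (feat, dom), grp in panel.groupby([feature_col, domain_col], sort=True):
        key = (feat, dom)
        try:
            pid, s, f = _prepare_panel(
                grp,
                symptom=symptom,
                feature=marker,
                participant=participant,
                timepoint=timepoint,
            )
        except PanelError:
            bad.append(key)
            continue
        st = _panel_stats(pid, s, f)
        th0 = _balanced_mle(pid, s, f)
        if th0 is None:
            th0 = _moment_init(pid, s, f)
        keys.append(key)
        stats_list.append(st)
        inits.append(th0)
        meta.append((st["n_participants"], st["n_obs"]))

    records = []
    if keys:
        stk = _stack_stats(stats_list)
        x0 = np.array(inits)
        theta, fx, conv = _minimize_batch(stk, x0, gtol=gtol)
        H = _hessian_batch(stk, theta, rel_step=hessian_step)
        for b, key in enumerate(keys):
            cov = _safe_inv(H[b])
            wald = _wald_from_cov(theta[b], cov)
            pars = BlmmParameters.from_theta(theta[b])
            records.append(
                {
                    "feature": key[0],
                    "domain": key[1],
                    "rho_b": wald["rho_b"][0],
                    "rho_w": wald["rho_w"][0],
                    "se_rho_b": wald["rho_b"][1],
                    "se_rho_w": wald["rho_w"][1],
                    "p_rho_b": wald["rho_b"][2],
                    "p_rho_w": wald["rho_w"][2],
                    "mu_s": pars.mu_s,
                    "mu_f": pars.mu_f,
                    "loglik": -fx[b],
                    "n_participants": meta[b][0],
                    "n_obs": meta[b][1],
                    "converged": bool(conv[b]),
                    "boundary": bool(
                        abs(wald["rho_b"][0]) >= 0.999
                        or abs(wald["rho_w"][0]) >= 0.999
                    ),
                }
            )
    for key in bad:
        records.append(
            {
                "feature": key[0],
                "domain": key[1],
                "rho_b": np.nan,
                "rho_w": np.nan,
                "se_rho_b": np.nan,
                "se_rho_w": np.nan,
                "p_rho_b": np.nan,
                "p_rho_w": np.nan,
                "mu_s": np.nan,
                "mu_f": np.nan,
                "loglik": np.nan,
                "n_participants": 0,
                "n_obs": 0,
                "converged": False,
                "boundary": False,
            }
        )
    out = pd.DataFrame.from_records(records)
    if len(out):
        out = out.sort_values(["feature", "domain"]).reset_index(drop=True)
    return out
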