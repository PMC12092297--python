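"""Synthetic smartphone-language cohort with known correlation structure.

Generates the three data streams the analysis pipeline consumes — daily
word bags, flash-survey item responses, and the supporting schedule /
device / completion tables — from a generative model that mirrors the
bivariate random-intercept model fitted downstream::

    severity_ijd = trend_j + b_id + e_ijd          (domain d)
    feature_icd  =           b_ic + e_ijc          (language category c)

Planted pairs (c, d) share correlated random intercepts (corr rho_b) and
correlated occasion residuals (corr rho_w); everything else is
independent. Survey items load on the severity factor through a
one-factor measurement model, and word bags are drawn from a
category-mixture multinomial whose category emission rates increase
monotonically (softmax link) with the latent category value. The ground
truth (latent values and planted correlations) is retained so every
downstream stage can be checked against what was planted, but is never
written into the pipeline's input files.

Nothing here attempts realistic natural language; only the statistical
structure the analysis assumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "CohortTables",
    "simulate_cohort",
    "simulate_bivariate_panel",
    "simulate_items",
    "write_fixture",
    "read_fixture",
    "DOMAINS",
    "CATEGORY_WORDS",
]

#: The ten symptom domains assessed by the flash surveys.
DOMAINS = (
    "pain",
    "depression",
    "sleep",
    "nightmares",
    "somatic",
    "thinking",
    "avoidance",
    "reexperiencing",
    "anxiety",
    "hyperarousal",
)

#: Toy vocabulary per language category; mirrored by the bundled lexicons.
CATEGORY_WORDS = {
    "pronoun_i": ["i", "me", "my", "mine", "myself"],
    "social": ["friend", "family", "mother", "father", "people", "together"],
    "negemo": ["sad", "angry", "hate", "hurt", "cry", "afraid", "worried"],
    "posemo": ["happy", "good", "love", "great", "glad", "hope"],
    "health": ["sick", "ill", "pain", "ache", "doctor", "tired", "hospital"],
    "cogproc": ["think", "know", "because", "reason", "understand", "cause"],
    "article": ["a", "an", "the"],
    "body": ["head", "arm", "leg", "heart", "stomach", "back", "hand"],
}

_OTHER_WORDS = [
    "go", "get", "see", "make", "time", "day", "work", "home", "come",
    "look", "want", "give", "use", "find", "tell", "call", "week", "year",
    "thing", "way", "place", "car", "food", "water", "door", "street",
]

_DEF_TIMEPOINTS = (7, 26, 45, 64, 84, 103, 122, 141, 161, 180)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults emulate the study conditions the pipeline targets: ten
    survey timepoints spanning days 7-180, a linearly declining latent
    severity trend, three survey items per domain with descending
    loadings, planned item-level missingness, and a median of ~150
    typed words per day.
    """

    n_participants: int = 200
    timepoints: tuple = _DEF_TIMEPOINTS
    n_features: int = 8
    planted_pairs: tuple = (
        ("negemo", "depression", 0.30, 0.15),
        ("health", "pain", 0.30, 0.20),
        ("social", "somatic", 0.25, 0.10),
    )
    n_domains: int = 10
    latent_trend: tuple | None = None  # default: linear decline +0.5 -> -0.5
    item_loadings: tuple = (0.8, 0.7, 0.6)
    item_noise_sd: tuple | None = None  # default: sqrt(1 - loading^2)
    missing_rate_survey: float = 0.15
    missing_rate_words: float = 0.20
    words_per_day_mean: float = 150.0
    word_link_scale: float = 0.8
    missing_mode: str = "mcar"  # or "mar"
    mar_strength: float = 1.0
    ar_rho: float = 0.0  # serial correlation hook for occasion residuals
    seed: int = 0
    enroll_start: str = "2024-01-01"
    enroll_span_days: int = 90

    @property
    def domains(self):
        return DOMAINS[: self.n_domains]

    @property
    def features(self):
        return tuple(list(CATEGORY_WORDS)[: self.n_features])

    @property
    def trend(self):
        if self.latent_trend is not None:
            return np.asarray(self.latent_trend, dtype=float)
        return np.linspace(0.5, -0.5, len(self.timepoints))

    def resolve_pairs(self):
        """Planted pairs as (feature_name, domain_name, rho_b, rho_w)."""
        feats, doms = self.features, self.domains
        out = []
        for fe, do, rb, rw in self.planted_pairs:
            fe = feats[fe] if isinstance(fe, int) else fe
            do = doms[do] if isinstance(do, int) else do
            out.append((fe, do, float(rb), float(rw)))
        return out

    def validate(self):
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        tps = np.asarray(self.timepoints)
        if not (np.diff(tps) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if not 0 <= self.missing_rate_survey <= 1:
            raise ValueError("missing_rate_survey must be in [0, 1]")
        if not 0 <= self.missing_rate_words <= 1:
            raise ValueError("missing_rate_words must be in [0, 1]")
        if len(self.trend) != len(tps):
            raise ValueError("latent_trend length must match timepoints")
        for fe, do, rb, rw in self.resolve_pairs():
            if fe not in self.features or do not in self.domains:
                raise ValueError(f"unknown planted pair ({fe}, {do})")
            for r in (rb, rw):
                if not -1 <= r <= 1:
                    raise ValueError("planted correlations must lie in [-1, 1]")
        # implied joint covariances must be positive definite
        for which in ("b", "w"):
            C = self._joint_cov(which)
            if np.linalg.eigvalsh(C).min() <= 1e-10:
                raise ValueError(
                    f"planted rho_{which} values imply a non-positive-definite "
                    "covariance"
                )
        return self

    def _joint_cov(self, which):
        doms, feats = list(self.domains), list(self.features)
        V = len(doms) + len(feats)
        C = np.eye(V)
        col = 2 if which == "b" else 3
        for fe, do, rb, rw in self.resolve_pairs():
            r = (rb, rw)[col - 2]
            i, j = doms.index(do), len(doms) + feats.index(fe)
            C[i, j] = C[j, i] = r
        return C


@dataclass
class GroundTruth:
    """Latent quantities retained for verification; not a pipeline input."""

    severity: pd.DataFrame  # participant_id, timepoint_day, domain, value
    features: pd.DataFrame  # participant_id, date, feature, value
    planted_pairs: list
    config: SimConfig


@dataclass
class CohortTables:
    word_bags: pd.DataFrame
    survey_items: pd.DataFrame
    schedule: pd.DataFrame
    device_log: pd.DataFrame
    completion: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# low-level draws


def _corr_pair_draw(rng, n, rho):
    """(n, 2) standard-normal draws with correlation rho; |rho|=1 allowed."""
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    return np.column_stack([z1, rho * z1 + np.sqrt(max(0.0, 1 - rho**2)) * z2])


def simulate_bivariate_panel(
    n_participants: int,
    n_timepoints: int,
    rho_b: float,
    rho_w: float,
    *,
    mu=(0.0, 0.0),
    sd_b=(1.0, 1.0),
    sd_w=(1.0, 1.0),
    trend=None,
    missing_rate: float = 0.0,
    seed=None,
    rng=None,
) -> pd.DataFrame:
    """Draw one (symptom, marker) panel from the bivariate intercept model.

    This is the generative mirror of the model :func:`langmark.blmm.fit_blmm`
    estimates, used for parameter-recovery and calibration studies. The
    boundary values ``rho = +/-1`` are permitted (the two deviation series
    become identical up to scale). ``missing_rate`` deletes each observed
    cell independently (missing completely at random).
    """
    if n_participants <= 0:
        raise ValueError("n_participants must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    n, J = n_participants, n_timepoints
    b = _corr_pair_draw(rng, n, rho_b) * np.asarray(sd_b)
    e = _corr_pair_draw(rng, n * J, rho_w).reshape(n, J, 2) * np.asarray(sd_w)
    tr = np.zeros(J) if trend is None else np.asarray(trend, dtype=float)
    s = mu[0] + tr[None, :] + b[:, None, 0] + e[:, :, 0]
    f = mu[1] + b[:, None, 1] + e[:, :, 1]
    if missing_rate > 0:
        s = np.where(rng.random((n, J)) < missing_rate, np.nan, s)
        f = np.where(rng.random((n, J)) < missing_rate, np.nan, f)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n), J),
            "timepoint_day": np.tile(np.arange(J), n),
            "symptom": s.ravel(),
            "marker": f.ravel(),
        }
    )


def simulate_items(
    n_rows: int,
    loadings,
    *,
    noise_sd=None,
    missing_rate: float = 0.0,
    seed=None,
    rng=None,
):
    """Draw one-factor item responses ``x_k = loading_k * eta + noise``.

    Returns ``(X, eta)`` with ``eta ~ N(0, 1)``. Default noise makes each
    item unit-variance (``noise_sd = sqrt(1 - loading^2)``). Used for
    measurement-model recovery checks.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lam = np.asarray(loadings, dtype=float)
    if noise_sd is None:
        noise_sd = np.sqrt(np.clip(1.0 - lam**2, 1e-12, None))
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), lam.shape)
    eta = rng.standard_normal(n_rows)
    X = eta[:, None] * lam[None, :] + rng.standard_normal(
        (n_rows, lam.size)
    ) * noise_sd[None, :]
    if missing_rate > 0:
        X = np.where(rng.random(X.shape) < missing_rate, np.nan, X)
    return X, eta


# ---------------------------------------------------------------------------
# cohort generation


def simulate_cohort(config: SimConfig) -> CohortTables:
    """Generate the full synthetic cohort from a validated configuration.

    Identical seeds produce byte-identical tables. Independent RNG
    streams (derived from the single seed by fixed spawn order) drive
    the latent draws, item noise, word emission, missingness, and
    enrollment dates, so enabling one stream never perturbs another.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_items, rng_words, rng_miss, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    doms = list(config.domains)
    feats = list(config.features)
    nD, nF = len(doms), len(feats)
    n = config.n_participants
    tps = np.asarray(config.timepoints)
    J = len(tps)
    trend = config.trend

    Lb = np.linalg.cholesky(config._joint_cov("b"))
    Lw = np.linalg.cholesky(config._joint_cov("w"))
    b = rng_latent.standard_normal((n, nD + nF)) @ Lb.T
    e = rng_latent.standard_normal((n, J, nD + nF)) @ Lw.T
    if config.ar_rho:
        # optional serial correlation in occasion residuals (misspecification
        # probe; the fitted model assumes independence across timepoints)
        a = config.ar_rho
        for j in range(1, J):
            e[:, j] = a * e[:, j - 1] + np.sqrt(1 - a**2) * e[:, j]

    sev = trend[None, :, None] + b[:, None, :nD] + e[:, :, :nD]  # (n, J, nD)
    feat_occ = b[:, None, nD:] + e[:, :, nD:]  # (n, J, nF) at survey occasions

    enroll = pd.Timestamp(config.enroll_start) + pd.to_timedelta(
        rng_misc.integers(0, config.enroll_span_days + 1, size=n), unit="D"
    )

    # --- schedule -----------------------------------------------------------
    schedule = pd.DataFrame(
        {
            "participant_id": np.repeat(_pids(n), J),
            "timepoint_day": np.tile(tps, n),
            "date": (
                np.repeat(enroll.values, J)
                + pd.to_timedelta(np.tile(tps, n), unit="D").to_numpy()
            ),
        }
    )
    schedule["date"] = pd.to_datetime(schedule["date"]).dt.strftime("%Y-%m-%d")

    # --- survey items -------------------------------------------------------
    lam = np.asarray(config.item_loadings, dtype=float)
    if config.item_noise_sd is None:
        noise_sd = np.sqrt(np.clip(1.0 - lam**2, 1e-12, None))
    else:
        noise_sd = np.broadcast_to(
            np.asarray(config.item_noise_sd, dtype=float), lam.shape
        )
    K = lam.size
    # planned missingness: the last item of each domain is administered at
    # every other timepoint only
    administered = np.ones((J, K), dtype=bool)
    administered[1::2, K - 1] = False

    rows = []
    eta_flat = sev.transpose(0, 1, 2)  # (n, J, nD)
    noise = rng_items.standard_normal((n, J, nD, K)) * noise_sd
    x = eta_flat[..., None] * lam + noise  # (n, J, nD, K)
    if config.missing_mode == "mar":
        sev_mean = sev.mean(axis=2)  # (n, J)
        base = np.log(
            max(config.missing_rate_survey, 1e-6)
            / (1 - min(config.missing_rate_survey, 1 - 1e-6))
        )
        p_miss = 1.0 / (
            1.0 + np.exp(-(base + config.mar_strength * sev_mean))
        )
        miss_ij = rng_miss.random((n, J)) < p_miss
        miss = np.broadcast_to(miss_ij[:, :, None, None], x.shape).copy()
    else:
        miss = rng_miss.random(x.shape) < config.missing_rate_survey
    obs = administered[None, :, None, :] & ~miss
    ii, jj, dd, kk = np.nonzero(obs)
    pid_labels = _pids(n)
    survey_items = pd.DataFrame(
        {
            "participant_id": pid_labels[ii],
            "timepoint_day": tps[jj],
            "item_id": np.array(
                [f"{doms[d]}_it{k + 1}" for d, k in zip(dd, kk)]
            ),
            "value": x[ii, jj, dd, kk],
        }
    )

    # --- word bags ----------------------------------------------------------
    # bags are generated for the day prior to and day of each survey
    word_days = np.unique(np.concatenate([tps - 1, tps]))
    day_to_occasion = {}
    for j, t in enumerate(tps):
        day_to_occasion[t - 1] = j
        day_to_occasion[t] = j
    vocab = {c: CATEGORY_WORDS[c] for c in feats}
    cat_names = feats + ["_other"]
    base_logit = np.zeros(nF + 1)
    base_logit[-1] = np.log(9.0)  # "other" mass keeps category shares ~5%

    day_missing = rng_miss.random((n, len(word_days))) < config.missing_rate_words
    n_words = rng_words.poisson(config.words_per_day_mean, size=(n, len(word_days)))

    bag_rows = {"participant_id": [], "date": [], "word": [], "count": []}
    truth_feat_rows = {
        "participant_id": [],
        "date": [],
        "feature": [],
        "value": [],
    }
    for i in range(n):
        for w_idx, day in enumerate(word_days):
            j = day_to_occasion[day]
            z = feat_occ[i, j]  # latent category values for this day
            date = (enroll[i] + pd.Timedelta(days=int(day))).strftime(
                "%Y-%m-%d"
            )
            truth_feat_rows["participant_id"].extend([pid_labels[i]] * nF)
            truth_feat_rows["date"].extend([date] * nF)
            truth_feat_rows["feature"].extend(feats)
            truth_feat_rows["value"].extend(z.tolist())
            if day_missing[i, w_idx] or n_words[i, w_idx] == 0:
                continue
            logits = base_logit.copy()
            logits[:nF] += config.word_link_scale * z
            p = np.exp(logits - logits.max())
            p /= p.sum()
            cat_counts = rng_words.multinomial(n_words[i, w_idx], p)
            for c_idx, cnt in enumerate(cat_counts):
                if cnt == 0:
                    continue
                words = (
                    vocab[cat_names[c_idx]]
                    if c_idx < nF
                    else _OTHER_WORDS
                )
                wc = rng_words.multinomial(cnt, np.full(len(words), 1 / len(words)))
                for w, cwc in zip(words, wc):
                    if cwc > 0:
                        bag_rows["participant_id"].append(pid_labels[i])
                        bag_rows["date"].append(date)
                        bag_rows["word"].append(w)
                        bag_rows["count"].append(int(cwc))
    word_bags = pd.DataFrame(bag_rows)

    # --- device log and completion -----------------------------------------
    device_log = pd.DataFrame(
        {
            "participant_id": pid_labels,
            "date": enroll.strftime("%Y-%m-%d"),
            "os": "android",
        }
    )
    counts = survey_items.groupby("participant_id").size()
    per_part_obs = counts.reindex(pid_labels, fill_value=0).to_numpy(dtype=float)
    completion = pd.DataFrame(
        {
            "participant_id": pid_labels,
            "flash_survey": per_part_obs / (administered.sum() * nD),
            "word_data": 1.0 - day_missing.mean(axis=1),
            "neurocognitive": rng_misc.beta(8, 2, size=n),
            "watch": rng_misc.beta(5, 3, size=n),
        }
    )

    truth = GroundTruth(
        severity=pd.DataFrame(
            {
                "participant_id": np.repeat(pid_labels, J * nD),
                "timepoint_day": np.tile(np.repeat(tps, nD), n),
                "domain": np.tile(doms, n * J),
                "value": sev.reshape(-1),
            }
        ),
        features=pd.DataFrame(truth_feat_rows),
        planted_pairs=config.resolve_pairs(),
        config=config,
    )
    return CohortTables(
        word_bags=word_bags,
        survey_items=survey_items,
        schedule=schedule,
        device_log=device_log,
        completion=completion,
        truth=truth,
    )


def _pids(n):
    return np.array([f"P{i:04d}" for i in range(n)])


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(tables: CohortTables, directory) -> dict:
    """Write all cohort tables as delimited text; returns the file map.

    The ground truth goes to ``truth.json`` / ``truth_*.csv`` sidecars so
    it can never be mistaken for a pipeline input.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("word_bags", "survey_items", "schedule", "device_log", "completion"):
        p = directory / f"{name}.csv"
        getattr(tables, name).to_csv(p, index=False)
        paths[name] = str(p)
    t = tables.truth
    (directory / "truth_severity.csv").write_text(
        t.severity.to_csv(index=False)
    )
    (directory / "truth_features.csv").write_text(
        t.features.to_csv(index=False)
    )
    cfg = dataclasses.asdict(t.config)
    cfg["timepoints"] = list(cfg["timepoints"])
    cfg["planted_pairs"] = [list(p) for p in t.planted_pairs]
    (directory / "truth.json").write_text(
        json.dumps(
            {
                "planted_pairs": [list(p) for p in t.planted_pairs],
                "config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in cfg.items()
                    if not isinstance(v, (pd.DataFrame,))
                },
            },
            indent=2,
            default=str,
        )
    )
    paths["truth"] = str(directory / "truth.json")
    return paths


def read_fixture(directory) -> dict:
    """Read the pipeline-facing tables back (ground truth excluded)."""
    directory = Path(directory)
    out = {}
    for name in ("word_bags", "survey_items", "schedule", "device_log", "completion"):
        p = directory / f"{name}.csv"
        if p.exists():
            out[name] = pd.read_csv(p)
    return out
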