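"""Split-half identification / validation of language markers.

Participants are randomly divided into two equal halves. In the
identification half, every (feature, domain) association — the
cross-sectional correlation ``rho_b`` and the longitudinal correlation
``rho_w`` are two separate tests — is screened with a
Benjamini–Hochberg false-discovery-rate correction across the full
feature x domain x association-type family. Surviving candidates are
refitted on the held-out validation half and confirmed with a
Bonferroni correction whose family is the candidate set. Confirmed
markers report the validation-half estimates.

The split is at the participant level: repeated measures within a
participant are dependent, so an observation-level split would leak
information between the halves.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "split_participants",
    "bh_adjust",
    "bonferroni_adjust",
    "run_selection",
    "CROSS_SECTIONAL",
    "LONGITUDINAL",
]

logger = logging.getLogger(__name__)

CROSS_SECTIONAL = "cross_sectional"
LONGITUDINAL = "longitudinal"


def split_participants(ids, seed: int) -> pd.Series:
    """Random equal partition of participants, deterministic given seed.

    Returns a Series mapping participant id -> {"identification",
    "validation"}; sizes differ by at most one.
    """
    ids = list(dict.fromkeys(ids))  # de-duplicate, preserve order
    if len(ids) < 2:
        raise ValueError("need at least 2 participants to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    half = len(ids) // 2
    labels = np.empty(len(ids), dtype=object)
    labels[perm[:half]] = "identification"
    labels[perm[half:]] = "validation"
    return pd.Series(labels, index=pd.Index(ids, name="participant_id"), name="half")


def _check_p(p):
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = _check_p(pvalues)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni adjusted p-values min(1, p*m); m defaults to len(p)."""
    p = _check_p(pvalues)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def _melt_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """One row per (feature, domain, association type) with its test."""
    rows = []
    for _, r in fits.iterrows():
        for atype, rho, p, se in (
            (CROSS_SECTIONAL, r["rho_b"], r["p_rho_b"], r.get("se_rho_b", np.nan)),
            (LONGITUDINAL, r["rho_w"], r["p_rho_w"], r.get("se_rho_w", np.nan)),
        ):
            rows.append(
                {
                    "feature": r["feature"],
                    "domain": r["domain"],
                    "association_type": atype,
                    "rho": rho,
                    "se": se,
                    "p": p,
                    "converged": bool(r["converged"]),
                }
            )
    return pd.DataFrame(rows)


def run_selection(
    fits_identification: pd.DataFrame,
    fits_validation: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """FDR screen on one half, Bonferroni confirmation on the other.

    Both inputs are fit tables from :func:`langmark.blmm.fit_blmm_pairs`
    over the same (feature, domain) pairs. Returns the marker table with
    one row per (feature, domain, association_type): estimates and raw /
    adjusted p-values from both halves, and status in {rejected,
    candidate, validated} (validated implies candidate). Estimates for
    validated markers are the validation-half values by construction of
    the table's ``rho_valid`` column.
    """
    key = ["feature", "domain"]
    a = fits_identification.set_index(key).sort_index()
    b = fits_validation.set_index(key).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("the two fit sets must cover identical (feature, domain) pairs")

    m1 = _melt_fits(a.reset_index())
    m2 = _melt_fits(b.reset_index())
    tab = m1.merge(
        m2,
        on=["feature", "domain", "association_type"],
        suffixes=("_ident", "_valid"),
    )

    usable = tab["converged_ident"] & np.isfinite(tab["p_ident"])
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("excluding %d non-converged identification tests", n_excluded)

    tab["p_ident_adj"] = np.nan
    tab.loc[usable, "p_ident_adj"] = bh_adjust(tab.loc[usable, "p_ident"])
    tab["is_candidate"] = usable & (tab["p_ident_adj"] < alpha)

    cand = tab["is_candidate"]
    n_cand = int(cand.sum())
    tab["p_valid_adj"] = np.nan
    if n_cand:
        ok2 = cand & tab["converged_valid"] & np.isfinite(tab["p_valid"])
        tab.loc[ok2, "p_valid_adj"] = bonferroni_adjust(
            tab.loc[ok2, "p_valid"], m=n_cand
        )
    tab["is_validated"] = cand & (tab["p_valid_adj"] < alpha)

    tab["status"] = "rejected"
    tab.loc[tab["is_candidate"], "status"] = "candidate"
    tab.loc[tab["is_validated"], "status"] = "validated"
    order = ["feature", "domain", "association_type"]
    cols = order + [
        "rho_ident",
        "p_ident",
        "p_ident_adj",
        "rho_valid",
        "se_valid",
        "p_valid",
        "p_valid_adj",
        "is_candidate",
        "is_validated",
        "status",
    ]
    return tab.sort_values(order, kind="stable").reset_index(drop=True)[cols]
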