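"""Lexicon-based language features from daily word bags.

A word bag is one participant-day's unordered mapping ``word -> count``;
the original text is unrecoverable by construction. Two feature families
are supported:

* **category lexicons** — dictionaries of literal tokens and prefix
  patterns (trailing ``*``), scored as the percentage of the day's words
  matching the category (the convention of word-count text analysis
  tools);
* **weighted lexicons** — ``term -> weight`` maps scored as
  ``intercept + sum(weight * relative frequency)``, the standard linear
  form for lexicon-based trait estimates.

A day on which nothing was typed carries no language signal, so empty
bags score as *missing*, never as zero usage.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WordBag",
    "CategoryLexicon",
    "WeightedLexicon",
    "score_category",
    "score_weighted",
    "build_feature_matrix",
    "normalize",
    "apply_normalization",
    "load_category_lexicons",
    "load_weighted_lexicon",
    "builtin_category_lexicons",
    "builtin_weighted_lexicons",
]


@dataclass(frozen=True)
class WordBag:
    """One participant-day of word counts."""

    participant_id: str
    date: str
    counts: dict

    def __post_init__(self):
        for w, c in self.counts.items():
            if not w or w != w.lower():
                raise ValueError(f"words must be non-empty lower-case: {w!r}")
            if c <= 0 or int(c) != c:
                raise ValueError(f"counts must be positive integers: {w}={c}")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class CategoryLexicon:
    """Set of literal tokens plus prefix patterns (trailing asterisk)."""

    name: str
    literals: frozenset
    prefixes: tuple

    @classmethod
    def from_terms(cls, name, terms) -> "CategoryLexicon":
        lits, pres = set(), []
        for t in terms:
            t = t.strip().lower()
            if not t or t == "*":
                raise ValueError(f"invalid lexicon term {t!r} in {name!r}")
            if t.endswith("*"):
                pres.append(t[:-1])
            else:
                lits.add(t)
        return cls(name=name, literals=frozenset(lits), prefixes=tuple(sorted(pres)))

    def matches(self, word: str) -> bool:
        """Prefix-anchored matching: a word counts at most once."""
        return word in self.literals or any(
            word.startswith(p) for p in self.prefixes
        )


@dataclass(frozen=True)
class WeightedLexicon:
    name: str
    weights: dict
    intercept: float = 0.0

    def __post_init__(self):
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError(f"weighted lexicon {self.name!r} has no nonzero weight")


def score_category(bag: WordBag, lex: CategoryLexicon) -> float:
    """Percent of the bag's words matching the category; NaN for empty bags."""
    total = bag.total
    if total == 0:
        return np.nan
    matched = sum(c for w, c in bag.counts.items() if lex.matches(w))
    return 100.0 * matched / total


def score_weighted(bag: WordBag, lex: WeightedLexicon) -> float:
    """intercept + sum of weight * relative frequency; NaN for empty bags."""
    total = bag.total
    if total == 0:
        return np.nan
    return lex.intercept + sum(
        w * bag.counts.get(t, 0) / total for t, w in lex.weights.items()
    )


# ---------------------------------------------------------------------------
# feature matrix


def build_feature_matrix(
    bags: pd.DataFrame,
    category_lexicons=(),
    weighted_lexicons=(),
    *,
    include_word_count: bool = True,
) -> pd.DataFrame:
    """Score every participant-day against every lexicon.

    ``bags`` is the long word-bag table (participant_id, date, word,
    count); duplicate (participant, date, word) rows are aggregated
    first, so splitting a count across rows cannot change any score.
    Returns a frame indexed by (participant_id, date) with one column
    per feature in deterministic order (word_count first, then category
    lexicons, then weighted lexicons, in the order given). Days absent
    from ``bags`` are simply absent — missing, not zero.
    """
    names = [lx.name for lx in category_lexicons] + [
        lx.name for lx in weighted_lexicons
    ]
    if include_word_count:
        names = ["word_count"] + names
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names across lexicons")

    bags = (
        bags.groupby(["participant_id", "date", "word"], as_index=False)["count"]
        .sum()
        .sort_values(["participant_id", "date", "word"], kind="stable")
    )
    vocab = pd.Index(bags["word"].unique())
    key = ["participant_id", "date"]
    total = bags.groupby(key)["count"].sum()

    cols = {}
    if include_word_count:
        cols["word_count"] = total.astype(float)
    for lx in category_lexicons:
        mask = np.fromiter((lx.matches(w) for w in vocab), bool, len(vocab))
        matched_words = set(vocab[mask])
        sel = bags["word"].isin(matched_words)
        hits = bags[sel].groupby(key)["count"].sum()
        cols[lx.name] = 100.0 * hits.reindex(total.index, fill_value=0) / total
    for lx in weighted_lexicons:
        w = bags["word"].map(lx.weights).fillna(0.0)
        contrib = (w * bags["count"]).groupby(
            [bags["participant_id"], bags["date"]]
        ).sum()
        cols[lx.name] = lx.intercept + contrib.reindex(total.index, fill_value=0) / total
    fm = pd.DataFrame(cols, index=total.index)[names]
    return fm.sort_index()


def normalize(fm: pd.DataFrame, fit_rows=None):
    """Z-score each feature column; returns (normalized frame, parameters).

    Means and sample standard deviations (n-1 denominator) are computed
    on ``fit_rows`` (a boolean mask or index subset; default all rows) so
    that, in the split workflow, scaling can be fitted on the
    identification half only and reused on the validation half. Missing
    cells stay missing. A zero-variance column raises, naming the column.
    """
    fit = fm if fit_rows is None else fm.loc[fit_rows]
    params = pd.DataFrame({"mean": fit.mean(), "sd": fit.std(ddof=1)})
    bad = params.index[(params["sd"] == 0) | params["sd"].isna()]
    if len(bad):
        raise ValueError(
            f"zero-variance feature column(s) in fitting rows: {list(bad)}"
        )
    return apply_normalization(fm, params), params


def apply_normalization(fm: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    return (fm - params["mean"]) / params["sd"]


# ---------------------------------------------------------------------------
# lexicon files (delimited text, UTF-8, lower-cased on load)


def load_category_lexicons(path) -> list:
    """Load category lexicons from a two-column (category, term) table."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    out = []
    for name, grp in df.groupby("category", sort=False):
        out.append(CategoryLexicon.from_terms(str(name).lower(), grp["term"].astype(str)))
    return out


def load_weighted_lexicon(path, name=None) -> WeightedLexicon:
    """Load one weighted lexicon from a (term, weight) table.

    The reserved term ``_intercept`` supplies the intercept.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    weights, intercept = {}, 0.0
    for t, w in zip(df["term"].astype(str), df["weight"].astype(float)):
        t = t.strip().lower()
        if t == "_intercept":
            intercept = float(w)
        else:
            weights[t] = float(w)
    if name is None:
        name = Path(path).stem
    return WeightedLexicon(name=name, weights=weights, intercept=intercept)


def _data_path(fname):
    return resources.files("langmark") / "lexicons" / fname


def builtin_category_lexicons() -> list:
    """The bundled toy category lexicons (match the generator's vocabulary)."""
    return load_category_lexicons(_data_path("categories.csv"))


def builtin_weighted_lexicons() -> list:
    """The bundled toy weighted lexicons (synthetic stand-ins for trait models)."""
    return [load_weighted_lexicon(_data_path("tone.csv"), name="tone")]
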