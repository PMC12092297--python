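"""Score word bags against category and weighted lexicons.

Category features are the percentage of the day's words matching a
dictionary (with trailing-asterisk prefix patterns); weighted features
are linear scores over relative frequencies.
"""

from langmark.lexicon import (
    CategoryLexicon,
    WeightedLexicon,
    WordBag,
    build_feature_matrix,
    builtin_category_lexicons,
    normalize,
    score_category,
    score_weighted,
)
from langmark.simulate import SimConfig, simulate_cohort

bag = WordBag("P0", "2024-01-01", {"i": 2, "hurt": 1, "the": 1})
pron = CategoryLexicon.from_terms("pronoun_i", ["i", "me", "my"])
tone = WeightedLexicon("tone", {"happy": 2.0, "hurt": -1.0})

print(f"pronoun percent: {score_category(bag, pron):.1f}   (2 of 4 words = 50%)")
print(f"tone score:      {score_weighted(bag, tone):+.2f}  (weighted relative frequency)")

bags = simulate_cohort(SimConfig(n_participants=10, seed=2)).word_bags
fm = build_feature_matrix(bags, builtin_category_lexicons())
fm_norm, params = normalize(fm)
print("\nfeature matrix (first rows, z-scored):")
print(fm_norm.head(3).round(2).to_string())
# each row is one participant-day; columns are percent-of-words features
# standardized to mean 0 / sd 1 so that markers share a common scale
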