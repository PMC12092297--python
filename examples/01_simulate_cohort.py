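"""Generate a small synthetic cohort and look at the planted structure.

The generator emulates a six-month post-trauma mobile study: ten flash
surveys, daily word bags around each survey, planned item missingness,
and three (language category, symptom domain) pairs with planted
between- and within-subject correlations.
"""

from langmark.simulate import SimConfig, simulate_cohort

cfg = SimConfig(n_participants=30, seed=1)
tables = simulate_cohort(cfg)

print(f"word-bag rows:     {len(tables.word_bags):>6}")
print(f"survey-item rows:  {len(tables.survey_items):>6}")
print("planted (feature, domain, rho_between, rho_within):")
for pair in tables.truth.planted_pairs:
    print("  ", pair)
print("\nfirst word-bag rows:")
print(tables.word_bags.head(5).to_string(index=False))

# rho_between: do participants who type more negative-emotion words carry
# higher stable depression severity? rho_within: do their fluctuations track?
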