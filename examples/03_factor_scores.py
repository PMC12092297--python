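"""Fit the pooled one-factor measurement model and score participants.

Survey items load on a latent severity factor; FIML uses whatever items
each row observed (planned missingness), and regression factor scores
summarize each participant-timepoint on a standardized scale.
"""

from langmark.measurement import fit_domains, score_domains
from langmark.simulate import SimConfig, simulate_cohort

tables = simulate_cohort(
    SimConfig(n_participants=150, n_domains=2, missing_rate_words=1.0,
              planted_pairs=(("negemo", "depression", 0.3, 0.15),), seed=3)
)
models = fit_domains(tables.survey_items)
for dom, m in models.items():
    print(f"{dom:12s} loadings {m.loadings.round(2)}  converged={m.converged}")

scores = score_domains(models, tables.survey_items)
print("\nfactor scores (higher = more severe):")
print(scores.head(6).to_string(index=False))
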