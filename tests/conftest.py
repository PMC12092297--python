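import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_bags():
    """Three participant-days of word counts (long format)."""
    rows = [
        ("P0", "2024-01-01", "i", 2),
        ("P0", "2024-01-01", "happy", 1),
        ("P0", "2024-01-01", "dog", 1),
        ("P1", "2024-01-01", "the", 3),
        ("P1", "2024-01-01", "sad", 2),
        ("P1", "2024-01-02", "illness", 3),
        ("P1", "2024-01-02", "sick", 1),
        ("P1", "2024-01-02", "silk", 1),
    ]
    return pd.DataFrame(rows, columns=["participant_id", "date", "word", "count"])


@pytest.fixture
def null_panel():
    """Complete balanced panel with independent symptom and marker."""
    from langmark.simulate import simulate_bivariate_panel

    return simulate_bivariate_panel(60, 5, 0.0, 0.0, seed=42)


def make_scores(values):
    """Long score table from {(pid, day, domain): value}."""
    rows = [
        {"participant_id": p, "timepoint_day": d, "domain": dom, "score": v}
        for (p, d, dom), v in values.items()
    ]
    return pd.DataFrame(rows)
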