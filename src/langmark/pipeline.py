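"""End-to-end orchestration: simulate/extract -> score -> preprocess ->
split -> fit -> select -> evaluate, with every stage writing delimited
text before the next begins and a run manifest for reproducibility.

All tabular I/O is CSV with headers; the manifest is JSON. Identical
configuration and inputs give byte-identical outputs: the only
randomness is the simulation seed and the participant-split seed, both
recorded in the manifest.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .blmm import fit_blmm_pairs
from .change import compute_changes, evaluate_markers
from .lexicon import (
    apply_normalization,
    build_feature_matrix,
    builtin_category_lexicons,
    builtin_weighted_lexicons,
    load_category_lexicons,
    load_weighted_lexicon,
    normalize,
)
from .measurement import fit_domains, score_domains
from .preprocess import (
    FilterReport,
    align_observations,
    cap_word_count,
    drop_os_switchers,
    filter_zero_features,
    missingness_diagnostic,
    prune_redundant,
)
from .selection import run_selection, split_participants
from .simulate import SimConfig, simulate_cohort, write_fixture

__all__ = ["PipelineConfig", "run_all", "DEFAULTS"]

DEFAULTS = {
    "alpha": 0.05,
    "spearman_threshold": 0.85,
    "zero_pct_threshold": 90.0,
    "wordcount_cap": 10_000,
    "split_seed": 20_240_101,
    "sim_seed": 0,
    "n_participants": 60,
    "endpoints": None,  # default: first and last scheduled timepoints
    "timepoint_means": False,
    "blmm_gtol": 1e-6,
    "normalize_on_identification": True,
    "prune_priority": [],
}


class PipelineConfig(dict):
    """Configuration mapping with defaults; loadable from YAML."""

    def __init__(self, *args, **kw):
        super().__init__(DEFAULTS)
        for a in args:
            self.update(a)
        self.update(kw)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def validate(self):
        if not 0 <= self["alpha"] <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0 <= self["spearman_threshold"] <= 1:
            raise ValueError("spearman_threshold must lie in [0, 1]")
        if not 0 <= self["zero_pct_threshold"] <= 100:
            raise ValueError("zero_pct_threshold must lie in [0, 100]")
        if self["wordcount_cap"] <= 0:
            raise ValueError("wordcount_cap must be positive")
        return self


def _load_lexicons(config):
    cats = (
        load_category_lexicons(config["category_lexicons"])
        if config.get("category_lexicons")
        else builtin_category_lexicons()
    )
    weighted = []
    for p in config.get("weighted_lexicons", []) or []:
        weighted.append(load_weighted_lexicon(p))
    if not config.get("weighted_lexicons"):
        weighted = builtin_weighted_lexicons()
    return cats, weighted


# ---------------------------------------------------------------------------
# stages (each reads/writes delimited text under the output directory)


def stage_simulate(config, outdir) -> dict:
    sim_kw = config.get("sim", {}) or {}
    sim_kw.setdefault("n_participants", config["n_participants"])
    sim_kw.setdefault("seed", config["sim_seed"])
    cfg = SimConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in sim_kw.items()})
    tables = simulate_cohort(cfg)
    return write_fixture(tables, Path(outdir) / "input")


def stage_extract(config, outdir) -> Path:
    indir = Path(config.get("input_dir", Path(outdir) / "input"))
    bags = pd.read_csv(indir / "word_bags.csv")
    cats, weighted = _load_lexicons(config)
    fm = build_feature_matrix(bags, cats, weighted)
    out = Path(outdir) / "features.csv"
    fm.to_csv(out)
    return out


def stage_score(config, outdir) -> Path:
    indir = Path(config.get("input_dir", Path(outdir) / "input"))
    items = pd.read_csv(indir / "survey_items.csv")
    domain_spec = config.get("domain_spec")
    models = fit_domains(items, domain_spec)
    scores = score_domains(models, items)
    out = Path(outdir) / "scores.csv"
    scores.to_csv(out, index=False)
    meas = pd.DataFrame(
        [
            {
                "domain": d,
                "items": "|".join(m.items),
                "loadings": "|".join(f"{v:.6g}" for v in m.loadings),
                "uniquenesses": "|".join(f"{v:.6g}" for v in m.uniquenesses),
                "loglik": m.loglik,
                "converged": m.converged,
            }
            for d, m in models.items()
        ]
    )
    meas.to_csv(Path(outdir) / "measurement_models.csv", index=False)
    return out


def stage_preprocess(config, outdir) -> dict:
    indir = Path(config.get("input_dir", Path(outdir) / "input"))
    outdir = Path(outdir)
    fm = pd.read_csv(outdir / "features.csv").set_index(
        ["participant_id", "date"]
    )
    scores = pd.read_csv(outdir / "scores.csv")
    schedule = pd.read_csv(indir / "schedule.csv")
    device_log = pd.read_csv(indir / "device_log.csv")

    report = FilterReport()
    fm, report.zero_dropped = filter_zero_features(
        fm, threshold=config["zero_pct_threshold"]
    )
    fm, report.wordcount_masked = cap_word_count(fm, cap=config["wordcount_cap"])
    fm, report.os_removed = drop_os_switchers(fm, device_log)
    fm, report.pruned = prune_redundant(
        fm,
        scores,
        schedule,
        threshold=config["spearman_threshold"],
        priority=config["prune_priority"],
    )

    comp_path = indir / "completion.csv"
    if comp_path.exists():
        completion = pd.read_csv(comp_path)
        diag, mar_ok = missingness_diagnostic(scores, completion)
        diag.to_csv(outdir / "missingness_diagnostic.csv", index=False)
    else:
        mar_ok = None

    # participant split happens before normalization so scaling can be
    # fitted on the identification half only (no leakage)
    pids = fm.index.get_level_values("participant_id").unique()
    split = split_participants(pids, config["split_seed"])
    split.rename("half").to_csv(outdir / "split.csv")
    if config["normalize_on_identification"]:
        fit_rows = fm.index.get_level_values("participant_id").isin(
            split.index[split == "identification"]
        )
    else:
        fit_rows = None
    fm_norm, norm_params = normalize(fm, fit_rows)
    norm_params.to_csv(outdir / "normalization.csv")

    panel = align_observations(fm_norm, scores, schedule)
    panel.to_csv(outdir / "panel.csv", index=False)
    with open(outdir / "filter_report.json", "w") as fh:
        fh.write(report.to_json())
    return {"report": report, "mar_plausible": mar_ok, "n_panel_rows": len(panel)}


def stage_fit(config, outdir) -> dict:
    outdir = Path(outdir)
    panel = pd.read_csv(outdir / "panel.csv")
    split = pd.read_csv(outdir / "split.csv").set_index("participant_id")["half"]
    out = {}
    for half in ("identification", "validation"):
        sub = panel[panel["participant_id"].isin(split.index[split == half])]
        fits = fit_blmm_pairs(sub, gtol=config["blmm_gtol"])
        path = outdir / f"fits_{half}.csv"
        fits.to_csv(path, index=False)
        out[half] = path
    return out


def stage_select(config, outdir) -> Path:
    outdir = Path(outdir)
    f1 = pd.read_csv(outdir / "fits_identification.csv")
    f2 = pd.read_csv(outdir / "fits_validation.csv")
    markers = run_selection(f1, f2, alpha=config["alpha"])
    path = outdir / "marker_table.csv"
    markers.to_csv(path, index=False)
    return path


def stage_evaluate(config, outdir) -> Path:
    outdir = Path(outdir)
    markers = pd.read_csv(outdir / "marker_table.csv")
    scores = pd.read_csv(outdir / "scores.csv")
    panel = pd.read_csv(outdir / "panel.csv")
    endpoints = config["endpoints"]
    records = compute_changes(
        scores, panel, endpoints=tuple(endpoints) if endpoints else None
    )
    metrics = evaluate_markers(markers, records, both_conventions=True)
    path = outdir / "change_metrics.csv"
    metrics.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------


def run_all(config, outdir) -> dict:
    """Run every stage in order and write the run manifest.

    ``config`` may be a mapping or a YAML path. Returns the manifest
    dict (also written to ``manifest.json``).
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig(config)
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = {
        "langmark_version": __version__,
        "python": platform.python_version(),
        "config": {k: v for k, v in config.items() if not isinstance(v, Path)},
        "stages": {},
    }
    if "input_dir" not in config:
        stage_simulate(config, outdir)
        config = PipelineConfig(config, input_dir=str(outdir / "input"))
        manifest["stages"]["simulate"] = {"input_dir": config["input_dir"]}

    stage_extract(config, outdir)
    fm = pd.read_csv(outdir / "features.csv")
    manifest["stages"]["extract"] = {"n_rows": len(fm), "n_features": fm.shape[1] - 2}

    stage_score(config, outdir)
    scores = pd.read_csv(outdir / "scores.csv")
    manifest["stages"]["score"] = {"n_rows": len(scores)}

    pre = stage_preprocess(config, outdir)
    manifest["stages"]["preprocess"] = {
        "n_panel_rows": pre["n_panel_rows"],
        "mar_plausible": pre["mar_plausible"],
        "zero_dropped": pre["report"].zero_dropped,
        "wordcount_masked": pre["report"].wordcount_masked,
        "os_removed": pre["report"].os_removed,
        "pruned": pre["report"].pruned,
    }

    stage_fit(config, outdir)
    fits1 = pd.read_csv(outdir / "fits_identification.csv")
    fits2 = pd.read_csv(outdir / "fits_validation.csv")
    manifest["stages"]["fit"] = {
        "n_pairs": len(fits1),
        "converged_identification": int(fits1["converged"].sum()),
        "converged_validation": int(fits2["converged"].sum()),
    }

    stage_select(config, outdir)
    markers = pd.read_csv(outdir / "marker_table.csv")
    manifest["stages"]["select"] = {
        "n_tests": len(markers),
        "n_candidates": int(markers["is_candidate"].sum()),
        "n_validated": int(markers["is_validated"].sum()),
    }

    stage_evaluate(config, outdir)
    metrics = pd.read_csv(outdir / "change_metrics.csv")
    manifest["stages"]["evaluate"] = {"n_markers_evaluated": len(metrics)}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
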