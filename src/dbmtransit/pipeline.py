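"""End-to-end orchestration: simulate -> classify -> prepare -> markov ->
adjust -> select, with reproducibility metadata.

Every stage reads and writes plain CSV; each output carries a commented
metadata header (seed, config hash, package version) so a run is fully
identified by its files.  A manifest JSON records per-stage row counts so
conservation can be audited.  Outputs are deterministic in the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .markov import FourStateMarkov, stratified_markov
from .prep import attrition_comparison, baseline_table, complete_case_filter
from .selection import stepwise_aic, univariate_screen
from .simulate import (
    SimConfig,
    apply_attrition,
    default_config,
    simulate_anthropometry,
    simulate_cohort,
)
from .states import classify_panel
from .transitions import odds_ratio_frame, run_adjusted_models

logger = logging.getLogger("dbmtransit")

DEFAULT_STAGES = ("simulate", "classify", "prepare", "markov", "adjust", "select")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str = "dbm_run"
    seed: int = 0
    n_subjects: int = 2000
    cohort: str = "YC"
    stages: tuple = DEFAULT_STAGES
    covariates: tuple = ("sex", "wealth_q", "residence", "hh_size")
    candidates: tuple = ("sex", "wealth_q", "residence", "hh_size", "mat_edu")
    targets: tuple = ("stunting", "overweight", "cso")
    stratifier: str | None = None
    selection_target: str = "stunting"
    dropout: float = 0.02
    field_missingness: float = 0.01
    panel_path: str | None = None  # start from an existing panel instead of simulating

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown run-config keys: {sorted(unknown)}")
        for key in ("stages", "covariates", "candidates", "targets"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    """CSV with a commented, deterministic metadata header."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dbmtransit {__version__} seed={config.seed} config={config.hash()}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def sim_config_from_run(config: RunConfig) -> SimConfig:
    from .simulate import AttritionSpec

    return default_config(
        n_subjects=config.n_subjects,
        seed=config.seed,
        cohort=config.cohort,
        attrition=AttritionSpec(
            dropout=config.dropout, field_missingness=config.field_missingness
        ),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dictionary.

    Stages toggled off are skipped; downstream stages then read the prior
    outputs in ``out_dir`` unchanged.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "dbmtransit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "stages": {},
    }

    def record(stage: str, rows_in: int, rows_out: int, **extra) -> None:
        manifest["stages"][stage] = {"rows_in": rows_in, "rows_out": rows_out, **extra}
        logger.info("stage %s: %d -> %d rows", stage, rows_in, rows_out)

    panel = None
    if "simulate" in config.stages:
        sim_cfg = sim_config_from_run(config)
        panel, truth = simulate_cohort(sim_cfg)
        n_full = len(panel)
        panel = simulate_anthropometry(panel, sim_cfg)
        panel = apply_attrition(panel, sim_cfg)
        write_csv(panel.drop(columns=["state"]), out / "panel.csv", config)
        truth_blob = {
            "initial_state_probs": list(map(float, sim_cfg.initial_state_probs)),
            "transition_matrices": [
                [[float(v) for v in row] for row in m] for m in sim_cfg.transition_matrices
            ],
            "seed": sim_cfg.seed,
        }
        (out / "truth.json").write_text(json.dumps(truth_blob, indent=1))
        record("simulate", n_full, len(panel))
    elif config.panel_path:
        panel = read_csv(config.panel_path)

    if "classify" in config.stages:
        if panel is None:
            panel = read_csv(out / "panel.csv")
        rows_in = len(panel)
        panel = classify_panel(panel)
        write_csv(panel, out / "classified.csv", config)
        record("classify", rows_in, len(panel),
               flagged=int(panel["state_missing"].sum()))

    analytic = None
    if "prepare" in config.stages:
        if panel is None:
            panel = read_csv(out / "classified.csv")
        analytic, log = complete_case_filter(panel, scope="states_and_covariates")
        write_csv(analytic, out / "analytic.csv", config)
        (out / "exclusions.json").write_text(json.dumps(log.counts, indent=1))
        table1 = baseline_table(analytic)
        write_csv(table1, out / "table1.csv", config)
        excluded = panel[panel["subject_id"].isin(log.reasons)]
        if len(excluded):
            comp = attrition_comparison(analytic, excluded)
            write_csv(comp, out / "attrition_comparison.csv", config)
        record("prepare", len(panel), len(analytic), excluded_subjects=log.n_excluded)

    if analytic is None and any(s in config.stages for s in ("markov", "adjust", "select")):
        analytic = read_csv(out / "analytic.csv")

    if "markov" in config.stages:
        res = FourStateMarkov(analytic).fit()
        write_csv(res.transitions_frame(), out / "transitions.csv", config)
        write_csv(res.marginals_frame(), out / "marginals.csv", config)
        if config.stratifier:
            for level, sres in stratified_markov(analytic, config.stratifier).items():
                write_csv(
                    sres.transitions_frame(),
                    out / f"transitions_{config.stratifier}_{level}.csv",
                    config,
                )
        record("markov", len(analytic), len(res.transitions_frame()))

    if "adjust" in config.stages:
        fits = run_adjusted_models(analytic, config.targets, config.covariates)
        ors = odds_ratio_frame(fits)
        write_csv(ors, out / "ors.csv", config)
        record("adjust", len(analytic), len(ors))

    if "select" in config.stages:
        screen = univariate_screen(analytic, config.candidates)
        report = stepwise_aic(
            analytic, config.selection_target, tuple(config.candidates)
        )
        blob = {
            "target": report.target,
            "candidates": list(report.candidates),
            "screen_passes": sorted(
                set(screen.loc[screen["passes"], "candidate"])
            ),
            "ladder": [
                {**step, "covariates": list(step["covariates"])} for step in report.ladder
            ],
            "selected": list(report.selected),
            "final_covariates": list(report.final_covariates),
        }
        (out / "selection.json").write_text(json.dumps(blob, indent=1))
        record("select", len(analytic), len(report.ladder))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
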