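"""Cohort readers/writers, run configuration and pipeline orchestration.

The cohort file contract is delimited text (CSV by default) with the
mandatory columns ``id, sex, time, event``, one column per panel lab
variable, and optional covariate columns.  Sex is decoded from a
configurable synonym map to {male, female}; unparseable lab cells become
missing with a logged count.  ``run_pipeline`` strings the stages
together — simulate -> score -> survival models -> comparison tables ->
curves — and writes a machine-readable manifest recording the seed and
parameters, so every artifact is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .compare import build_group_table, render_group_table
from .index import (DEFAULT_COMPLETENESS, DEFAULT_CUTPOINT, score_cohort,
                    summarise_fi)
from .panel import DataError, code_cohort, load_reference_panel, panel_variables
from .simulate import SimulationConfig, generate_cohort
from .survival import (COVARIATE_SETS, FitError, ModelSpec,
                       cumulative_hazard_by_group, fit_cox,
                       per_variable_hr_screen, plot_cumulative_hazard)

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("id", "sex", "time", "event")

SEX_SYNONYMS = {
    "male": "male", "m": "male", "man": "male", "men": "male", "1": "male",
    "female": "female", "f": "female", "woman": "female", "women": "female",
    "2": "female", "0": "female",
}


class SchemaError(ValueError):
    """Cohort file violates the header contract."""


def read_cohort(
    path: str | Path,
    delimiter: str = ",",
    lost_policy: str = "exclude",
    followup: float = 4.0,
) -> pd.DataFrame:
    """Read a cohort table, decoding sex and event and typing lab columns.

    Subjects lost to follow-up (missing time or event) are handled per
    ``lost_policy``: ``"exclude"`` (default) drops them with a logged
    count; ``"censor"`` keeps them censored at ``followup``.
    """
    if lost_policy not in ("exclude", "censor"):
        raise ValueError(f"unknown lost_policy {lost_policy!r}")
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file lacks mandatory columns: {missing}")
    sex = df["sex"].astype(str).str.strip().str.lower().map(SEX_SYNONYMS)
    if sex.isna().any():
        bad = df.loc[sex.isna(), "sex"].unique()[:5]
        raise DataError(f"undecodable sex values: {list(bad)}")
    df["sex"] = sex
    lost = (pd.to_numeric(df["time"], errors="coerce").isna()
            | pd.to_numeric(df["event"], errors="coerce").isna())
    if lost.any():
        if lost_policy == "exclude":
            logger.warning("excluding %d subjects lost to follow-up",
                           int(lost.sum()))
            df = df[~lost].reset_index(drop=True)
        else:
            logger.warning("censoring %d lost subjects at t=%g",
                           int(lost.sum()), followup)
            df.loc[lost, "time"] = followup
            df.loc[lost, "event"] = 0
    df["event"] = pd.to_numeric(df["event"], errors="raise").astype(int)
    if not df["event"].isin([0, 1]).all():
        raise SchemaError("event column must be 0/1")
    df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
    n_bad = 0
    for col in df.columns:
        if col in MANDATORY_COLUMNS or df[col].dtype != object:
            continue
        if col in ("education",):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_bad += int((coerced.isna() & df[col].notna()).sum())
        df[col] = coerced
    if n_bad:
        logger.warning("coerced %d unparseable cells to missing", n_bad)
    logger.info("read cohort: %d subjects from %s", len(df), path)
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV (floats at full precision)."""
    cohort.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    output_dir: str = "filab_run"
    cohort_path: Optional[str] = None     # None: simulate instead
    panel_name: str = "panel_table3"
    cutpoint: float = DEFAULT_CUTPOINT
    completeness_threshold: float = DEFAULT_COMPLETENESS
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int = 0
    make_figure: bool = False

    def __post_init__(self) -> None:
        # one top-level seed drives the simulation stage
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Simulate (or load), score, analyse, and write all artifacts.

    Returns a mapping artifact name -> file path.  Artifacts: the scored
    cohort, the FI distribution summary, the per-variable hazard screen,
    the four-model frailty report, both comparison tables, the
    cumulative-hazard curves, and a JSON manifest with seed, parameters
    and package version.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _stage(name: str):
        logger.info("pipeline stage: %s", name)

    _stage("input")
    if config.cohort_path is None:
        cohort = generate_cohort(config.simulation)
        source = f"simulated(seed={config.simulation.seed})"
    else:
        cohort = read_cohort(config.cohort_path)
        source = str(config.cohort_path)

    _stage("score")
    panel = load_reference_panel(config.panel_name)
    deficits = code_cohort(cohort, panel)
    scores = score_cohort(
        deficits, config.completeness_threshold, config.cutpoint
    )
    scored = pd.concat([cohort, scores], axis=1)
    score_cols = ["id", "fi", "n_deficits", "n_considered", "valid", "frail"]
    scored[score_cols].to_csv(out / "scored.csv", index=False)
    artifacts["scored"] = str(out / "scored.csv")

    summary = summarise_fi(scores, config.cutpoint)
    with open(out / "fi_summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=2)
    artifacts["fi_summary"] = str(out / "fi_summary.json")

    usable = scored[scored["valid"].astype(bool)].copy()

    _stage("hazard screen")
    screen = per_variable_hr_screen(usable, deficits.loc[usable.index])
    screen.to_csv(out / "variable_screen.csv", index=False)
    artifacts["variable_screen"] = str(out / "variable_screen.csv")

    _stage("frailty models")
    model_rows = []
    report_lines = [
        "Cox proportional-hazards models of frailty and mortality",
        f"{'model':<14}{'HR':>8}{'95% CI':>18}",
        "-" * 40,
    ]
    for setname in COVARIATE_SETS:
        try:
            fit = fit_cox(usable, ModelSpec("frail", setname),
                          drop_constant_covariates=True)
        except FitError as exc:
            # rare covariates can separate in small cohorts; surface, don't die
            logger.warning("model %s not estimable: %s", setname, exc)
            model_rows.append({
                "model": setname, "term": "frail", "hr": np.nan,
                "ci_lower": np.nan, "ci_upper": np.nan, "n_events": np.nan,
            })
            report_lines.append(f"{setname:<14}{'not estimable':>26}")
            continue
        t = fit.term("frail")
        model_rows.append({
            "model": setname, "term": "frail", "hr": t["hr"],
            "ci_lower": t["ci_lower"], "ci_upper": t["ci_upper"],
            "n_events": fit.n_events,
        })
        ci = f"({t['ci_lower']:.2f}, {t['ci_upper']:.2f})"
        report_lines.append(f"{setname:<14}{t['hr']:>8.2f}{ci:>18}")
    pd.DataFrame(model_rows).to_csv(out / "frailty_models.csv", index=False)
    artifacts["frailty_models"] = str(out / "frailty_models.csv")
    (out / "frailty_models.txt").write_text("\n".join(report_lines) + "\n")
    artifacts["frailty_models_txt"] = str(out / "frailty_models.txt")

    _stage("comparison tables")
    for grouping, fname in (("frail", "table_frailty"),
                            ("event", "table_survival")):
        table = build_group_table(usable, grouping)
        table.to_csv(out / f"{fname}.csv", index=False)
        (out / f"{fname}.txt").write_text(render_group_table(table) + "\n")
        artifacts[fname] = str(out / f"{fname}.csv")

    _stage("curves")
    curves = cumulative_hazard_by_group(usable, "frail")
    curve_df = pd.concat(
        [c.assign(group=label) for label, c in curves.items()],
        ignore_index=True,
    )
    curve_df.to_csv(out / "cumulative_hazard.csv", index=False)
    artifacts["cumulative_hazard"] = str(out / "cumulative_hazard.csv")
    if config.make_figure:
        plot_cumulative_hazard(curves, str(out / "cumulative_hazard.png"))
        artifacts["figure"] = str(out / "cumulative_hazard.png")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "source": source,
        "panel": config.panel_name,
        "cutpoint": config.cutpoint,
        "completeness_threshold": config.completeness_threshold,
        "simulation": _jsonable(config.simulation)
        if config.cohort_path is None else None,
        "n_subjects": int(len(cohort)),
        "n_valid": int(usable.shape[0]),
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
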