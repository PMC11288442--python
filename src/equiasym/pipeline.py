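"""End-to-end orchestration: simulate/load -> strides -> QC -> classify -> associate.

`run_pipeline` executes the configured stages and writes a report bundle
(tidy CSV tables, JSON summaries and a run manifest with version, seed and
config hash) into the output directory.  In simulate mode the cohort can be
produced either at trial-summary level (fast, arbitrary n) or trace level,
where every trial is generated as displacement signals and pushed through
stride segmentation, extrema extraction and stride-level QC before being
summarized — the full measurement path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (
    GaitConfig, PopulationConfig, PopulationTables,
    generate_displacement_trace, generate_population,
)
from .strides import segment_strides, compute_stride_asymmetries, records_to_frame
from .qc import remove_outliers_iterative, apply_inclusion_rules, QCReport
from .classify import (
    Thresholds, TrialSummary, summarize_trial, assess_horses,
    population_summary, concordance_summary, parameter_table,
)
from .association import (
    build_association_table, run_association_suite, results_to_frame,
)
from .io import read_study_workbook, DatasetSchema


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    mode: str = "simulate"  # simulate | workbook | csv
    input_path: str | None = None
    schema_path: str | None = None
    output_dir: str = "equiasym_out"
    seed: int = 0
    head_threshold_mm: float = 6.0
    pelvis_threshold_mm: float = 3.0
    #: simulate mode: cohort size and whether to run the trace-level path
    n_horses: int = 71
    n_riders: int = 51
    trace_level: bool = False
    noise_sd: float = 0.5  # mm sensor noise on trace-level trials
    associate: bool = True
    #: extra keyword overrides forwarded to PopulationConfig
    population: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def simulate_trials_trace_level(
    pop: PopulationTables,
    noise_sd: float = 0.5,
    sample_rate: float = 200.0,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-measure a simulated cohort through the full signal path.

    For every trial of the cohort a displacement-trace trial is generated
    with the trial's parameter means injected as trial-level asymmetries
    and its per-parameter SDs as stride-to-stride variability;
    strides are segmented from the pastern reference, the four differences
    extracted, head outlier strides removed, and the trial summarized.
    Trials failing the stride-count inclusion rules are dropped.

    Returns the extracted trial-summary table and the QC report table.
    """
    rows, qc_rows = [], []
    for i, (_, tr) in enumerate(pop.trials.iterrows()):
        cfg = GaitConfig(
            n_strides=int(tr["n_strides"]),
            sample_rate=sample_rate,
            asym_hd_min=tr["mean_hd_min"],
            asym_hd_max=tr["mean_hd_max"],
            asym_pd_min=tr["mean_pd_min"],
            asym_pd_max=tr["mean_pd_max"],
            stride_duration_mean=tr["mean_stride_duration"],
            stride_duration_cv=0.03,
            stride_asym_sd=tuple(
                float(tr[f"sd_{p}"]) for p in
                ("hd_min", "hd_max", "pd_min", "pd_max")
            ),
            noise_sd=noise_sd,
            outlier_stride_prob=0.02,
            seed=(base_seed + 7919 * i) % (2**31),
        )
        trial = generate_displacement_trace(cfg)
        intervals = segment_strides(trial.pastern)
        records = compute_stride_asymmetries(
            trial.head, trial.pelvis, intervals,
            smooth_cutoff_hz=15.0 if noise_sd > 0 else None,
            min_prominence="auto" if noise_sd > 0 else 0.0,
        )
        strides = records_to_frame(records)
        strides = strides.loc[~strides["flagged"]]
        trial_id = f"{tr['horse_id']}:{tr['condition']}"
        cleaned, report = remove_outliers_iterative(strides, trial_id=trial_id)
        summary = summarize_trial(
            cleaned, horse_id=tr["horse_id"], condition=tr["condition"]
        )
        included, reason = apply_inclusion_rules(summary)
        report.included = report.included and included
        report.exclusion_reason = report.exclusion_reason or reason
        qc_rows.append(dataclasses.asdict(report))
        if report.included:
            rows.append(dataclasses.asdict(summary))
    return pd.DataFrame(rows), pd.DataFrame(qc_rows)


def _apply_inclusion(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a trial-summary table by the stride-count inclusion rules."""
    keep, qc_rows = [], []
    for idx, row in trials.iterrows():
        summary = TrialSummary.from_row(row)
        included, reason = apply_inclusion_rules(summary)
        qc_rows.append(
            {
                "trial_id": f"{row['horse_id']}:{row['condition']}",
                "n_strides_in": int(row["n_strides"]),
                "included": included,
                "exclusion_reason": reason,
            }
        )
        if included:
            keep.append(idx)
    return trials.loc[keep], pd.DataFrame(qc_rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline and write the report bundle.

    Returns a dict with the in-memory results (trials, assessments,
    summaries, association results).  Each stage failure raises
    :class:`PipelineError` naming the stage; outputs of completed stages
    are already on disk at that point.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    thresholds = Thresholds(config.head_threshold_mm, config.pelvis_threshold_mm)
    bundle: dict = {}

    config_yaml = yaml.safe_dump(asdict(config), sort_keys=True)
    manifest = {
        "package": "equiasym",
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    # --- input stage -----------------------------------------------------
    horses = questionnaire = None
    try:
        if config.mode == "simulate":
            pop = generate_population(
                PopulationConfig(
                    n_horses=config.n_horses,
                    n_riders=config.n_riders,
                    seed=config.seed,
                    **config.population,
                )
            )
            horses, questionnaire = pop.horses, pop.questionnaire
            if config.trace_level:
                trials, qc_reports = simulate_trials_trace_level(
                    pop, noise_sd=config.noise_sd, base_seed=config.seed
                )
            else:
                trials, qc_reports = _apply_inclusion(pop.trials)
            horses.to_csv(out / "horses.csv", index=False)
            questionnaire.to_csv(out / "questionnaire.csv", index=False)
        elif config.mode == "workbook":
            schema = (DatasetSchema.from_yaml(config.schema_path)
                      if config.schema_path else None)
            data = read_study_workbook(config.input_path, schema)
            horses = data.horses
            trials, qc_reports = _apply_inclusion(data.trials)
            if len(data.row_errors):
                data.row_errors.to_csv(out / "row_errors.csv", index=False)
        elif config.mode == "csv":
            trials, qc_reports = _apply_inclusion(pd.read_csv(config.input_path))
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(f"input stage failed: {exc}") from exc
    trials.to_csv(out / "trials.csv", index=False)
    qc_reports.to_csv(out / "qc_reports.csv", index=False)
    bundle["trials"], bundle["qc_reports"] = trials, qc_reports

    # --- classification stage --------------------------------------------
    try:
        assessments = assess_horses(trials, thresholds, horses=horses)
        summaries = {
            surface: population_summary(assessments, surface)
            for surface in ("hard", "soft")
        }
        concordance = concordance_summary(assessments)
        tables = {
            cond: parameter_table(trials, cond, thresholds)
            for cond in ("straight_hard", "straight_soft")
            if (trials["condition"] == cond).any()
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"classification stage failed: {exc}") from exc
    assessments.to_csv(out / "assessments.csv", index=False)
    (out / "population_summary.json").write_text(
        json.dumps({"surfaces": summaries, "concordance": concordance}, indent=2)
    )
    for cond, tbl in tables.items():
        tbl.to_csv(out / f"parameter_table_{cond}.csv", index=False)
    bundle.update(
        assessments=assessments, summaries=summaries,
        concordance=concordance, parameter_tables=tables,
    )

    # --- association stage -----------------------------------------------
    if config.associate and questionnaire is not None:
        try:
            table = build_association_table(assessments, trials, questionnaire)
            results = run_association_suite(table)
            report = results_to_frame(results)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"association stage failed: {exc}") from exc
        report.to_csv(out / "association_results.csv", index=False)
        bundle["association_results"] = results
        bundle["association_report"] = report

    return bundle
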