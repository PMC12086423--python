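"""End-to-end reproducible runs.

``run_pipeline`` executes: simulate (or ingest) -> QC -> metrics -> staging
-> control-anchored threshold derivation -> classification (any-k rule and
PPS) -> evaluation, and writes every table plus a machine-readable manifest.
All randomness is confined to cohort simulation and is driven by the single
run seed, so identical config + seed reproduces identical artifacts byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    PPSModel,
    ThresholdSet,
    any_k_rule,
    count_elevated,
    derive_thresholds,
    fit_pps,
    pps_band,
    progression_outcome,
)
from .data import (
    ParticipantRecord,
    participants_to_frame,
    read_participants_csv,
    read_traces_csv,
    write_traces_csv,
)
from .evaluate import (
    confusion_stats,
    group_compare,
    km_estimate,
    logrank,
    offset_correlations,
    repeatability_report,
    roc,
)
from .metrics import DISCRIMINATING_METRICS, METRIC_FIELDS, compute_metrics, metrics_table
from .preprocess import ImplausibilityRules, QCConfig, qc_filter, qc_report
from .staging import stage_participants
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("cgmstaging")


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (strict: unknown keys are rejected)."""

    seed: int = 0
    simulate: CohortConfig | None = None
    traces_csv: str | None = None
    participants_csv: str | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    threshold_metrics: tuple[str, ...] = DISCRIMINATING_METRICS
    rule_k: int = 2
    pps_horizon_years: float = 1.0
    pps_band_low: float = 0.19
    pps_band_high: float = 0.4
    output_dir: str = "cgm_run"
    write_traces: bool = False
    verbosity: int = 1

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        d = dict(raw)
        for key, sub in (("simulate", CohortConfig), ("qc", QCConfig)):
            if isinstance(d.get(key), Mapping):
                d[key] = _build_dataclass(sub, d[key])
        if "threshold_metrics" in d:
            d["threshold_metrics"] = tuple(d["threshold_metrics"])
        return _build_dataclass(cls, d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _build_dataclass(cls, d: Mapping[str, Any]):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - valid
    if unknown:
        raise PipelineError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    d = dict(d)
    if cls is QCConfig and isinstance(d.get("rules"), Mapping):
        d["rules"] = _build_dataclass(ImplausibilityRules, d["rules"])
    return cls(**d)


def _config_dict(cfg) -> Any:
    if dataclasses.is_dataclass(cfg) and not isinstance(cfg, type):
        return {f.name: _config_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, Mapping):
        return {k: _config_dict(v) for k, v in cfg.items()}
    if isinstance(cfg, (list, tuple)):
        return [_config_dict(v) for v in cfg]
    return cfg


@dataclass
class PipelineResult:
    config: RunConfig
    participants: list[ParticipantRecord]
    qc: pd.DataFrame
    metrics: pd.DataFrame
    staging: pd.DataFrame
    thresholds: ThresholdSet
    classification: pd.DataFrame
    pps: PPSModel | None
    evaluation: dict
    artifacts: dict[str, str]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> PipelineResult:
    level = {0: logging.WARNING, 1: logging.INFO}.get(config.verbosity, logging.DEBUG)
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save_df(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        artifacts[name] = str(path)

    def save_text(name: str, text: str, suffix: str = "json") -> None:
        path = outdir / f"{name}.{suffix}"
        path.write_text(text)
        artifacts[name] = str(path)

    # ------------------------------------------------------------------ input
    if config.simulate is not None:
        sim = replace(config.simulate, seed=config.seed)
        log.info("simulating cohort (%d/%d/%d, seed %d)",
                 sim.n_control, sim.n_stage1, sim.n_stage2, sim.seed)
        cohort = generate_cohort(sim)
        participants, traces = cohort.participants, cohort.traces
    elif config.traces_csv and config.participants_csv:
        traces = read_traces_csv(config.traces_csv)
        participants = read_participants_csv(config.participants_csv)
    else:
        raise PipelineError("config needs either a simulate block or input CSV paths")

    save_df("participants", participants_to_frame(participants))
    if config.write_traces:
        write_traces_csv(traces, outdir / "traces.csv")
        artifacts["traces"] = str(outdir / "traces.csv")

    # --------------------------------------------------------------------- QC
    qc_results = [qc_filter(t, config.qc) for t in traces]
    qc_df = qc_report(qc_results)
    save_df("qc_report", qc_df)
    included = [r.trace for r in qc_results if r.included]
    log.info("QC: %d of %d traces included", len(included), len(traces))
    if not included:
        raise PipelineError("all traces excluded by QC")

    # ---------------------------------------------------------------- metrics
    interval = config.qc.interval_minutes
    mets = [compute_metrics(t, interval_minutes=interval) for t in included]
    mdf = metrics_table(mets)
    save_df("metrics", mdf)

    # ---------------------------------------------------------------- staging
    sdf = stage_participants(participants)
    save_df("staging", sdf)
    pdf = participants_to_frame(participants).merge(sdf[["participant_id", "label"]])

    # first QC-passed session per participant drives classification
    first = (
        mdf.sort_values(["participant_id", "session_id"])
        .groupby("participant_id", as_index=False)
        .first()
        .merge(pdf, on="participant_id")
    )

    # ------------------------------------------------------------- thresholds
    controls = first[first["label"] == "control"]
    if controls.empty:
        raise PipelineError("no controls available for threshold derivation")
    thresholds = derive_thresholds(controls, config.threshold_metrics)
    save_text("thresholds", thresholds.to_json())
    log.info("thresholds: %s", thresholds.rounded())

    # ------------------------------------------------- classification and PPS
    eligible, outcome = progression_outcome(
        first["followup_years"], first["progressed_stage3"],
        first["progression_time"], config.pps_horizon_years,
    )
    aab_pos = (first["label"] != "control").to_numpy()
    fit_mask = aab_pos & eligible
    pps = None
    if len(np.unique(outcome[fit_mask])) == 2:
        pps = fit_pps(
            first.loc[fit_mask],
            outcome[fit_mask],
            metric_names=config.threshold_metrics,
            horizon_years=config.pps_horizon_years,
        )
        save_text("pps_model", pps.to_json())
    else:
        log.warning("PPS not fitted: outcome has a single class among eligible")

    cls_rows = []
    for i, (_, row) in enumerate(first.iterrows()):
        vals = row[list(config.threshold_metrics)].to_dict()
        n_elev = count_elevated(vals, thresholds)
        entry = {
            "participant_id": row["participant_id"],
            "label": row["label"],
            "n_elevated": n_elev,
            "any_k_flag": n_elev >= config.rule_k,
            "eligible_horizon": bool(eligible[i]),
            "progressed_within_horizon": bool(outcome[i]),
        }
        if pps is not None:
            score = float(pps.score(vals)[0])
            entry["pps_score"] = score
            entry["pps_band"] = pps_band(score, config.pps_band_low, config.pps_band_high)
        cls_rows.append(entry)
    cdf = pd.DataFrame(cls_rows)
    save_df("classification", cdf)

    # ------------------------------------------------------------- evaluation
    evaluation = _evaluate(first, cdf, thresholds, config)
    save_text("evaluation", json.dumps(evaluation, indent=2, sort_keys=True,
                                       default=_json_default))

    # Table-1-style group comparison
    by_group = {
        g: first[first["label"] == g]
        for g in ("control", "stage1", "stage2")
        if (first["label"] == g).any()
    }
    if len(by_group) >= 2:
        gc = group_compare(by_group, numeric_cols=["age", *METRIC_FIELDS],
                           categorical_cols=["sex"])
        save_df("group_compare", gc)

    # repeat wears, if any participant has two QC-passed sessions
    pair_ids = mdf["participant_id"].value_counts()
    pair_ids = pair_ids[pair_ids == 2].index
    if len(pair_ids) > 0:
        pair_df = mdf[mdf["participant_id"].isin(pair_ids)]
        rep_table, rep_summary = repeatability_report(pair_df, thresholds, k=config.rule_k)
        save_df("repeatability", rep_table)
        evaluation["repeatability"] = rep_summary

    # output location and log level do not affect results: keep the manifest
    # (and its hash) identical across re-runs of the same analysis
    cfg_dict = _config_dict(config)
    cfg_dict.pop("output_dir", None)
    cfg_dict.pop("verbosity", None)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "artifacts": sorted(artifacts),
    }
    save_text("manifest", json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        config=config, participants=participants, qc=qc_df, metrics=mdf,
        staging=sdf, thresholds=thresholds, classification=cdf, pps=pps,
        evaluation=evaluation, artifacts=artifacts,
    )


def _evaluate(first: pd.DataFrame, cdf: pd.DataFrame,
              thresholds: ThresholdSet, config: RunConfig) -> dict:
    """Headline statistics of a run; tolerant of degenerate simulated cohorts."""
    ev: dict[str, Any] = {"thresholds": thresholds.rounded(3)}

    controls = first[first["label"] == "control"]
    stage2 = first[first["label"] == "stage2"]
    if len(controls) >= 3:
        ev["offset_correlations"] = offset_correlations(controls).to_dict("records")
    if not controls.empty and not stage2.empty:
        aucs = {}
        for m in config.threshold_metrics:
            scores = np.concatenate([controls[m], stage2[m]])
            labels = np.concatenate([np.zeros(len(controls)), np.ones(len(stage2))]) > 0
            r = roc(scores, labels)
            aucs[m] = {"auc": r.auc, "ci": [r.ci_low, r.ci_high]}
        ev["roc_control_vs_stage2"] = aucs

    pos = cdf[cdf["label"] != "control"]
    elig = pos[pos["eligible_horizon"]]
    if not elig.empty and elig["progressed_within_horizon"].any():
        cs = confusion_stats(elig["any_k_flag"], elig["progressed_within_horizon"])
        ev["any_k_vs_progression"] = {
            "tp": cs.tp, "fp": cs.fp, "fn": cs.fn, "tn": cs.tn, **cs.rounded()
        }
        ev["any_k_flagged_by_stage"] = {
            g: int((pos["any_k_flag"] & (pos["label"] == g)).sum())
            for g in ("stage1", "stage2")
        }

    if "pps_band" in cdf.columns:
        cs = confusion_stats(
            elig["pps_score"] >= config.pps_band_low, elig["progressed_within_horizon"]
        )
        ev["pps_ge_low_vs_progression"] = {
            "tp": cs.tp, "fp": cs.fp, "fn": cs.fn, "tn": cs.tn, **cs.rounded()
        }
        scores = elig["pps_score"].to_numpy()
        r = roc(scores, elig["progressed_within_horizon"].to_numpy(dtype=bool))
        ev["pps_roc"] = {"auc": r.auc, "ci": [r.ci_low, r.ci_high]}

        pos_part = first[first["label"] != "control"].merge(
            cdf[["participant_id", "pps_band"]], on="participant_id"
        )
        bands = {}
        groups = []
        for band in ("low", "mid", "high"):
            sub = pos_part[pos_part["pps_band"] == band]
            if sub.empty:
                continue
            km = km_estimate(sub["progression_time"], sub["progressed_stage3"],
                             config.pps_horizon_years)
            bands[band] = {"n": len(sub), "risk_pct": km.risk_pct,
                           "ci": list(km.risk_ci)}
            groups.append((sub["progression_time"].to_numpy(),
                           sub["progressed_stage3"].to_numpy(dtype=bool)))
        ev["km_risk_by_pps_band"] = bands
        if len(groups) >= 2:
            stat, p = logrank(groups)
            ev["logrank_pps_bands"] = {"statistic": stat, "p": p}

    # 1-year risk above the historical TA140 > 10 % cutoff
    pos_first = first[first["label"] != "control"]
    high = pos_first[pos_first["ta140"] > 10.0]
    if not high.empty:
        km = km_estimate(high["progression_time"], high["progressed_stage3"],
                         config.pps_horizon_years)
        ev["km_risk_ta140_gt10"] = {"n": len(high), "risk_pct": km.risk_pct,
                                    "ci": list(km.risk_ci)}
    return ev
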