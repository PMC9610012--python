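"""End-to-end orchestration: simulate -> score -> features -> models -> subgroups -> report.

A single run is driven by a :class:`RunConfig` (fully serialisable; every
run writes its resolved config, config hash and seed next to its outputs,
so reruns are reproducible end to end).  One user-facing seed governs all
stochastic stages through a documented per-stage derivation
(``crc32(stage name) XOR seed``, truncated to 31 bits).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_data, features, modeling, scoring, subgroups, synthetic_data

log = logging.getLogger("volleymine")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs; serialisable to/from dict."""

    seed: int = 0
    input_dir: str | None = None          # None -> simulate a season
    output_dir: str = "volleymine_out"
    simulate: bool = True
    subgroup_runs: int = 1000
    subgroup_top_k: int = 10
    cv_folds: int = 10
    windows: tuple[int, ...] = features.WINDOWS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = list(self.windows)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "windows" in d:
            d["windows"] = tuple(d["windows"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def _fmt(x, nd=2):
    return "n/a" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}f}"


def _strict_json(obj):
    """NaN/inf -> null so the report is valid strict JSON."""
    if isinstance(obj, dict):
        return {k: _strict_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_strict_json(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def render_report(evaluations: dict | None, subgroup_results: dict | None,
                  distributions: pd.DataFrame | None, trend: dict | None = None) -> tuple[str, dict]:
    """Markdown + JSON report from whatever stages completed."""
    md: list[str] = ["# Season analysis report", ""]
    js: dict = {}

    if distributions is not None and len(distributions):
        md += ["## Match performance by action type", "",
               "| Action | Mean score | SD | Records |", "|---|---|---|---|"]
        js["scores"] = {}
        for r in distributions.itertuples():
            md.append(f"| {r.action_type} | {_fmt(r.mean)} | {_fmt(r.sd)} | {r.n} |")
            js["scores"][r.action_type] = {"mean": r.mean, "sd": r.sd, "n": int(r.n)}
        md.append("")

    if trend:
        md += ["## Season trend (Spearman rho of score vs match index)", ""]
        js["trend"] = trend
        for side, t in trend.items():
            md.append(f"- {side}: rho = {_fmt(t['rho'])} (p = {_fmt(t['p'], 3)}, n = {t['n']})")
        md.append("")

    if evaluations:
        md += ["## Model evaluation", "",
               "| Side | Model | MAE (95% CI) | MAE reduction | p | Cohen's d (95% CI) | Effect |",
               "|---|---|---|---|---|---|---|"]
        js["models"] = {}
        for side, evals in evaluations.items():
            js["models"][side] = {}
            for kind, ev in evals.items():
                ci = f"{_fmt(ev.mae_ci[0])}-{_fmt(ev.mae_ci[1])}"
                if kind == "naive_baseline":
                    md.append(f"| {side} | {kind} | {_fmt(ev.mae)} ({ci}) | | | | |")
                else:
                    dci = f"{_fmt(ev.d_ci[0])}-{_fmt(ev.d_ci[1])}"
                    md.append(
                        f"| {side} | {kind} | {_fmt(ev.mae)} ({ci}) | -{_fmt(ev.mae_reduction_pct, 1)}% "
                        f"| {_fmt(ev.paired_p, 4)} | {_fmt(ev.cohens_d)} ({dci}) | {ev.effect} |")
                js["models"][side][kind] = {
                    "mae": ev.mae, "mae_ci": list(ev.mae_ci), "n_test": ev.n_test,
                    "mae_reduction_pct": ev.mae_reduction_pct, "paired_p": ev.paired_p,
                    "cohens_d": ev.cohens_d, "d_ci": list(ev.d_ci), "effect": ev.effect,
                    "degenerate": ev.degenerate,
                }
        md.append("")

    if subgroup_results is not None:
        md += ["## Subgroup discovery (significant at 5% false-discovery probability)", "",
               "| Action | Subgroup | Sign | Size | p | Cohen's d (95% CI) | Effect |",
               "|---|---|---|---|---|---|---|"]
        js["subgroups"] = {}
        for action, res in subgroup_results.items():
            sig = res[res["significant"]] if len(res) else res
            js["subgroups"][action] = [
                {"condition": f"{r.feature} {r.operator} {r.threshold:g}",
                 "quality": r.quality, "size_fraction": r.size_fraction,
                 "fd_probability": r.fd_probability, "cohens_d": r.cohens_d,
                 "d_ci": [r.d_ci_low, r.d_ci_high], "effect": r.effect}
                for r in sig.itertuples()
            ]
            if not len(sig):
                md.append(f"| {action} | No significant results | | | | | |")
            for r in sig.itertuples():
                sign = "+" if r.quality > 0 else "-"
                md.append(
                    f"| {action} | {r.feature} {r.operator} {r.threshold:g} | {sign} "
                    f"| {r.size_fraction * 100:.1f}% | {_fmt(r.fd_probability, 3)} "
                    f"| {_fmt(r.cohens_d)} ({_fmt(r.d_ci_low)}-{_fmt(r.d_ci_high)}) | {r.effect} |")
        md.append("")

    return "\n".join(md), _strict_json(js)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a bundle of in-memory results.

    Writes per-stage CSV/markdown/JSON artifacts into
    ``config.output_dir``; any stage failure raises :class:`StageError`
    naming the stage, with earlier outputs left on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(
        {**config.to_dict(), "config_hash": config.config_hash()}, indent=2) + "\n")

    # -- simulate / load ---------------------------------------------------
    try:
        if config.input_dir is None and config.simulate:
            dataset, historic = synthetic_data.generate_season(
                seed=stage_seed(config.seed, "simulate"))
            season_dir = out / "season"
            core_data.write_season(dataset, season_dir)
            historic.to_csv(season_dir / "historic_outcomes.csv", index=False)
        else:
            dataset = core_data.load_season(config.input_dir)
            historic = pd.read_csv(Path(config.input_dir) / "historic_outcomes.csv")
        log.info("dataset: %d players, %d action rows", dataset.roster["player_id"].nunique(),
                 len(dataset.actions))
    except Exception as e:
        raise StageError("simulate/load", e) from e

    # -- scoring -----------------------------------------------------------
    try:
        score_map = scoring.build_score_map(historic)
        targets = scoring.targets_from_dataset(dataset, score_map)
        targets.to_csv(out / "performance_targets.csv", index=False)
        log.info("scoring: %d performance targets", len(targets))
    except Exception as e:
        raise StageError("score", e) from e

    # -- features ----------------------------------------------------------
    try:
        fcfg = features.FeatureConfig(windows=tuple(config.windows))
        matrix = features.build_feature_matrix(dataset, targets, fcfg)
        matrix.to_csv(out / "features.csv", index=False)
        log.info("features: %d rows x %d predictors", len(matrix),
                 len(features.predictor_columns(matrix)))
    except Exception as e:
        raise StageError("features", e) from e

    distributions = (targets.groupby("action_type")
                     .agg(mean=("score", "mean"), sd=("score", "std"), n=("score", "size"))
                     .reset_index())
    trend = modeling.season_trend(targets)

    # -- modeling ----------------------------------------------------------
    evaluations = {}
    try:
        for side in ("offense", "defense"):
            evaluations[side] = modeling.run_model_comparison(
                matrix, side, seed=stage_seed(config.seed, f"model-{side}"),
                cv_folds=config.cv_folds)
            log.info("modeling %s: baseline MAE %.3f", side,
                     evaluations[side]["naive_baseline"].mae)
    except Exception as e:
        raise StageError("modeling", e) from e

    # -- subgroups ---------------------------------------------------------
    subgroup_results = {}
    try:
        for action in scoring.RELEVANT_ACTIONS:
            res = subgroups.subgroup_analysis(
                matrix, action, n_runs=config.subgroup_runs,
                seed=stage_seed(config.seed, f"subgroups-{action}"),
                top_k=config.subgroup_top_k)
            subgroup_results[action] = res
            res.to_csv(out / f"subgroups_{action}.csv", index=False)
            log.info("subgroups %s: %d significant", action,
                     int(res["significant"].sum()) if len(res) else 0)
    except Exception as e:
        raise StageError("subgroups", e) from e

    # -- report ------------------------------------------------------------
    try:
        md, js = render_report(evaluations, subgroup_results, distributions, trend)
        js["config_hash"] = config.config_hash()
        js["seed"] = config.seed
        (out / "report.md").write_text(md)
        (out / "report.json").write_text(json.dumps(js, indent=2, allow_nan=False) + "\n")
    except Exception as e:
        raise StageError("report", e) from e

    return {"dataset": dataset, "score_map": score_map, "targets": targets,
            "matrix": matrix, "evaluations": evaluations,
            "subgroups": subgroup_results, "distributions": distributions,
            "trend": trend, "report_json": js}
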