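"""End-to-end orchestration: simulate or load, filter, rank, select, learn.

One config drives the whole analysis and one master seed fans out
deterministically to every stochastic stage (generator truth,
missingness, CV splits, bootstrap, BN restarts), so a run is exactly
reproducible and each stage is independently re-runnable from its
derived seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, bn as bnmod, generator as gen
from .cohort import (Cohort, RawCohort, complete_case_filter, read_cohort,
                     summarize_panels, write_cohort)
from .models import aic_backward_eliminate, nagelkerke_drop_ranking
from .ranking import MetricSpec, SelectionTrace, drop_one_importance_multi, skeletonize
from .schema import OUTCOME, crash_schema

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "derive_seed"]

_STAGES = ("truth", "sample", "missingness", "cv", "bootstrap_sp",
           "bootstrap_se", "bn", "queries")


def derive_seed(master: int, stage: str) -> int:
    """Stage seed derived from the master seed; stable and documented.

    Uses numpy's SeedSequence with the stage index as spawn key, folded
    to a 31-bit integer.
    """
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([int(master), idx]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    input_path: str | None = None  # CSV path; None = simulate
    n: int = 5000
    master_seed: int = 0
    folds: int = 5
    cycles: int = 6
    pauc_range: tuple[float, float] = (0.9, 1.0)
    alpha: float = 0.05
    boot_reps: int = 2000
    bn_restarts: int = 2
    bn_smoothing: float = 1.0
    calibrate_generator: bool = True
    apply_missingness: bool = True
    output_dir: str = "tbiroc_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.pauc_range, list):
            cfg.pauc_range = tuple(cfg.pauc_range)
        return cfg


@dataclass
class ReportBundle:
    output_dir: Path
    frequency_table: pd.DataFrame
    importance: dict[str, pd.DataFrame]
    traces: dict[str, SelectionTrace]
    aic_trace: pd.DataFrame
    key_predictors: dict[str, list[str]]
    bn_edges: dict[str, list[tuple[str, str]]]
    queries: dict[str, dict]
    manifest: dict


def _build_cohort(cfg: PipelineConfig) -> tuple[RawCohort, dict]:
    if cfg.input_path is not None:
        raw = read_cohort(cfg.input_path, crash_schema())
        return raw, {"source": cfg.input_path}
    model = gen.default_truth(derive_seed(cfg.master_seed, "truth"))
    if cfg.calibrate_generator:
        model = gen.calibrate(model)
    cohort = gen.sample_cohort(model, cfg.n, derive_seed(cfg.master_seed, "sample"))
    if cfg.apply_missingness:
        raw = gen.apply_missingness(cohort, seed=derive_seed(cfg.master_seed, "missingness"))
    else:
        raw = RawCohort(cohort.records, cohort.schema)
    return raw, {"source": "synthetic", "n": cfg.n,
                 "calibrated": cfg.calibrate_generator}


def _float_fmt(x):
    return float(x) if isinstance(x, (np.floating, float)) else x


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run the full analysis and write all artifacts under the output dir."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    raw, source_info = _build_cohort(cfg)
    write_cohort(raw, out / "raw_cohort.csv")
    cohort, report = complete_case_filter(raw)
    if cohort.n == 0:
        raise RuntimeError("filter stage: no complete-case records retained")
    report.to_json(out / "exclusion_report.json")
    freq = summarize_panels(raw)
    freq.to_csv(out / "frequency_table.csv", index=False)

    predictors = list(cohort.schema.predictors)
    cv_seed = derive_seed(cfg.master_seed, "cv")
    specs = {
        "full_auc": MetricSpec("full_auc", cfg.pauc_range, cfg.folds, cfg.cycles, cv_seed),
        "pauc_specificity": MetricSpec("pauc_specificity", cfg.pauc_range,
                                       cfg.folds, cfg.cycles, cv_seed),
        "pauc_sensitivity": MetricSpec("pauc_sensitivity", cfg.pauc_range,
                                       cfg.folds, cfg.cycles, cv_seed),
    }

    importance = {"nagelkerke": nagelkerke_drop_ranking(cohort, predictors)}
    importance.update(drop_one_importance_multi(cohort, predictors, list(specs.values())))
    for name, tbl in importance.items():
        tbl.to_csv(out / f"importance_{name}.csv", index=False)

    aic = aic_backward_eliminate(cohort, predictors)
    aic.steps.to_csv(out / "aic_backward_trace.csv", index=False)

    traces: dict[str, SelectionTrace] = {}
    key_predictors: dict[str, list[str]] = {}
    for short, target, seed_stage in (("sp", "pauc_specificity", "bootstrap_sp"),
                                      ("se", "pauc_sensitivity", "bootstrap_se")):
        trace = skeletonize(cohort, importance[target], specs[target],
                            alpha=cfg.alpha, boot_reps=cfg.boot_reps,
                            seed=derive_seed(cfg.master_seed, seed_stage))
        trace.to_json(out / f"selection_trace_{short}.json")
        trace.layout().to_csv(out / f"selection_layout_{short}.csv")
        traces[target] = trace
        key_predictors[target] = trace.key_predictors

    # constrained Bayesian-network association analysis -----------------
    bn_edges: dict[str, list[tuple[str, str]]] = {}
    queries: dict[str, dict] = {}
    data = cohort.records[predictors + [OUTCOME]]
    states = {v: cohort.schema[v].categories for v in data.columns}
    for target, keys in key_predictors.items():
        short = "sp" if target.endswith("specificity") else "se"
        constraints = bnmod.EdgeConstraints(
            whitelist=frozenset((k, OUTCOME) for k in keys))
        dag = bnmod.hill_climb(data, constraints, states=states,
                               restarts=cfg.bn_restarts,
                               seed=derive_seed(cfg.master_seed, "bn"))
        pbn = bnmod.fit_cpts(dag, data, states=states, smoothing=cfg.bn_smoothing)
        bn_edges[target] = sorted(dag.edges)
        (out / f"bn_{short}.dot").write_text(bnmod.dag_to_dot(dag, set(keys)))
        (out / f"bn_{short}_edges.txt").write_text(
            "\n".join(f"{u}\t{v}" for u, v in sorted(dag.edges)) + "\n")
        with open(out / f"bn_{short}_cpts.json", "w") as fh:
            json.dump({v: pbn.cpts[v].tolist() for v in dag.nodes}, fh)
        q = {
            "P(ec | cause=road traffic accident)":
                bnmod.query(pbn, "ec", {"cause": "road traffic accident"}).to_dict(),
            "P(ec | cause=fall >2 meters)":
                bnmod.query(pbn, "ec", {"cause": "fall >2 meters"}).to_dict(),
            "P(ec | cause=other)":
                bnmod.query(pbn, "ec", {"cause": "other"}).to_dict(),
            "P(cause | age=<20)": bnmod.query(pbn, "cause", {"age": "<20"}).to_dict(),
            "P(cause | age=>55)": bnmod.query(pbn, "cause", {"age": ">55"}).to_dict(),
        }
        queries[target] = q
        with open(out / f"bn_{short}_queries.json", "w") as fh:
            json.dump(q, fh, indent=2)

    manifest = {
        "package": "tbiroc",
        "version": __version__,
        "python": platform.python_version(),
        "master_seed": cfg.master_seed,
        "stage_seeds": {s: derive_seed(cfg.master_seed, s) for s in _STAGES},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "source": source_info,
        "n_raw": raw.n,
        "n_complete": cohort.n,
        "key_predictors": key_predictors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return ReportBundle(
        output_dir=out, frequency_table=freq, importance=importance,
        traces=traces, aic_trace=aic.steps, key_predictors=key_predictors,
        bn_edges=bn_edges, queries=queries, manifest=manifest)
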