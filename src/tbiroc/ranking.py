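"""Drop-one importance ranking and stepwise model skeletonization.

The core procedure of the analysis: rank predictors by the percent
decrease in a target ROC metric (full AUC, or standardized partial AUC
over the 90-100% specificity or sensitivity band) when each is dropped
from the cross-validated complete model, then peel off the
lowest-ranking variables one at a time until the drop in the metric
versus the complete model becomes significant.  The surviving set is
the "key predictors".

All model comparisons are paired: every candidate model is evaluated on
the identical cross-validation splits as the complete model.  Full-AUC
comparisons use DeLong's test; partial-area comparisons use the
stratified paired bootstrap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import rocm
from .cohort import Cohort
from .models import CVPredictions, cv_predict, _rank_table, _ordered_predictors

__all__ = [
    "MetricSpec",
    "SelectionTrace",
    "drop_one_importance",
    "drop_one_importance_multi",
    "skeletonize",
]

_TARGETS = ("full_auc", "pauc_specificity", "pauc_sensitivity")


@dataclass(frozen=True)
class MetricSpec:
    """Which ROC target drives the ranking, plus the CV settings."""

    target: str = "pauc_specificity"
    range: tuple[float, float] = (0.9, 1.0)
    folds: int = 5
    cycles: int = 6
    split_seed: int = 0
    pool: str = "pooled"  # or "averaged": per-record mean across cycles

    def __post_init__(self) -> None:
        if self.target not in _TARGETS:
            raise ValueError(f"target must be one of {_TARGETS}")
        lo, hi = self.range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("range must be a non-empty sub-interval of [0, 1]")

    @property
    def axis(self) -> str:
        return "sensitivity" if self.target == "pauc_sensitivity" else "specificity"

    def evaluate(self, scores: np.ndarray, labels: np.ndarray) -> float:
        if self.target == "full_auc":
            return rocm.auc(rocm.roc_curve(scores, labels))
        return rocm.standardized_pauc(scores, labels, self.axis, self.range)


def _cv_scores(cohort: Cohort, predictors, spec: MetricSpec) -> tuple[np.ndarray, np.ndarray, CVPredictions]:
    cv = cv_predict(cohort, predictors, folds=spec.folds, cycles=spec.cycles,
                    split_seed=spec.split_seed)
    scores, labels = cv.averaged() if spec.pool == "averaged" else cv.pooled()
    return scores, labels, cv


def drop_one_importance_multi(cohort: Cohort, predictors,
                              specs: list[MetricSpec]) -> dict[str, pd.DataFrame]:
    """Drop-one importance under several ROC targets from one CV pass.

    All specs must share CV settings (the predictions do not depend on
    the metric target); returns one ranking table per target.
    """
    ordered = _ordered_predictors(cohort, predictors)
    if len(ordered) < 2:
        raise ValueError("need at least two predictors to rank")
    base = specs[0]
    for s in specs[1:]:
        if (s.folds, s.cycles, s.split_seed, s.pool) != (
                base.folds, base.cycles, base.split_seed, base.pool):
            raise ValueError("all metric specs must share CV settings")
    scores, labels, cv_full = _cv_scores(cohort, ordered, base)
    fulls = {s.target: s.evaluate(scores, labels) for s in specs}
    rows: dict[str, list[dict]] = {s.target: [] for s in specs}
    for v in ordered:
        sc, lb, cv_v = _cv_scores(cohort, [p for p in ordered if p != v], base)
        assert cv_v.fold_hash() == cv_full.fold_hash()
        for s in specs:
            m = s.evaluate(sc, lb)
            full = fulls[s.target]
            rows[s.target].append({
                "predictor": v, "metric_full": full, "metric_without": m,
                "drop": full - m, "percent_drop": 100.0 * (full - m) / full})
    return {t: _rank_table(r) for t, r in rows.items()}


def drop_one_importance(cohort: Cohort, predictors, spec: MetricSpec) -> pd.DataFrame:
    """Percent drop in the target metric when each predictor is left out.

    The complete model and every leave-one-out model share identical CV
    fold memberships; percent_drop may be negative (removing a variable
    can improve out-of-sample performance), ties break alphabetically.
    """
    return drop_one_importance_multi(cohort, predictors, [spec])[spec.target]


@dataclass
class SelectionTrace:
    """Stepwise elimination ledger mirroring the published model tables.

    ``models[k]`` retains ``p - k - 1`` predictors (model k+1 of the
    tables); each row records the metric, its CI and the paired p-value
    of the comparison against the complete model.
    """

    complete_predictors: list[str]
    ranking: pd.DataFrame
    models: pd.DataFrame  # columns: model, retained, metric, ci_low, ci_high, p_value
    metric_complete: float
    ci_complete: tuple[float, float]
    selected_index: int  # -1 = complete model (first comparison already significant)
    alpha: float
    method: str

    @property
    def key_predictors(self) -> list[str]:
        if self.selected_index < 0:
            return list(self.complete_predictors)
        return list(self.models.iloc[self.selected_index]["retained"])

    def layout(self) -> pd.DataFrame:
        """Rank x model '+'-mark layout in the style of the published tables."""
        order = list(self.ranking["predictor"])
        cols = {"Complete": ["+"] * len(order)}
        for _, row in self.models.iterrows():
            retained = set(row["retained"])
            cols[str(int(row["model"]))] = ["+" if v in retained else "" for v in order]
        out = pd.DataFrame(cols, index=pd.Index(order, name="variable"))
        out.insert(0, "rank", np.arange(1, len(order) + 1))
        return out

    def to_json(self, path: str | Path) -> None:
        obj = {
            "complete_predictors": self.complete_predictors,
            "metric_complete": self.metric_complete,
            "ci_complete": list(self.ci_complete),
            "alpha": self.alpha,
            "method": self.method,
            "selected_index": int(self.selected_index),
            "key_predictors": self.key_predictors,
            "models": [
                {"model": int(r["model"]), "retained": list(r["retained"]),
                 "metric": float(r["metric"]), "ci_low": float(r["ci_low"]),
                 "ci_high": float(r["ci_high"]), "p_value": float(r["p_value"])}
                for _, r in self.models.iterrows()
            ],
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def skeletonize(cohort: Cohort, ranking: pd.DataFrame, spec: MetricSpec,
                alpha: float = 0.05, boot_reps: int = 2000,
                seed: int = 0) -> SelectionTrace:
    """Stepwise elimination of the lowest-ranking predictors.

    The ranking is fixed from the complete model and never recomputed;
    model k drops the k lowest-ranked predictors.  Each model's pooled
    CV predictions are compared against the complete model on identical
    splits; the selected ("most simplistic") model is the last whose
    p-value is >= alpha before the first significant drop.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    order = list(ranking.sort_values("rank")["predictor"])
    missing = set(order) ^ set(_ordered_predictors(cohort, order))
    if missing:
        raise ValueError(f"ranking does not cover the cohort predictors: {missing}")
    p = len(order)
    scores_c, labels, cv_c = _cv_scores(cohort, order, spec)
    metric_c = spec.evaluate(scores_c, labels)
    ci_c = rocm.pauc_ci(scores_c, labels, spec.axis,
                        spec.range if spec.target != "full_auc" else (0.0, 1.0),
                        reps=boot_reps, seed=seed)
    rows = []
    crossed = False
    selected = -1
    for k in range(1, p):
        retained = order[: p - k]
        s, l, cv_k = _cv_scores(cohort, retained, spec)
        assert cv_k.fold_hash() == cv_c.fold_hash()
        metric = spec.evaluate(s, l)
        band = spec.range if spec.target != "full_auc" else (0.0, 1.0)
        ci = rocm.pauc_ci(s, l, spec.axis, band, reps=boot_reps,
                          seed=seed + k)
        if spec.target == "full_auc":
            test = rocm.delong_test(scores_c, s, labels)
        else:
            test = rocm.bootstrap_pauc_test(scores_c, s, labels, spec.axis,
                                            spec.range, reps=boot_reps,
                                            seed=seed + k)
        rows.append({"model": k, "retained": retained, "metric": metric,
                     "ci_low": ci[0], "ci_high": ci[1], "p_value": test.p_value})
        if not crossed:
            if test.p_value >= alpha:
                selected = k - 1
            else:
                crossed = True
    models = pd.DataFrame(rows)
    return SelectionTrace(
        complete_predictors=order,
        ranking=ranking.reset_index(drop=True),
        models=models,
        metric_complete=metric_c,
        ci_complete=ci_c,
        selected_index=selected,
        alpha=alpha,
        method="delong" if spec.target == "full_auc" else "bootstrap",
    )
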