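"""Logistic outcome models over dummy-coded categorical predictors.

Covers the model-fit side of the analysis: reference-coded design
matrices, maximum-likelihood logistic fits, repeated K-fold
cross-validated out-of-sample predictions (the input to every ROC-based
ranking), Nagelkerke pseudo-R² drop ranking, and AIC backward
elimination.  Fold partitions depend only on (n, folds, cycles,
split_seed), never on the predictor subset, so models compared against
each other are evaluated on identical splits — the pairing the DeLong
and bootstrap comparisons rely on.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .cohort import Cohort

__all__ = [
    "DesignMatrix",
    "FittedModel",
    "CVPredictions",
    "encode_design",
    "fit_logistic",
    "cv_predict",
    "nagelkerke_r2",
    "nagelkerke_drop_ranking",
    "aic_backward_eliminate",
    "AICTrace",
]


@dataclass
class DesignMatrix:
    """Indicator columns in per-predictor blocks (first category = reference)."""

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]
    block_map: dict[str, list[int]]

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class FittedModel:
    coefficients: np.ndarray
    intercept: float
    log_likelihood: float
    n: int
    converged: bool
    column_names: list[str]

    @property
    def n_params(self) -> int:
        return len(self.coefficients) + 1

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(self.intercept + X @ self.coefficients)


def _ordered_predictors(cohort: Cohort, predictors) -> list[str]:
    wanted = set(predictors)
    unknown = wanted - set(cohort.schema.predictors)
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    return [p for p in cohort.schema.predictors if p in wanted]


def encode_design(cohort: Cohort, predictors) -> DesignMatrix:
    """Dummy-code the chosen predictors, one block each, schema order."""
    ordered = _ordered_predictors(cohort, predictors)
    if not ordered:
        raise ValueError("predictors must be a non-empty subset")
    cols, names = [], []
    block_map: dict[str, list[int]] = {}
    for p in ordered:
        cats = cohort.schema[p].categories
        observed = cohort.records[p].nunique()
        if observed < 2:
            raise ValueError(f"predictor {p!r} has a single observed category")
        idx = []
        for cat in cats[1:]:
            idx.append(len(names))
            names.append(f"{p}[{cat}]")
            cols.append((cohort.records[p] == cat).to_numpy(dtype=float))
        block_map[p] = idx
    X = np.column_stack(cols)
    return DesignMatrix(X=X, y=cohort.y, column_names=names, block_map=block_map)


def fit_logistic(design: DesignMatrix | None = None, *, X: np.ndarray | None = None,
                 y: np.ndarray | None = None,
                 column_names: list[str] | None = None) -> FittedModel:
    """Maximum-likelihood logistic regression (Newton/IRLS via statsmodels).

    Falls back to L-BFGS when the Hessian is singular (e.g. collinear
    indicator blocks, where the MLE is non-unique but the likelihood is
    still well defined).  Non-convergence is flagged, never silent.
    """
    if design is not None:
        X, y, column_names = design.X, design.y, design.column_names
    if X is None or y is None:
        raise ValueError("either a DesignMatrix or X and y are required")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need more records than free parameters")
    Xc = sm.add_constant(X, has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xc)
        try:
            res = model.fit(disp=0, method="newton", maxiter=100, tol=1e-10)
        except (np.linalg.LinAlgError, Exception):
            res = model.fit(disp=0, method="lbfgs", maxiter=1000)
        converged = bool(res.mle_retvals.get("converged", True))
    params = np.asarray(res.params, dtype=float)
    return FittedModel(
        coefficients=params[1:],
        intercept=float(params[0]),
        log_likelihood=float(res.llf),
        n=len(y),
        converged=converged,
        column_names=list(column_names) if column_names else
        [f"x{i}" for i in range(X.shape[1])],
    )


def fit_intercept_only(y: np.ndarray) -> FittedModel:
    """Closed-form null model: intercept = logit(prevalence)."""
    y = np.asarray(y, dtype=float)
    p = y.mean()
    if not 0 < p < 1:
        raise ValueError("outcome has a single class")
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return FittedModel(coefficients=np.empty(0), intercept=float(np.log(p / (1 - p))),
                       log_likelihood=ll, n=len(y), converged=True, column_names=[])


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVPredictions:
    """Pooled out-of-sample probabilities over (record, cycle) pairs."""

    table: pd.DataFrame  # columns: record, cycle, prob, outcome
    folds: int
    cycles: int
    split_seed: int
    fold_assignment: dict[int, np.ndarray]

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All (record, cycle) predictions stacked: (scores, labels)."""
        return (self.table["prob"].to_numpy(), self.table["outcome"].to_numpy())

    def averaged(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-record mean probability across cycles."""
        g = self.table.groupby("record", sort=True).agg(
            prob=("prob", "mean"), outcome=("outcome", "first"))
        return g["prob"].to_numpy(), g["outcome"].to_numpy()

    def fold_hash(self) -> str:
        """Digest of the fold memberships; equal hashes == identical splits."""
        h = hashlib.sha256()
        for c in sorted(self.fold_assignment):
            h.update(self.fold_assignment[c].tobytes())
        return h.hexdigest()


def _fold_assignment(n: int, folds: int, cycles: int, split_seed: int) -> dict[int, np.ndarray]:
    out = {}
    for c in range(cycles):
        rng = np.random.default_rng(np.random.SeedSequence([int(split_seed), c]))
        perm = rng.permutation(n)
        assign = np.empty(n, dtype=np.int64)
        for f, chunk in enumerate(np.array_split(perm, folds)):
            assign[chunk] = f
        out[c] = assign
    return out


def cv_predict(cohort: Cohort, predictors, folds: int = 5, cycles: int = 6,
               split_seed: int = 0) -> CVPredictions:
    """Repeated K-fold out-of-sample predicted probabilities.

    Each cycle draws a fresh random partition; every record is predicted
    exactly once per cycle by a model trained on the other folds.
    Training-fold indicator columns that are constant (a category absent
    from the fold) are dropped for that fit only.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    design = encode_design(cohort, predictors)
    n = design.n
    assignment = _fold_assignment(n, folds, cycles, split_seed)
    eps = 1e-12
    recs, cycs, probs, outs = [], [], [], []
    for c in range(cycles):
        assign = assignment[c]
        for f in range(folds):
            test = assign == f
            train = ~test
            Xtr, ytr = design.X[train], design.y[train]
            keep = Xtr.std(axis=0) > 0
            model = fit_logistic(X=Xtr[:, keep], y=ytr,
                                 column_names=[design.column_names[i]
                                               for i in np.flatnonzero(keep)])
            p = model.predict(design.X[test][:, keep])
            recs.append(np.flatnonzero(test))
            cycs.append(np.full(test.sum(), c))
            probs.append(np.clip(p, eps, 1 - eps))
            outs.append(design.y[test])
    table = pd.DataFrame({
        "record": np.concatenate(recs),
        "cycle": np.concatenate(cycs),
        "prob": np.concatenate(probs),
        "outcome": np.concatenate(outs),
    }).sort_values(["cycle", "record"], kind="mergesort").reset_index(drop=True)
    return CVPredictions(table=table, folds=folds, cycles=cycles,
                         split_seed=split_seed, fold_assignment=assignment)


# ---------------------------------------------------------------------------
# Nagelkerke R² and rankings


def nagelkerke_r2(full: FittedModel, null: FittedModel) -> float:
    """Nagelkerke's normalized Cox-Snell pseudo-R² in [0, 1]."""
    if full.n != null.n:
        raise ValueError("full and null models must share records")
    if null.coefficients.size != 0:
        raise ValueError("null model must be intercept-only")
    if full.log_likelihood < null.log_likelihood - 1e-8:
        raise ValueError("full model log-likelihood below null (nested MLE violated)")
    n = full.n
    cox_snell = 1.0 - np.exp(2.0 * (null.log_likelihood - full.log_likelihood) / n)
    max_cs = 1.0 - np.exp(2.0 * null.log_likelihood / n)
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0))


def _rank_table(rows: list[dict]) -> pd.DataFrame:
    tbl = pd.DataFrame(rows)
    tbl = tbl.sort_values(["drop", "predictor"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    tbl["rank"] = np.arange(1, len(tbl) + 1)
    return tbl


def nagelkerke_drop_ranking(cohort: Cohort, predictors) -> pd.DataFrame:
    """Drop-one importance from full-data Nagelkerke R² decreases."""
    ordered = _ordered_predictors(cohort, predictors)
    if len(ordered) < 2:
        raise ValueError("need at least two predictors to rank")
    null = fit_intercept_only(cohort.y)
    full = fit_logistic(encode_design(cohort, ordered))
    r2_full = nagelkerke_r2(full, null)
    rows = []
    for v in ordered:
        reduced = fit_logistic(encode_design(cohort, [p for p in ordered if p != v]))
        r2_without = nagelkerke_r2(reduced, null)
        rows.append({"predictor": v, "metric_full": r2_full,
                     "metric_without": r2_without, "drop": r2_full - r2_without,
                     "percent_drop": 100.0 * (r2_full - r2_without) / r2_full
                     if r2_full > 0 else 0.0})
    return _rank_table(rows)


@dataclass
class AICTrace:
    """Backward-elimination ledger: one row per removal attempt."""

    steps: pd.DataFrame  # columns: step, removed, aic, n_predictors
    final_predictors: list[str]
    final_aic: float


def aic_backward_eliminate(cohort: Cohort, predictors) -> AICTrace:
    """Greedy backward elimination on AIC: drop whole predictor blocks.

    At each step removes the block whose exclusion lowers AIC most;
    stops when every single removal would raise it.
    """
    current = _ordered_predictors(cohort, predictors)
    if not current:
        raise ValueError("need at least one predictor")

    def model_aic(preds) -> float:
        if not preds:
            return fit_intercept_only(cohort.y).aic
        m = fit_logistic(encode_design(cohort, preds))
        if not m.converged:
            raise RuntimeError(f"fit failed to converge for predictors {preds}")
        return m.aic

    aic_now = model_aic(current)
    rows = [{"step": 0, "removed": None, "aic": aic_now, "n_predictors": len(current)}]
    step = 0
    while current:
        candidates = [(model_aic([p for p in current if p != v]), v) for v in current]
        best_aic, best_v = min(candidates)
        if best_aic >= aic_now:
            break
        step += 1
        current = [p for p in current if p != best_v]
        aic_now = best_aic
        rows.append({"step": step, "removed": best_v, "aic": aic_now,
                     "n_predictors": len(current)})
    return AICTrace(steps=pd.DataFrame(rows), final_predictors=current,
                    final_aic=aic_now)
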