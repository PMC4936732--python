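"""Synthetic head-injury cohort generator.

Emulates the statistical structure the downstream analysis assumes: the
trial's marginal category frequencies, a planted dependency DAG among
the admission predictors, a logistic outcome mechanism, and the trial's
missing-data codes ("no data", "unable to assess", "scan not done").

Dependence among the assessment and imaging variables is induced by an
ordinal latent severity driver with graded-response CPTs, collapsed onto
the observed motor-response node (the clinically dominant severity
marker): motor absorbs the latent, and every other severity-linked
variable keeps an exact single-parent CPT given motor.  Marginals are
then calibrated, in topological order, by per-category log-odds shifts
against exactly computed marginals, so the model reproduces the target
frequency table while keeping its dependence structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from . import bn as bnmod
from .bn import DAG, ParameterizedBN
from .cohort import Cohort, RawCohort
from .schema import (ALIVE_UNKNOWN, IMAGING_VARS, NO_DATA, OUTCOME, PREDICTORS,
                     SCAN_NOT_DONE, UNABLE_TO_ASSESS, Schema, VariableSchema,
                     crash_schema)

__all__ = [
    "GenerativeModel",
    "MissingnessConfig",
    "CalibrationTargets",
    "default_truth",
    "default_targets",
    "calibrate",
    "sample_cohort",
    "apply_missingness",
    "planted_model",
]


# ---------------------------------------------------------------------------
# model container


@dataclass
class GenerativeModel:
    """Predictor Bayesian network plus a logistic outcome mechanism.

    ``outcome_coefficients[v]`` holds one log-odds offset per category of
    ``v`` (reference offsets need not be zero; only contrasts matter).
    The outcome is drawn as Bernoulli(sigmoid(intercept + sum of
    offsets)), positive class = poor outcome.
    """

    bn: ParameterizedBN
    outcome_coefficients: dict[str, np.ndarray]
    outcome_intercept: float
    schema: Schema

    def __post_init__(self) -> None:
        for v in self.bn.dag.nodes:
            if v not in self.outcome_coefficients:
                raise ValueError(f"no outcome coefficients for predictor {v!r}")
            if len(self.outcome_coefficients[v]) != self.bn.card(v):
                raise ValueError(f"coefficient length mismatch for {v!r}")

    @property
    def predictors(self) -> tuple[str, ...]:
        return self.bn.dag.nodes

    def exact_marginal(self, var: str) -> np.ndarray:
        return bnmod.exact_marginal(self.bn, var)

    def to_dict(self) -> dict:
        return {
            "edges": sorted(map(list, self.bn.dag.edges)),
            "states": {v: list(s) for v, s in self.bn.states.items()},
            "cpts": {v: self.bn.cpts[v].tolist() for v in self.bn.dag.nodes},
            "outcome_coefficients": {v: list(map(float, c))
                                     for v, c in self.outcome_coefficients.items()},
            "outcome_intercept": float(self.outcome_intercept),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)


# ---------------------------------------------------------------------------
# defaults


@dataclass(frozen=True)
class MissingnessConfig:
    """Missing-data mechanism (MCAR throughout).

    * ``p_no_ct`` — CT scan not performed: "scan not done" on all five
      imaging variables jointly.
    * ``p_imaging_no_data`` — among scanned records, all five imaging
      findings unrecorded jointly ("no data"); the trial reports 128 of
      7945 scanned patients with CT findings missing.
    * ``mcar_no_data`` — per-variable independent "no data" rates.
    * ``p_pupils_unassessable`` — pupil reaction not assessable.
    * ``p_outcome_unknown`` / ``p_outcome_no_data`` — six-month outcome
      alive-with-unknown-disability / entirely unrecorded.
    """

    p_no_ct: float = 2063 / 10008
    p_imaging_no_data: float = 128 / 7945
    mcar_no_data: tuple[tuple[str, float], ...] = (
        ("cause", 143 / 10008),
        ("ec", 238 / 10008),
    )
    p_pupils_unassessable: float = 538 / 10008
    p_outcome_unknown: float = 120 / 10008
    p_outcome_no_data: float = 333 / 10008

    def __post_init__(self) -> None:
        probs = [self.p_no_ct, self.p_imaging_no_data, self.p_pupils_unassessable,
                 self.p_outcome_unknown, self.p_outcome_no_data,
                 *(p for _, p in self.mcar_no_data)]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("missingness probabilities must lie in [0, 1]")

    def expected_retention(self) -> float:
        """Complete-case retention probability under independent MCAR."""
        keep = (1.0 - self.p_no_ct) * (1.0 - self.p_imaging_no_data)
        keep *= 1.0 - self.p_pupils_unassessable
        keep *= 1.0 - self.p_outcome_unknown - self.p_outcome_no_data
        for _, p in self.mcar_no_data:
            keep *= 1.0 - p
        return keep


# Complete-data category counts of the trial's frequency table; the
# calibration targets are these counts normalized within each variable.
TABLE1_COMPLETE_COUNTS: dict[str, tuple[int, ...]] = {
    "sex": (5706, 1239),
    "age": (892, 1191, 860, 754, 1199, 899, 1150),
    "cause": (4780, 920, 1245),
    "ec": (1638, 5307),
    "eye": (2680, 1261, 1764, 1240),
    "motor": (601, 407, 515, 933, 2723, 1766),
    "verbal": (2640, 1124, 821, 2006, 354),
    "pupils": (5791, 496, 658),
    "phm": (1974, 4971),
    "sah": (2206, 4739),
    "oblt": (1663, 5282),
    "mdls": (1021, 5924),
    "hmt": (2718, 4227),
    OUTCOME: (2763, 4182),
}


@dataclass(frozen=True)
class CalibrationTargets:
    """Target marginal distribution per variable plus the poor-outcome rate."""

    marginals: dict[str, np.ndarray]
    poor_outcome_rate: float

    def __post_init__(self) -> None:
        for v, m in self.marginals.items():
            if abs(float(np.sum(m)) - 1.0) > 1e-6:
                raise ValueError(f"target marginal for {v!r} does not sum to 1")
        if not 0.0 < self.poor_outcome_rate < 1.0:
            raise ValueError("poor_outcome_rate must be in (0, 1)")


def default_targets() -> CalibrationTargets:
    marginals = {v: np.asarray(c, dtype=float) / sum(c)
                 for v, c in TABLE1_COMPLETE_COUNTS.items() if v != OUTCOME}
    out = TABLE1_COMPLETE_COUNTS[OUTCOME]
    return CalibrationTargets(marginals, poor_outcome_rate=out[0] / sum(out))


# graded-response construction for the latent severity driver ----------------

_SEVERITY_P = np.array([0.32, 0.30, 0.23, 0.15])  # mild -> critical

# ordinal variables: response positions run best -> worst within each tuple
_ORDINAL_CHILDREN = {
    # variable: (positions are schema category indices, best category index)
    "eye": 3,      # spontaneous is best (last category)
    "verbal": 4,   # orientated is best
    "pupils": 0,   # both reactive is best (first category)
}

_BINARY_CT_P_YES = {  # P(finding | severity level), increasing with severity
    "phm": (0.10, 0.22, 0.40, 0.55),
    "sah": (0.12, 0.26, 0.45, 0.62),
    "oblt": (0.05, 0.14, 0.38, 0.68),
    "mdls": (0.03, 0.08, 0.26, 0.55),
    "hmt": (0.15, 0.32, 0.55, 0.72),
}

DEFAULT_OUTCOME_COEFFICIENTS: dict[str, tuple[float, ...]] = {
    "sex": (0.0, 0.05),
    "age": (0.0, 0.15, 0.30, 0.50, 0.80, 1.15, 1.60),
    "cause": (0.0, 0.10, 0.05),
    "ec": (0.55, 0.0),
    "eye": (0.70, 0.50, 0.25, 0.0),
    "motor": (2.10, 1.80, 1.40, 0.90, 0.45, 0.0),
    "verbal": (0.90, 0.65, 0.45, 0.20, 0.0),
    "pupils": (0.0, 0.90, 1.40),
    "phm": (0.20, 0.0),
    "sah": (0.25, 0.0),
    "oblt": (0.65, 0.0),
    "mdls": (0.55, 0.0),
    "hmt": (0.45, 0.0),
}


def _graded_cpt(n_cat: int, best_index: int, sharp: float = 1.2) -> np.ndarray:
    """P(category | severity level): rows = 4 severity levels.

    Category positions run 0 (worst) .. n_cat-1 (best); ``best_index``
    says which schema category index is the best response.
    """
    positions = np.arange(n_cat, dtype=float)
    if best_index == 0:
        positions = positions[::-1]  # first category is best
    out = np.zeros((len(_SEVERITY_P), n_cat))
    centers = np.linspace(n_cat - 1, 0, len(_SEVERITY_P))  # mild -> best response
    for s, mu in enumerate(centers):
        w = np.exp(-sharp * np.abs(positions - mu))
        out[s] = w / w.sum()
    return out


def default_truth(seed: int = 0) -> GenerativeModel:
    """The documented default generative model.

    Roots: sex, age, motor (motor carries the collapsed latent
    severity); edges age -> cause -> ec and motor -> each remaining
    assessment/imaging variable.  ``seed`` applies a small reproducible
    jitter to the CPTs so distinct seeds give distinct (but structurally
    identical) truths.
    """
    schema = crash_schema()
    rng = np.random.default_rng(seed)

    def jitter(cpt: np.ndarray) -> np.ndarray:
        noisy = cpt * np.exp(0.03 * rng.standard_normal(cpt.shape))
        return noisy / noisy.sum(axis=-1, keepdims=True)

    states = {v: schema[v].categories for v in PREDICTORS}
    cards = {v: len(states[v]) for v in PREDICTORS}

    cpts: dict[str, np.ndarray] = {}
    cpts["sex"] = jitter(np.array([0.80, 0.20]))
    cpts["age"] = jitter(np.full(cards["age"], 1.0 / cards["age"]))

    # age -> cause: RTA declines and falls rise with age
    base = np.array([0.72, 0.08, 0.20])
    cause = np.zeros((cards["age"], 3))
    for i in range(cards["age"]):
        shift = i / (cards["age"] - 1)
        cause[i] = base + np.array([-0.18, 0.16, 0.02]) * shift
    cpts["cause"] = jitter(cause / cause.sum(axis=1, keepdims=True))

    # cause -> ec: extracranial injury most likely after RTA, then falls
    cpts["ec"] = jitter(np.array([[0.27, 0.73], [0.22, 0.78], [0.10, 0.90]]))

    # latent severity collapsed onto motor -----------------------------------
    p_sev = _SEVERITY_P / _SEVERITY_P.sum()
    p_motor_given_s = _graded_cpt(cards["motor"], best_index=cards["motor"] - 1)
    p_motor = p_sev @ p_motor_given_s
    # posterior of the latent given the observed anchor
    p_s_given_motor = (p_motor_given_s * p_sev[:, None]).T / p_motor[:, None]

    cpts["motor"] = jitter(p_motor)
    for v, best in _ORDINAL_CHILDREN.items():
        child = _graded_cpt(cards[v], best_index=best)
        cpts[v] = jitter(p_s_given_motor @ child)
    for v, p_yes in _BINARY_CT_P_YES.items():
        child = np.column_stack([np.asarray(p_yes), 1.0 - np.asarray(p_yes)])
        cpts[v] = jitter(p_s_given_motor @ child)

    edges = {("age", "cause"), ("cause", "ec")}
    edges |= {("motor", v) for v in (*_ORDINAL_CHILDREN, *_BINARY_CT_P_YES)}
    dag = DAG(tuple(PREDICTORS), frozenset(edges))
    pbn = ParameterizedBN(dag, states, cpts)

    coeffs = {v: np.asarray(c, dtype=float)
              for v, c in DEFAULT_OUTCOME_COEFFICIENTS.items()}
    return GenerativeModel(pbn, coeffs, outcome_intercept=-3.0, schema=schema)


# ---------------------------------------------------------------------------
# exact quantities and calibration


def _component_eta_distribution(model: GenerativeModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the outcome linear predictor (minus intercept).

    Enumerates the joint within each weakly connected DAG component and
    combines components by independence.  Returns (probabilities, eta).
    """
    import networkx as nx

    g = model.bn.dag.to_networkx()
    probs = np.array([1.0])
    eta = np.array([0.0])
    for comp in nx.weakly_connected_components(g):
        order = [v for v in model.bn.dag.topological_order() if v in comp]
        cprob = np.array([1.0])
        ceta = np.array([0.0])
        codes: dict[str, np.ndarray] = {}
        for v in order:
            card = model.bn.card(v)
            parents = model.bn.dag.parents(v)
            cfg = np.zeros(len(cprob), dtype=np.int64)
            for p in parents:
                cfg = cfg * model.bn.card(p) + codes[p]
            rows = model.bn.cpts[v].reshape(-1, card)[cfg]  # (K, card)
            cprob = (cprob[:, None] * rows).ravel()
            ceta = (ceta[:, None] + model.outcome_coefficients[v][None, :]).ravel()
            for u in codes:
                codes[u] = np.repeat(codes[u], card)
            codes[v] = np.tile(np.arange(card), cfg.shape[0])
        probs = (probs[:, None] * cprob[None, :]).ravel()
        eta = (eta[:, None] + ceta[None, :]).ravel()
        # prune negligible mass to keep the outer products bounded
        keep = probs > 1e-15
        probs, eta = probs[keep], eta[keep]
    return probs, eta


def exact_poor_outcome_rate(model: GenerativeModel,
                            intercept: float | None = None) -> float:
    """Exact P(poor outcome) under the model's logistic mechanism."""
    probs, eta = _component_eta_distribution(model)
    b0 = model.outcome_intercept if intercept is None else intercept
    return float(probs @ expit(eta + b0))


def calibrate(model: GenerativeModel, targets: CalibrationTargets | None = None,
              tol: float = 1e-6, max_iter: int = 500) -> GenerativeModel:
    """Match exact marginals to the targets by per-category log-odds shifts.

    Variables are processed in topological order; each sweep multiplies
    the CPT column of every category by exp(delta_c) (a log-odds shift)
    chosen as the fixed-point update target/current, then renormalizes
    rows, until the exactly marginalized distribution is within ``tol``
    of the target per category.  The outcome intercept is then solved by
    1-D root finding against the exact poor-outcome rate.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    targets = targets or default_targets()
    cpts = {v: model.bn.cpts[v].copy() for v in model.bn.dag.nodes}
    pbn = ParameterizedBN(model.bn.dag, dict(model.bn.states), cpts)
    worst_var, worst_err = None, 0.0
    for v in pbn.dag.topological_order():
        if v not in targets.marginals:
            continue
        t = np.asarray(targets.marginals[v], dtype=float)
        converged = False
        for _ in range(max_iter):
            m = bnmod.exact_marginal(pbn, v)
            err = float(np.max(np.abs(m - t)))
            if err < tol:
                converged = True
                break
            factor = np.where(m > 0, t / np.maximum(m, 1e-300), 1.0)
            cpt = cpts[v] * factor
            cpts[v] = cpt / cpt.sum(axis=-1, keepdims=True)
            pbn = ParameterizedBN(pbn.dag, pbn.states, cpts)
        if not converged and err > worst_err:
            worst_var, worst_err = v, err
    if worst_var is not None:
        raise RuntimeError(
            f"marginal calibration failed to converge; worst variable "
            f"{worst_var!r} (residual {worst_err:.3g})")

    out = GenerativeModel(pbn, {k: v.copy() for k, v in model.outcome_coefficients.items()},
                          model.outcome_intercept, model.schema)
    probs, eta = _component_eta_distribution(out)

    def f(b0: float) -> float:
        return float(probs @ expit(eta + b0)) - targets.poor_outcome_rate

    out.outcome_intercept = float(brentq(f, -30.0, 30.0, xtol=1e-12))
    return out


# ---------------------------------------------------------------------------
# sampling and missingness


def sample_cohort(model: GenerativeModel, n: int, seed: int) -> Cohort:
    """Ancestral sampling of predictors plus logistic outcome draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pred_df = bnmod.sample_bn(model.bn, n, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    eta = np.full(n, model.outcome_intercept)
    for v in model.predictors:
        codes = pd.Categorical(pred_df[v], categories=list(model.bn.states[v])).codes
        eta += model.outcome_coefficients[v][codes]
    poor = rng.random(n) < expit(eta)
    out_var = model.schema.outcome
    cats = model.schema[out_var].categories
    pred_df[out_var] = np.where(poor, cats[0], cats[1])
    return Cohort(pred_df[list(model.schema.names)], model.schema)


def apply_missingness(cohort: Cohort, cfg: MissingnessConfig | None = None,
                      seed: int = 0) -> RawCohort:
    """Overwrite values with the trial's missing codes, MCAR.

    "scan not done" (and, among scanned records, joint "no data") hits
    all five imaging variables of a record together; the other codes are
    applied independently per record.
    """
    cfg = cfg or MissingnessConfig()
    rng = np.random.default_rng(seed)
    df = cohort.records.copy()
    n = len(df)

    no_ct = rng.random(n) < cfg.p_no_ct
    img_nodata = (~no_ct) & (rng.random(n) < cfg.p_imaging_no_data)
    for v in IMAGING_VARS:
        if v in df.columns:
            df.loc[no_ct, v] = SCAN_NOT_DONE
            df.loc[img_nodata, v] = NO_DATA

    for v, p in cfg.mcar_no_data:
        if v in df.columns:
            df.loc[rng.random(n) < p, v] = NO_DATA

    if "pupils" in df.columns:
        df.loc[rng.random(n) < cfg.p_pupils_unassessable, "pupils"] = UNABLE_TO_ASSESS

    out_var = cohort.schema.outcome
    if out_var is not None:
        u = rng.random(n)
        df.loc[u < cfg.p_outcome_unknown, out_var] = ALIVE_UNKNOWN
        df.loc[(u >= cfg.p_outcome_unknown)
               & (u < cfg.p_outcome_unknown + cfg.p_outcome_no_data), out_var] = NO_DATA

    return RawCohort(df, cohort.schema)


# ---------------------------------------------------------------------------
# small planted models for method validation


def planted_model(n_predictors: int = 10,
                  informative: dict[str, float] | None = None,
                  n_categories: int = 3,
                  intercept: float = -0.5,
                  seed: int = 0) -> GenerativeModel:
    """Independent categorical predictors with a chosen few driving outcome.

    Predictors are named ``v01`` .. ``vNN`` with mildly non-uniform
    marginals; ``informative`` maps predictor name to a coefficient
    scale: category c of an informative predictor contributes
    ``scale * c / (n_categories - 1)`` to the outcome log-odds, all
    other predictors contribute nothing.
    """
    if informative is None:
        informative = {"v01": 2.0, "v02": 1.5}
    names = tuple(f"v{i + 1:02d}" for i in range(n_predictors))
    unknown = set(informative) - set(names)
    if unknown:
        raise ValueError(f"informative predictors not in model: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cats = tuple(f"c{j}" for j in range(n_categories))
    variables = [VariableSchema(v, "synthetic", cats) for v in names]
    variables.append(VariableSchema(OUTCOME, "outcome", ("poor", "good")))
    schema = Schema(variables)

    states = {v: cats for v in names}
    cpts = {}
    for v in names:
        w = 1.0 + 0.3 * rng.random(n_categories)
        cpts[v] = w / w.sum()
    dag = DAG(names, frozenset())
    pbn = ParameterizedBN(dag, states, cpts)
    coeffs = {}
    grad = np.arange(n_categories, dtype=float) / max(n_categories - 1, 1)
    for v in names:
        coeffs[v] = informative.get(v, 0.0) * grad
    return GenerativeModel(pbn, coeffs, outcome_intercept=intercept, schema=schema)
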