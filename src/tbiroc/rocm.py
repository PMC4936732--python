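"""ROC curves, full and partial AUC, DeLong and bootstrap comparisons.

The partial area (pAUC) restricts the curve to a high-specificity or
high-sensitivity band (90-100% by default, the clinically relevant
region) and is standardized after McClish so that chance performance in
the band maps to 0.5 and perfect performance to 1, making partial areas
over different bands comparable.

Full-AUC comparisons of paired models use DeLong's nonparametric test
(placement-value covariance); partial-area comparisons, for which the
classical DeLong covariance is not defined, use a stratified paired
bootstrap and are labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "ROCCurve",
    "PAUCResult",
    "PairedTestResult",
    "roc_curve",
    "auc",
    "pauc",
    "chance_area",
    "standardize_pauc",
    "delong_variance",
    "delong_test",
    "bootstrap_pauc_test",
    "pauc_ci",
    "standardized_pauc",
]


@dataclass(frozen=True)
class ROCCurve:
    """Operating points sorted with specificity non-decreasing.

    Includes the corner points (sp=0, se=1) and (sp=1, se=0); one point
    per distinct score threshold, ties grouped (trapezoidal convention).
    """

    specificity: np.ndarray
    sensitivity: np.ndarray
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        sp, se = self.specificity, self.sensitivity
        if np.any(np.diff(sp) < -1e-12) or np.any(np.diff(se) > 1e-12):
            raise ValueError("operating points are not monotone")


@dataclass(frozen=True)
class PAUCResult:
    axis: str
    range: tuple[float, float]
    raw_area: float
    standardized: float
    ci_low: float | None = None
    ci_high: float | None = None
    method: str = ""

    @property
    def below_chance(self) -> bool:
        return self.standardized < 0.5


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    method: str
    estimate: float
    replicates: int | None = None


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical ROC from scores (higher = more likely positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    # last index of each tie group of descending scores
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    se = np.r_[0.0, tps / n_pos][::-1]
    sp = np.r_[0.0, fps / n_neg][::-1]
    sp = 1.0 - sp
    # ensure both corners explicitly present
    if sp[0] != 0.0 or se[0] != 1.0:
        sp = np.r_[0.0, sp]
        se = np.r_[1.0, se]
    return ROCCurve(sp, se, n_pos, n_neg)


def _interval_area(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Area under the piecewise-linear curve (x, y) over x in [lo, hi].

    x must be non-decreasing; vertical segments (repeated x) have zero
    width and contribute nothing; interval boundaries are linearly
    interpolated within their segment.
    """
    x0, x1 = x[:-1], x[1:]
    y0, y1 = y[:-1], y[1:]
    a = np.clip(x0, lo, hi)
    b = np.clip(x1, lo, hi)
    width = b - a
    dx = x1 - x0
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(dx > 0, (y1 - y0) / np.where(dx > 0, dx, 1.0), 0.0)
    ya = y0 + slope * (a - x0)
    yb = y0 + slope * (b - x0)
    return float(np.sum(np.where(width > 0, 0.5 * (ya + yb) * width, 0.0)))


def auc(curve: ROCCurve) -> float:
    """Trapezoidal area; equals the Mann-Whitney statistic with ties at half credit."""
    return _interval_area(curve.specificity, curve.sensitivity, 0.0, 1.0)


def pauc(curve: ROCCurve, axis: str = "specificity",
         range: tuple[float, float] = (0.9, 1.0)) -> float:
    """Raw partial area over a specificity or sensitivity band.

    The sensitivity-axis partial area integrates specificity with
    respect to sensitivity — the curve-transposition identity — so a
    single interval integrator serves both axes.
    """
    lo, hi = range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("range must be a non-empty sub-interval of [0, 1]")
    if axis == "specificity":
        return _interval_area(curve.specificity, curve.sensitivity, lo, hi)
    if axis == "sensitivity":
        # along the curve, sensitivity decreases as specificity increases;
        # reverse so the integration variable is non-decreasing
        return _interval_area(curve.sensitivity[::-1], curve.specificity[::-1], lo, hi)
    raise ValueError(f"unknown axis {axis!r}")


def chance_area(range: tuple[float, float]) -> float:
    """Area under the chance diagonal within the band (either axis)."""
    lo, hi = range
    return (hi - lo) - 0.5 * (hi**2 - lo**2)


def standardize_pauc(raw: float, range: tuple[float, float] = (0.9, 1.0)) -> float:
    """McClish standardization: 0.5 at chance, 1 at the maximum.

    Returns 0.5 * (1 + (raw - min) / (max - min)); values below 0.5
    indicate below-chance performance in the band.
    """
    lo, hi = range
    a_min = chance_area(range)
    a_max = hi - lo
    if raw > a_max + 1e-9 or raw < -1e-9:
        raise ValueError("raw partial area outside feasible bounds")
    return 0.5 * (1.0 + (raw - a_min) / (a_max - a_min))


def standardized_pauc(scores, labels, axis: str = "specificity",
                      range: tuple[float, float] = (0.9, 1.0)) -> float:
    """Convenience: standardized partial area straight from scores."""
    return standardize_pauc(pauc(roc_curve(scores, labels), axis, range), range)


# ---------------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    ranks = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def _delong_components(score_matrix: np.ndarray, labels: np.ndarray):
    """AUCs and the placement-value covariance matrices (Sun & Xu form).

    ``score_matrix`` is (k models, n records); returns (aucs, S) where S
    is the k x k covariance matrix of the AUC estimates.
    """
    pos = score_matrix[:, labels == 1]
    neg = score_matrix[:, labels == 0]
    m, n = pos.shape[1], neg.shape[1]
    k = score_matrix.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.r_[pos[r], neg[r]])
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if k > 1 else np.atleast_2d(np.var(v01[0], ddof=1))
    s10 = np.cov(v10) if k > 1 else np.atleast_2d(np.var(v10[0], ddof=1))
    S = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, S


def delong_variance(scores, labels) -> float:
    """DeLong variance of a single empirical AUC."""
    labels = _check_labels(labels)
    _, S = _delong_components(np.asarray(scores, dtype=float)[None, :], labels)
    return float(S[0, 0])


def delong_test(scores_a, scores_b, labels) -> PairedTestResult:
    """Two-sided DeLong test for two correlated (paired) AUCs."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired inputs must share records and labels")
    aucs, S = _delong_components(np.vstack([scores_a, scores_b]), labels)
    delta = float(aucs[0] - aucs[1])
    var = float(S[0, 0] + S[1, 1] - 2.0 * S[0, 1])
    if var <= 0:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
        z = 0.0 if abs(delta) < 1e-12 else np.inf * np.sign(delta)
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return PairedTestResult(statistic=float(z), p_value=p, method="delong", estimate=delta)


# ---------------------------------------------------------------------------
# stratified bootstrap for partial areas


def _sorted_class_setup(scores: np.ndarray, labels: np.ndarray):
    """Pre-sorted structures for weighted ROC evaluation."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), len(s) - 1]
    return order, y, distinct


def _weighted_std_pauc(order, y_sorted, distinct, w, axis, rng_range) -> float:
    """Standardized pAUC of one weighted resample (w = per-record counts)."""
    ws = w[order]
    wpos = ws * y_sorted
    wneg = ws * (1 - y_sorted)
    tp = np.cumsum(wpos)[distinct]
    fp = np.cumsum(wneg)[distinct]
    se = np.r_[0.0, tp / tp[-1]][::-1]
    sp = 1.0 - np.r_[0.0, fp / fp[-1]][::-1]
    if sp[0] != 0.0 or se[0] != 1.0:
        sp = np.r_[0.0, sp]
        se = np.r_[1.0, se]
    lo, hi = rng_range
    if axis == "specificity":
        raw = _interval_area(sp, se, lo, hi)
    else:
        raw = _interval_area(se[::-1], sp[::-1], lo, hi)
    return standardize_pauc(raw, rng_range)


def _bootstrap_weights(labels: np.ndarray, reps: int, seed: int) -> np.ndarray:
    """Per-class multinomial record weights == stratified resampling.

    Resampling positives and negatives separately preserves class
    balance and makes a single-class resample impossible.
    """
    rng = np.random.default_rng(seed)
    n = len(labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    w = np.zeros((reps, n))
    w[:, pos_idx] = rng.multinomial(len(pos_idx), np.full(len(pos_idx), 1.0 / len(pos_idx)),
                                    size=reps)
    w[:, neg_idx] = rng.multinomial(len(neg_idx), np.full(len(neg_idx), 1.0 / len(neg_idx)),
                                    size=reps)
    return w


def bootstrap_pauc_test(scores_a, scores_b, labels, axis: str = "specificity",
                        range: tuple[float, float] = (0.9, 1.0),
                        reps: int = 2000, seed: int = 0) -> PairedTestResult:
    """Stratified paired bootstrap z-test for a standardized-pAUC difference.

    The same per-class resample weights apply to both models (pairing);
    z = observed difference / bootstrap SD of the difference, two-sided
    normal p.  With ``range=(0, 1)`` this is a bootstrap AUC test, since
    the standardized partial area over the full band equals the AUC.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired inputs must share records and labels")
    full = np.ones(len(labels))
    setup_a = _sorted_class_setup(scores_a, labels)
    setup_b = _sorted_class_setup(scores_b, labels)
    d_obs = (_weighted_std_pauc(*setup_a, full, axis, range)
             - _weighted_std_pauc(*setup_b, full, axis, range))
    weights = _bootstrap_weights(labels, reps, seed)
    diffs = np.empty(reps)
    for r in np.arange(reps):
        diffs[r] = (_weighted_std_pauc(*setup_a, weights[r], axis, range)
                    - _weighted_std_pauc(*setup_b, weights[r], axis, range))
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        p = 1.0 if abs(d_obs) < 1e-12 else 0.0
        z = 0.0
    else:
        z = d_obs / sd
        p = float(2.0 * norm.sf(abs(z)))
    return PairedTestResult(statistic=float(z), p_value=p, method="bootstrap",
                            estimate=float(d_obs), replicates=reps)


def pauc_ci(scores, labels, axis: str = "specificity",
            range: tuple[float, float] = (0.9, 1.0),
            reps: int = 2000, seed: int = 0,
            level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the standardized partial area."""
    if reps < 100:
        raise ValueError("reps must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    setup = _sorted_class_setup(scores, labels)
    weights = _bootstrap_weights(labels, reps, seed)
    vals = np.empty(reps)
    for r in np.arange(reps):
        vals[r] = _weighted_std_pauc(*setup, weights[r], axis, range)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def pauc_result(scores, labels, axis: str = "specificity",
                range: tuple[float, float] = (0.9, 1.0),
                reps: int = 2000, seed: int = 0) -> PAUCResult:
    """Point estimate plus percentile-bootstrap CI in one object."""
    curve = roc_curve(scores, labels)
    raw = pauc(curve, axis, range)
    std = standardize_pauc(raw, range)
    lo, hi = pauc_ci(scores, labels, axis, range, reps=reps, seed=seed)
    return PAUCResult(axis=axis, range=range, raw_area=raw, standardized=std,
                      ci_low=lo, ci_high=hi, method="stratified percentile bootstrap")
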