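"""Screening-validation statistics.

Everything the validation of a threshold-based screening test needs:
confusion matrices and the five screening metrics, the random-classifier
chance baseline, ROC curves with trapezoidal AUC and Youden's index,
percentile-bootstrap confidence intervals and bootstrap p-values against
chance, per-threshold metric sweeps, and the Hanley-McNeil AUC sample-size
formula.

The chance baseline is the random classifier that predicts class i with a
fixed selection probability q_i regardless of the input, against true-class
priors p_j; its confusion matrix has cells q_i * p_j.  Two consequences used
as checks throughout: with uniform q the chance accuracy is 1/K for any
priors, and the chance NPV equals the negative-class prior exactly.

Zero-denominator metrics are returned as NaN (flagged, never raised) so
sweeps over extreme thresholds always complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

LABELS = ("positive", "negative")


@dataclass(frozen=True)
class BinaryConfusion:
    """TP/FP/FN/TN; counts, or cell probabilities for chance models."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ScreeningMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def undefined(self) -> tuple[str, ...]:
        """Names of metrics whose denominator was zero (returned as NaN)."""
        return tuple(name for name in ("accuracy", "sensitivity", "specificity",
                                       "ppv", "npv")
                     if math.isnan(getattr(self, name)))

    def as_dict(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv}


def confusion_from_predictions(predicted: Sequence[str],
                               true: Sequence[str]) -> BinaryConfusion:
    """Exact counts from parallel positive/negative label sequences."""
    if len(predicted) != len(true):
        raise ValueError(f"length mismatch: {len(predicted)} predictions "
                         f"vs {len(true)} truths")
    bad = {v for v in (*predicted, *true)} - set(LABELS)
    if bad:
        raise ValueError(f"labels must be in {LABELS}; got {sorted(bad)}")
    tp = sum(p == "positive" and t == "positive" for p, t in zip(predicted, true))
    fp = sum(p == "positive" and t == "negative" for p, t in zip(predicted, true))
    fn = sum(p == "negative" and t == "positive" for p, t in zip(predicted, true))
    tn = sum(p == "negative" and t == "negative" for p, t in zip(predicted, true))
    return BinaryConfusion(tp, fp, fn, tn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_confusion(cm: BinaryConfusion) -> ScreeningMetrics:
    """Accuracy, sensitivity, specificity, PPV, NPV; NaN where undefined."""
    return ScreeningMetrics(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


# ---------------------------------------------------------------------------
# chance-level random classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChanceModel:
    """Selection probabilities q (per predicted class) and class priors p."""

    q: Mapping[str, float]
    p: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.q) != set(self.p):
            raise ValueError("q and p must be over the same class set")
        for name, dist in (("q", self.q), ("p", self.p)):
            if any(v < 0 for v in dist.values()):
                raise ValueError(f"{name} has negative entries")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")

    @classmethod
    def uniform_binary(cls, prior_positive: float) -> "ChanceModel":
        return cls(q={"positive": 0.5, "negative": 0.5},
                   p={"positive": prior_positive, "negative": 1.0 - prior_positive})

    def cell(self, predicted: str, true: str) -> float:
        return self.q[predicted] * self.p[true]

    def accuracy(self) -> float:
        """Multiclass chance accuracy: sum_i q_i p_i (1/K for uniform q)."""
        return sum(self.q[c] * self.p[c] for c in self.q)


def chance_confusion(model: ChanceModel) -> tuple[BinaryConfusion, ScreeningMetrics]:
    """The probability-form confusion matrix of the random classifier.

    Only meaningful for the binary positive/negative class set; use
    :meth:`ChanceModel.accuracy` for multiclass baselines.
    """
    if set(model.q) != set(LABELS):
        raise ValueError("chance_confusion requires the binary positive/negative classes")
    cm = BinaryConfusion(tp=model.cell("positive", "positive"),
                         fp=model.cell("positive", "negative"),
                         fn=model.cell("negative", "positive"),
                         tn=model.cell("negative", "negative"))
    return cm, metrics_from_confusion(cm)


# ---------------------------------------------------------------------------
# ROC / AUC / Youden
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    fpr: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity - self.fpr


@dataclass(frozen=True)
class RocCurve:
    points: tuple[RocPoint, ...]
    auc: float
    positive_low: bool


def roc_curve(scores: Sequence[float], positive: Sequence[bool],
              positive_low: bool = True) -> RocCurve:
    """ROC over all achievable thresholds, AUC by trapezoidal integration.

    With ``positive_low`` (the screening convention: low score suggests
    impairment) a case is called positive when its score is <= the threshold.
    The sweep runs from the strictest cut (nobody positive; sentinel
    threshold) to the loosest, so sensitivity and FPR are non-decreasing
    along the curve.  The trapezoidal AUC over this step curve equals the
    Mann-Whitney concordance with ties counted 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(positive, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative case")

    oriented = s if positive_low else -s
    thresholds = np.unique(oriented)  # ascending = strict -> loose
    pts = [RocPoint(float("-inf") if positive_low else float("inf"), 0.0, 0.0)]
    for t in thresholds:
        call_pos = oriented <= t
        sens = float((call_pos & y).sum() / n_pos)
        fpr = float((call_pos & ~y).sum() / n_neg)
        pts.append(RocPoint(float(t if positive_low else -t), sens, fpr))
    fprs = np.array([p.fpr for p in pts])
    tprs = np.array([p.sensitivity for p in pts])
    auc = float(np.trapezoid(tprs, fprs))
    return RocCurve(tuple(pts), auc, positive_low)


def mann_whitney_auc(scores: Sequence[float], positive: Sequence[bool],
                     positive_low: bool = True) -> float:
    """Concordance probability P(oriented positive ranks above negative), ties 1/2.

    Independent of :func:`roc_curve`; used as its cross-check.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(positive, dtype=bool)
    oriented = -s if positive_low else s
    pos = oriented[y][:, None]
    neg = oriented[~y][None, :]
    n_pairs = pos.shape[0] * neg.shape[1]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / n_pairs)


def youden_threshold(roc: RocCurve) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the strictest achievable (finite) threshold.
    """
    finite = [p for p in roc.points if math.isfinite(p.threshold)]
    best = max(finite, key=lambda p: (p.youden_j, -p.threshold if roc.positive_low
                                      else p.threshold))
    return best.threshold, best.youden_j


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    seed: int
    boot_mean: float
    n_redrawn: int
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def bootstrap_statistic(records: Sequence, statistic: Callable[[Sequence], float],
                        n_boot: int = 1000, seed: int = 0,
                        level: float = 0.95) -> BootstrapResult:
    """Percentile bootstrap: resample records with replacement, same n.

    Resamples on which the statistic is undefined (NaN or a raised
    ValueError/ZeroDivisionError, e.g. a single-class resample) are redrawn;
    the count of redraws is reported.  Deterministic per seed.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two records to bootstrap")
    rng = np.random.default_rng(seed)
    n = len(records)
    samples = np.empty(n_boot)
    redrawn = 0
    filled = 0
    attempts_cap = 50 * n_boot
    attempts = 0
    while filled < n_boot:
        attempts += 1
        if attempts > attempts_cap:
            raise RuntimeError("statistic undefined on almost every resample")
        idx = rng.integers(0, n, size=n)
        try:
            value = float(statistic([records[i] for i in idx]))
        except (ValueError, ZeroDivisionError):
            value = float("nan")
        if math.isnan(value):
            redrawn += 1
            continue
        samples[filled] = value
        filled += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    return BootstrapResult(point_estimate=float(statistic(records)),
                           ci_low=float(lo), ci_high=float(hi), level=level,
                           n_boot=n_boot, seed=seed,
                           boot_mean=float(samples.mean()),
                           n_redrawn=redrawn, samples=samples)


@dataclass(frozen=True)
class ChanceComparison:
    """Bootstrap p-value: fraction of resampled statistics at or below chance."""

    count_at_or_below: int
    n_boot: int

    @property
    def p(self) -> float:
        return self.count_at_or_below / self.n_boot

    @property
    def at_floor(self) -> bool:
        """True when no resample fell to chance; report as p < 1/n_boot."""
        return self.count_at_or_below == 0

    @property
    def floor(self) -> float:
        return 1.0 / self.n_boot

    def display(self) -> str:
        return f"<{self.floor:g}" if self.at_floor else f"{self.p:g}"


def p_vs_chance(records: Sequence, statistic: Callable[[Sequence], float],
                chance_value: float, n_boot: int = 1000, seed: int = 0
                ) -> tuple[ChanceComparison, BootstrapResult]:
    """Count how often the bootstrapped statistic falls to or below chance.

    The comparison uses <= (falling "below chance" includes hitting it),
    which is conservative.
    """
    boot = bootstrap_statistic(records, statistic, n_boot=n_boot, seed=seed)
    count = int((boot.samples <= chance_value).sum())
    return ChanceComparison(count, n_boot), boot


# ---------------------------------------------------------------------------
# threshold sweep
# ---------------------------------------------------------------------------

_METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "npv")


def _metrics_by_threshold(scores: np.ndarray, positive: np.ndarray,
                          max_score: int) -> np.ndarray:
    """(n_thresholds, 5) metric array for cuts t=0..max_score, rule score<=t."""
    bins = np.arange(max_score + 2)
    pos_hist = np.histogram(scores[positive], bins=bins)[0]
    neg_hist = np.histogram(scores[~positive], bins=bins)[0]
    tp = np.cumsum(pos_hist).astype(float)     # called positive among impaired
    fp = np.cumsum(neg_hist).astype(float)
    n_pos, n_neg = positive.sum(), (~positive).sum()
    fn, tn = n_pos - tp, n_neg - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.stack([
            (tp + tn) / (n_pos + n_neg),
            np.where(tp + fn > 0, tp / (tp + fn), np.nan),
            np.where(tn + fp > 0, tn / (tn + fp), np.nan),
            np.where(tp + fp > 0, tp / (tp + fp), np.nan),
            np.where(tn + fn > 0, tn / (tn + fn), np.nan),
        ], axis=1)
    return out


def threshold_sweep(scores: Sequence[int], positive: Sequence[bool],
                    max_score: int = 8, n_boot: int = 1000, seed: int = 0,
                    level: float = 0.95) -> dict:
    """Metrics with bootstrap CIs at every cut t in 0..max_score.

    Resampling unit is the patient.  Resamples where a metric is undefined
    (zero denominator) are excluded from that metric's percentile interval,
    with the exclusion count reported.  Also identifies the screening-optimal
    threshold: the t maximizing sensitivity + NPV where both are defined,
    ties broken toward the strictest (lowest) t.
    """
    s = np.asarray(scores, dtype=int)
    y = np.asarray(positive, dtype=bool)
    if not (y.any() and (~y).any()):
        raise ValueError("cohort must contain both statuses")
    rng = np.random.default_rng(seed)
    point = _metrics_by_threshold(s, y, max_score)
    boots = np.empty((n_boot, max_score + 1, 5))
    n = len(s)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _metrics_by_threshold(s[idx], y[idx], max_score)
    alpha = (1.0 - level) / 2.0
    sweep = {}
    for t in range(max_score + 1):
        entry: dict = {"threshold": t, "metrics": {}, "ci": {}, "n_undefined": {}}
        for m, name in enumerate(_METRIC_NAMES):
            col = boots[:, t, m]
            valid = col[~np.isnan(col)]
            entry["metrics"][name] = float(point[t, m])
            entry["n_undefined"][name] = int(np.isnan(col).sum())
            if len(valid):
                lo, hi = np.quantile(valid, [alpha, 1.0 - alpha])
                entry["ci"][name] = (float(lo), float(hi))
            else:
                entry["ci"][name] = (float("nan"), float("nan"))
        sweep[t] = entry

    best_t, best_val = None, -np.inf
    for t in range(max_score + 1):
        sens = sweep[t]["metrics"]["sensitivity"]
        npv = sweep[t]["metrics"]["npv"]
        if math.isnan(sens) or math.isnan(npv):
            continue
        if sens + npv > best_val + 1e-12:
            best_t, best_val = t, sens + npv
    return {"sweep": sweep, "best_screen_threshold": best_t,
            "n_boot": n_boot, "seed": seed, "level": level}


# ---------------------------------------------------------------------------
# Hanley-McNeil sample size
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleSizeSpec:
    auc: float
    alpha: float = 0.05
    power: float = 0.8
    two_sided: bool = False

    def __post_init__(self) -> None:
        if not (0.5 < self.auc < 1.0):
            raise ValueError("target AUC must lie strictly between 0.5 and 1")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must lie strictly between 0 and 1")


def hanley_mcneil_variance(auc: float, n1: int, n2: int) -> float:
    """V = [A(1-A) + (n1-1)(Q1-A^2) + (n2-1)(Q2-A^2)] / (n1 n2)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    return (auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
            + (n2 - 1) * (q2 - auc ** 2)) / (n1 * n2)


def hanley_mcneil_n(spec: SampleSizeSpec, max_n: int = 100_000) -> dict:
    """Smallest equal group size detecting AUC = A against the 0.5 null.

    Uses the variance formula under the alternative (at A) and under the null
    (at 0.5); n per group is the smallest n with
    ``A - 0.5 >= z_alpha * sqrt(V0(n)) + z_power * sqrt(VA(n))``.
    All intermediate quantities are returned.
    """
    a = spec.auc
    z_alpha = stats.norm.ppf(1.0 - (spec.alpha / 2 if spec.two_sided else spec.alpha))
    z_power = stats.norm.ppf(spec.power)
    for n in range(2, max_n + 1):
        v_null = hanley_mcneil_variance(0.5, n, n)
        v_alt = hanley_mcneil_variance(a, n, n)
        if a - 0.5 >= z_alpha * math.sqrt(v_null) + z_power * math.sqrt(v_alt):
            return {"n_per_group": n,
                    "q1": a / (2.0 - a), "q2": 2.0 * a ** 2 / (1.0 + a),
                    "v_null": v_null, "v_alt": v_alt,
                    "z_alpha": float(z_alpha), "z_power": float(z_power),
                    "alpha": spec.alpha, "power": spec.power,
                    "two_sided": spec.two_sided, "auc": a}
    raise RuntimeError(f"no n <= {max_n} attains the requested power")
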