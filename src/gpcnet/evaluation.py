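"""Metrics, AUC comparison statistics, FDR correction and classical baselines.

The DeLong test for correlated AUCs is implemented from its structural
components (one per positive and per negative sample, computed with
midranks); everything routine — threshold metrics, AUC/AUPRC, the classical
baseline models, the BH step-up adjustment, the fold-level t-test — delegates
to scikit-learn, statsmodels and scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("gpcnet.evaluation")

__all__ = [
    "MetricSet",
    "ComparisonResult",
    "compute_metrics",
    "delong_test",
    "bootstrap_compare",
    "bh_fdr",
    "cv_mean_ttest",
    "run_baselines",
    "tyrosine_creatinine_correct",
]


@dataclass
class MetricSet:
    auc: float
    auprc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in ("auc", "auprc", "accuracy",
                                           "precision", "recall", "f1")}
        d.update({f"confusion_{k}": v for k, v in self.confusion.items()})
        return d


@dataclass
class ComparisonResult:
    statistic: float
    raw_p: float
    method: str
    adjusted_p: float | None = None
    n_resamples: int | None = None
    degenerate: bool = False


def compute_metrics(y: Sequence[float], scores: Sequence[float],
                    threshold: float = 0.5) -> MetricSet:
    """Curve metrics (rank AUC with midranks, step-integrated AUPRC) plus
    threshold metrics and confusion rates at the given cutoff."""
    y = np.asarray(y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("labels and scores must have the same length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC/AUPRC undefined: only one class present")
    pred = (scores >= threshold).astype(float)
    tp = float(np.sum((pred == 1) & (y == 1)))
    fp = float(np.sum((pred == 1) & (y == 0)))
    tn = float(np.sum((pred == 0) & (y == 0)))
    fn = float(np.sum((pred == 0) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / n_pos
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricSet(
        auc=float(roc_auc_score(y, scores)),
        auprc=float(average_precision_score(y, scores)),
        accuracy=(tp + tn) / len(y),
        precision=precision,
        recall=recall,
        f1=f1,
        confusion={"tpr": tp / n_pos, "fnr": fn / n_pos,
                   "tnr": tn / n_neg, "fpr": fp / n_neg,
                   "tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


# ---------------------------------------------------------------------------
# DeLong test
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its structural components V10 (per positive), V01 (per negative).

    V10[i] = (1/n_neg) sum_j psi(pos_i, neg_j), psi = 1/0.5/0 for >/=/<, and
    symmetrically for V01; both computed in O(n log n) via midranks.
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def delong_test(scores_a: Sequence[float], scores_b: Sequence[float],
                y: Sequence[float]) -> ComparisonResult:
    """Paired DeLong test of the AUC difference between two score vectors.

    The variance of AUC_a - AUC_b comes from the empirical covariance of the
    paired structural components; p is two-sided normal. Zero variance (e.g.
    identical scores) yields a degenerate result with p = 1.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and y must have the same length")
    auc_a, v10_a, v01_a = delong_components(a, y)
    auc_b, v10_b, v01_b = delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    delta = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        return ComparisonResult(statistic=0.0, raw_p=1.0, method="delong",
                                degenerate=True)
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return ComparisonResult(statistic=float(z), raw_p=float(min(p, 1.0)),
                            method="delong")


# ---------------------------------------------------------------------------
# bootstrap and fold-level comparisons
# ---------------------------------------------------------------------------

_METRIC_FNS: dict[str, Callable] = {
    "auc": lambda y, s: roc_auc_score(y, s),
    "auprc": lambda y, s: average_precision_score(y, s),
    "accuracy": lambda y, s: np.mean((np.asarray(s) >= 0.5) == np.asarray(y)),
    "f1": lambda y, s: compute_metrics(y, s).f1,
    "precision": lambda y, s: compute_metrics(y, s).precision,
    "recall": lambda y, s: compute_metrics(y, s).recall,
}


def bootstrap_compare(
    y: Sequence[float],
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    metric: str = "auprc",
    B: int = 1000,
    seed: int = 0,
) -> ComparisonResult:
    """Paired bootstrap test of a metric difference between two models.

    Samples are resampled with replacement (the same indices for both
    models); a single-class resample is redrawn and counted. The statistic is
    the median of the per-resample differences; the two-sided p-value is
    2*min(Pr(diff <= 0), Pr(diff >= 0)) with +1 smoothing, capped at 1.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if metric not in _METRIC_FNS:
        raise ValueError(f"unknown metric '{metric}'; choose from {sorted(_METRIC_FNS)}")
    y = np.asarray(y, dtype=float)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    fn = _METRIC_FNS[metric]
    rng = np.random.default_rng(seed)
    diffs = np.empty(B)
    redraws = 0
    for i in range(B):
        while True:
            idx = rng.integers(0, len(y), size=len(y))
            if len(np.unique(y[idx])) == 2:
                break
            redraws += 1
            if redraws > 100 * B:
                raise RuntimeError("could not draw two-class bootstrap resamples")
        diffs[i] = fn(y[idx], a[idx]) - fn(y[idx], b[idx])
    if redraws:
        logger.info("bootstrap_compare: redrew %d single-class resample(s)", redraws)
    p_low = (1 + np.sum(diffs <= 0)) / (B + 1)
    p_high = (1 + np.sum(diffs >= 0)) / (B + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    degenerate = bool(np.all(diffs == 0))
    return ComparisonResult(statistic=float(np.median(diffs)),
                            raw_p=1.0 if degenerate else float(p),
                            method="bootstrap", n_resamples=B,
                            degenerate=degenerate)


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cv_mean_ttest(scores_model_a: Sequence[float],
                  scores_model_b: Sequence[float]) -> ComparisonResult:
    """Two-sample equal-variance t-test on fold-level metrics."""
    a = np.asarray(scores_model_a, dtype=float)
    b = np.asarray(scores_model_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fold metric lists must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("need at least two folds")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        return ComparisonResult(statistic=0.0, raw_p=1.0, method="ttest",
                                degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(statistic=float(t), raw_p=float(p), method="ttest")


# ---------------------------------------------------------------------------
# classical baselines
# ---------------------------------------------------------------------------

def _default_baselines(seed: int) -> dict[str, object]:
    return {
        "random_forest": RandomForestClassifier(random_state=seed),
        "svm": SVC(random_state=seed),
        "logistic_regression": LogisticRegression(max_iter=2000, random_state=seed),
        "decision_tree": DecisionTreeClassifier(random_state=seed),
    }


def _scores_of(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    raw = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-raw))   # squash to (0,1) so threshold 0.5 applies


def run_baselines(
    X_flat: np.ndarray,
    y: Sequence[float],
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    seed: int = 0,
    models: Mapping[str, object] | None = None,
) -> dict[str, tuple[MetricSet, np.ndarray]]:
    """Fit the classical comparators on flattened features; test-split metrics.

    Returns {model name: (MetricSet, test scores)}; a model whose fit fails is
    reported with a warning and omitted.
    """
    X_flat = np.asarray(X_flat, dtype=float)
    y = np.asarray(y, dtype=float)
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    out: dict[str, tuple[MetricSet, np.ndarray]] = {}
    for name, model in (models or _default_baselines(seed)).items():
        try:
            model.fit(X_flat[train_idx], y[train_idx])
            scores = _scores_of(model, X_flat[test_idx])
            out[name] = (compute_metrics(y[test_idx], scores), scores)
        except Exception as exc:   # report per-model, keep the harness alive
            logger.warning("baseline '%s' failed: %s", name, exc)
    return out


# ---------------------------------------------------------------------------
# urinary tyrosine correction
# ---------------------------------------------------------------------------

def tyrosine_creatinine_correct(tyr_umol_per_l: float, cr_mmol_per_l: float) -> float:
    """Creatinine-normalized urinary tyrosine.

    Tyr(umol/L) x 1000 x (10/9) / (Cr(mmol/L) x 113): the 10/9 factor undoes
    the 9:1 urine/stabilizer dilution and 113 is the molar mass of creatinine,
    giving umol tyrosine per mmol creatinine.
    """
    if cr_mmol_per_l <= 0:
        raise ValueError("creatinine concentration must be positive")
    return tyr_umol_per_l * 1000.0 * (10.0 / 9.0) / (cr_mmol_per_l * 113.0)
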