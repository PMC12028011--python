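"""Discrimination metrics, prevalence-adjusted predictive values,
bootstrap confidence intervals and the paired DeLong AUC comparison.

PPV/NPV follow the standard prevalence parameterization::

    PPV = Se*p / (Se*p + (1-Sp)*(1-p))
    NPV = Sp*(1-p) / ((1-Se)*p + Sp*(1-p))

so predictive values can be transported to any pre-test probability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "auc",
    "confusion_counts",
    "ppv_npv",
    "solve_prevalence",
    "bootstrap_ci",
    "delong_test",
    "evaluate_scores",
]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1D array")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary (0/1)")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic, ties as 1/2."""
    labels = _check_labels(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = stats.rankdata(scores)  # mid-ranks handle ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_counts(scores, labels, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) at ``score >= threshold`` -> predicted positive."""
    labels = np.asarray(labels).astype(int)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, tn, fn


def ppv_npv(sensitivity: float, specificity: float, prevalence: float) -> tuple[float, float]:
    """Prevalence-adjusted positive and negative predictive values."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    se, sp, p = sensitivity, specificity, prevalence
    ppv_den = se * p + (1 - sp) * (1 - p)
    npv_den = (1 - se) * p + sp * (1 - p)
    if ppv_den == 0 or npv_den == 0:
        raise ValueError("degenerate operating point: zero denominator in PPV or NPV")
    return se * p / ppv_den, sp * (1 - p) / npv_den


def solve_prevalence(sensitivity: float, specificity: float, ppv: float) -> float:
    """Closed-form inversion of the PPV equation for the prevalence.

    From ``PPV = Se*p / (Se*p + (1-Sp)(1-p))`` the unique solution is
    ``p = PPV*(1-Sp) / (PPV*(1-Sp) + Se*(1-PPV))``.
    """
    se, sp = sensitivity, specificity
    if not 0 < ppv < 1:
        raise ValueError(f"ppv={ppv} must be strictly inside (0, 1)")
    num = ppv * (1 - sp)
    den = num + se * (1 - ppv)
    if den == 0 or num == 0:
        raise ValueError("no prevalence in (0, 1) attains this PPV at this operating point")
    p = num / den
    if not 0 < p < 1:
        raise ValueError(f"solved prevalence {p} outside (0, 1)")
    check, _ = ppv_npv(se, sp, p)
    if abs(check - ppv) > 1e-9:
        raise AssertionError("prevalence inversion failed its self-check")
    return p


def bootstrap_ci(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the AUC over case-level resamples.

    Resamples containing a single class are redrawn (with a warning after
    many retries).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(np.asarray(labels))
    rng = np.random.default_rng(seed)
    n = scores.size
    values = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            if labels[idx].min() != labels[idx].max():
                break
            redraws += 1
        else:  # pragma: no cover - pathological class balance
            raise RuntimeError("could not draw a two-class bootstrap resample")
        values[b] = auc(scores[idx], labels[idx])
    if redraws:
        warnings.warn(f"redrew {redraws} single-class bootstrap resamples", stacklevel=2)
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# DeLong
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _delong_structural_components(scores: np.ndarray, labels: np.ndarray):
    """Per-case placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    a = (all_ranks[:m].sum() / m - (m + 1) / 2.0) / n
    return a, v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Two-sided DeLong comparison of two paired AUCs.

    Returns ``(auc_a, auc_b, p_value)``. Identical score vectors (zero
    variance of the difference) yield p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_labels(np.asarray(labels))
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be paired (equal length)")

    auc_a, v10_a, v01_a = _delong_structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _delong_structural_components(scores_b, labels)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]))
    s01 = np.cov(np.stack([v01_a, v01_b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0 or diff == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return float(auc_a), float(auc_b), p


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-cohort evaluation summary."""

    n: int
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    prevalence: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_json(self, path=None) -> str:
        payload = {
            k: (None if isinstance(v, float) and not np.isfinite(v) else v)
            for k, v in asdict(self).items()
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def evaluate_scores(
    scores,
    labels,
    threshold: float = 0.5,
    prevalence: Optional[float] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvalReport:
    """Full evaluation of one score vector at one operating threshold.

    ``prevalence`` defaults to the cohort's empirical positive fraction, in
    which case the prevalence-parameterized PPV/NPV agree exactly with the
    confusion-matrix ratios (checked internally).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(np.asarray(labels))
    tp, fp, tn, fn = confusion_counts(scores, labels, threshold)
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    empirical_prev = (tp + fn) / labels.size
    prev = empirical_prev if prevalence is None else float(prevalence)
    try:
        ppv, npv = ppv_npv(se, sp, prev)
    except ValueError:
        # degenerate operating point (e.g. no positive predictions at all)
        ppv = tp / (tp + fp) if tp + fp else float("nan")
        npv = tn / (tn + fn) if tn + fn else float("nan")
    if prevalence is None:
        # consistency of the analytic predictive values with raw counts
        if tp + fp > 0 and np.isfinite(ppv):
            assert abs(ppv - tp / (tp + fp)) < 1e-9
        if tn + fn > 0 and np.isfinite(npv):
            assert abs(npv - tn / (tn + fn)) < 1e-9
    ci = bootstrap_ci(scores, labels, n_boot=n_boot, seed=seed)
    return EvalReport(
        n=labels.size,
        auc=auc(scores, labels),
        auc_ci=ci,
        threshold=threshold,
        sensitivity=se,
        specificity=sp,
        ppv=ppv,
        npv=npv,
        prevalence=prev,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )
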