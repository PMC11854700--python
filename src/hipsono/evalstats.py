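"""Cohort-level evaluation statistics.

ROC/AUC of the alpha-based score, sensitivity/specificity at the 60-degree
cutoff, pooled-variance Student t comparisons, Benjamini-Hochberg FDR
adjustment, and the qualified-vs-disqualified rater-error comparison.

Score convention: ``score = 60 - alpha_deg`` so that larger scores mean
more DDH-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CohortRecord",
    "TTestResult",
    "RaterComparisonReport",
    "score_from_alpha",
    "roc_auc",
    "roc_curve_points",
    "sens_spec_at_cutoff",
    "student_t_test",
    "fdr_adjust",
    "rater_error_comparison",
]


def score_from_alpha(alpha_deg: float, cutoff_deg: float = 60.0) -> float:
    """Diagnostic score: positive when alpha is below the DDH cutoff."""
    return float(cutoff_deg - alpha_deg)


@dataclass(frozen=True)
class CohortRecord:
    """One frame of a scored cohort."""

    true_label: bool
    score: float
    qualified: bool = True
    rater_alphas: tuple[float, ...] | None = None


def _split_scores(records: Sequence[CohortRecord]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([r.score for r in records], dtype=float)
    labels = np.array([bool(r.true_label) for r in records])
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(records: Sequence[CohortRecord]) -> float:
    """AUC as the Mann-Whitney pairwise-ranking probability, ties = 0.5."""
    scores, labels = _split_scores(records)
    pos = scores[labels]
    neg = scores[~labels]
    ranks = stats.rankdata(scores)  # midranks handle ties as 0.5 pairs
    r_pos = ranks[labels].sum()
    n_pos, n_neg = len(pos), len(neg)
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_points(records: Sequence[CohortRecord]) -> list[tuple[float, float, float]]:
    """(fpr, tpr, threshold) triples sweeping score thresholds high -> low."""
    scores, labels = _split_scores(records)
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    curve = [(0.0, 0.0, float("inf"))]
    tp = fp = 0
    for i in range(len(scores)):
        tp += int(labels[i])
        fp += int(not labels[i])
        if i + 1 < len(scores) and scores[i + 1] == scores[i]:
            continue  # only emit after each distinct threshold
        curve.append((fp / n_neg, tp / n_pos, float(scores[i])))
    return curve


def sens_spec_at_cutoff(
    records: Sequence[CohortRecord], threshold: float = 0.0
) -> tuple[float, float]:
    """Sensitivity and specificity of ``score > threshold`` as the DDH call.

    With the ``60 - alpha`` score convention, ``threshold=0`` reproduces
    the alpha < 60 cutoff.
    """
    scores, labels = _split_scores(records)
    pred = scores > threshold
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    return tp / (tp + fn), tn / (tn + fp)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: float
    mean_a: float
    mean_b: float


def student_t_test(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sided two-sample t test (pooled-variance Student by default)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return TTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        df=df,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass(frozen=True)
class RaterComparisonReport:
    inter: TTestResult
    intra: TTestResult
    n_qualified: int
    n_disqualified: int


def _rater_errors(rater_alphas: tuple[float, ...]) -> tuple[float, float]:
    """(inter, intra) absolute errors from (r1a, r1b, r2a, r2b) readings."""
    if rater_alphas is None or len(rater_alphas) < 4:
        raise ValueError("need 4 rater readings (2 raters x 2 repeats) per frame")
    r1a, r1b, r2a, r2b = rater_alphas[:4]
    inter = abs((r1a + r1b) / 2.0 - (r2a + r2b) / 2.0)
    intra = abs(r1a - r1b)
    return inter, intra


def rater_error_comparison(records: Sequence[CohortRecord]) -> RaterComparisonReport:
    """Compare inter-/intra-rater absolute errors across the quality gate.

    Per frame, the inter-rater error is the absolute difference between the
    two raters' mean readings and the intra-rater error is the absolute
    difference between rater 1's repeats; the qualified and disqualified
    groups are then compared with the pooled-variance Student t test.
    """
    groups: dict[bool, dict[str, list[float]]] = {
        True: {"inter": [], "intra": []},
        False: {"inter": [], "intra": []},
    }
    for rec in records:
        if rec.rater_alphas is None:
            raise ValueError("record without rater readings")
        inter, intra = _rater_errors(rec.rater_alphas)
        groups[bool(rec.qualified)]["inter"].append(inter)
        groups[bool(rec.qualified)]["intra"].append(intra)
    nq = len(groups[True]["inter"])
    nd = len(groups[False]["inter"])
    if nq < 2 or nd < 2:
        raise ValueError("need >= 2 qualified and >= 2 disqualified frames")
    return RaterComparisonReport(
        inter=student_t_test(groups[True]["inter"], groups[False]["inter"]),
        intra=student_t_test(groups[True]["intra"], groups[False]["intra"]),
        n_qualified=nq,
        n_disqualified=nd,
    )
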