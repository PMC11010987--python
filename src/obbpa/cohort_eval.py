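"""Cohort-level evaluation: group tests, confusion metrics, ROC.

Group differences follow a gated decision tree common in clinical
biomarker reports: Shapiro-Wilk normality per group and Levene's
variance-homogeneity test route the data to one-way ANOVA with Tukey's
post hoc (normal, homoscedastic), Welch's ANOVA with Games-Howell
(normal, heteroscedastic) or Kruskal-Wallis with Conover's post hoc
(non-normal).  Post hoc tests run only when the omnibus test is
significant.  Diagnostic performance is summarised as sensitivity /
specificity from confusion counts, trapezoidal ROC/AUC, and the
biopsy-avoidance fraction (negative calls among patients who would
otherwise all be biopsied).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "TestResult",
    "BiopsyAvoidance",
    "sen_spe",
    "roc_auc",
    "group_test",
    "biopsy_avoidance",
    "conover_posthoc",
    "confusion_from_calls",
]

ALPHA_GATE = 0.05
SIGNIFICANCE_TIERS = (0.05, 0.01, 0.001)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with the cohort context they came from."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = "cs_PCa"
    cohort_filter: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def sen_spe(counts: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity and specificity in percent.

    ``SEN = 100*TP/(TP+FN)`` over the disease class and
    ``SPE = 100*TN/(TN+FP)`` over the non-disease class; either is
    undefined (raises) when its class is empty.
    """
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: no positive-class patients")
    if counts.tn + counts.fp == 0:
        raise ValueError("specificity undefined: no negative-class patients")
    sen = 100.0 * counts.tp / (counts.tp + counts.fn)
    spe = 100.0 * counts.tn / (counts.tn + counts.fp)
    return sen, spe


def confusion_from_calls(
    calls: np.ndarray, is_disease: np.ndarray, **context
) -> ConfusionCounts:
    """Confusion counts from boolean biopsy calls and class labels."""
    calls = np.asarray(calls, dtype=bool)
    is_disease = np.asarray(is_disease, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(calls & is_disease)),
        fp=int(np.sum(calls & ~is_disease)),
        tn=int(np.sum(~calls & ~is_disease)),
        fn=int(np.sum(~calls & is_disease)),
        **context,
    )


def roc_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC for a score against binary labels.

    Thresholds sweep the unique score values (ties step simultaneously,
    so integer composite scores yield coarse stepwise curves).  Returns
    ``(fpr, tpr, thresholds, auc)``; raises when a class is absent.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("ROC undefined: only one class present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return fpr, tpr, thr, float(_sk_auc(fpr, tpr))


@dataclass(frozen=True)
class TestResult:
    """Outcome of the gated group-difference analysis."""

    path: str  # anova_tukey / welch_gameshowell / kruskal_conover
    normality_p: dict[str, float]
    levene_p: float
    omnibus_p: float
    pairwise: pd.DataFrame | None  # None when omnibus not significant


def _games_howell(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    import pingouin as pg

    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    frame = pd.DataFrame({"value": values, "group": labels})
    res = pg.pairwise_gameshowell(data=frame, dv="value", between="group")
    return pd.DataFrame(
        {"group_a": res["A"], "group_b": res["B"], "p": res["pval"]}
    )


def conover_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Conover-Iman all-pairs rank comparison after Kruskal-Wallis.

    Pooled ranks (ties averaged) feed t statistics
    ``t = (Rbar_i - Rbar_j) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))``
    with ``S^2`` the rank variance and ``H`` the Kruskal-Wallis
    statistic, referred to Student's t on ``N - k`` degrees of freedom.
    """
    names = list(groups)
    sizes = {g: len(groups[g]) for g in names}
    pooled = np.concatenate([groups[g] for g in names])
    n_total, k = pooled.size, len(names)
    ranks = stats.rankdata(pooled)
    rank_by_group: dict[str, np.ndarray] = {}
    start = 0
    for g in names:
        rank_by_group[g] = ranks[start : start + sizes[g]]
        start += sizes[g]
    h_stat = stats.kruskal(*groups.values()).statistic
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1) ** 2 / 4.0) / (n_total - 1)
    factor = s2 * (n_total - 1 - h_stat) / (n_total - k)
    dof = n_total - k
    rows = []
    for a, b in itertools.combinations(names, 2):
        diff = rank_by_group[a].mean() - rank_by_group[b].mean()
        se = np.sqrt(factor * (1.0 / sizes[a] + 1.0 / sizes[b]))
        t = diff / se
        p = 2.0 * stats.t.sf(abs(t), dof)
        rows.append({"group_a": a, "group_b": b, "p": float(min(p, 1.0))})
    return pd.DataFrame(rows)


def _tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    res = stats.tukey_hsd(*groups.values())
    names = list(groups)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {"group_a": names[i], "group_b": names[j], "p": float(res.pvalue[i, j])}
        )
    return pd.DataFrame(rows)


def group_test(groups: dict[str, np.ndarray], alpha: float = ALPHA_GATE) -> TestResult:
    """Gated group-difference test over two or more groups.

    Routes to ANOVA+Tukey when every group passes Shapiro-Wilk and
    Levene accepts homoscedasticity; to Welch's ANOVA + Games-Howell
    when groups are normal but heteroscedastic; otherwise (any
    non-normal group, regardless of variance) to Kruskal-Wallis +
    Conover — the conservative completion of the routing table.  Post
    hoc runs only when the omnibus p-value is below ``alpha``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, vals in groups.items():
        if vals.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
        if np.ptp(vals) == 0:
            raise ValueError(f"group {name!r} is constant; tests are degenerate")

    normality = {k: float(stats.shapiro(v).pvalue) for k, v in groups.items()}
    levene_p = float(stats.levene(*groups.values(), center="mean").pvalue)
    all_normal = all(p >= alpha for p in normality.values())

    if all_normal and levene_p >= alpha:
        path = "anova_tukey"
        omnibus = float(stats.f_oneway(*groups.values()).pvalue)
        posthoc_fn = _tukey
    elif all_normal:
        path = "welch_gameshowell"
        import pingouin as pg

        values = np.concatenate(list(groups.values()))
        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        frame = pd.DataFrame({"value": values, "group": labels})
        omnibus = float(
            pg.welch_anova(data=frame, dv="value", between="group")["p_unc"].iloc[0]
        )
        posthoc_fn = _games_howell
    else:
        path = "kruskal_conover"
        omnibus = float(stats.kruskal(*groups.values()).pvalue)
        posthoc_fn = conover_posthoc

    pairwise = posthoc_fn(groups) if omnibus < alpha else None
    return TestResult(
        path=path,
        normality_p=normality,
        levene_p=levene_p,
        omnibus_p=omnibus,
        pairwise=pairwise,
    )


@dataclass(frozen=True)
class BiopsyAvoidance:
    """Negative calls among patients who would otherwise be biopsied."""

    avoided: int
    total: int
    fraction_pct: float
    missed_cs: int | None  # None when ground truth is unavailable


def biopsy_avoidance(
    calls, labels=None, cohort_mask=None
) -> BiopsyAvoidance:
    """Fraction of biopsies avoidable under a score's negative calls.

    ``calls`` are biopsy calls (True = positive, biopsy indicated);
    ``labels`` (optional) are ground-truth group labels used to count
    missed clinically significant cancers among the negatives;
    ``cohort_mask`` restricts the accounting (e.g. a tPSA window).
    """
    calls = np.asarray(calls, dtype=bool)
    if cohort_mask is not None:
        cohort_mask = np.asarray(cohort_mask, dtype=bool)
        calls_f = calls[cohort_mask]
        labels_f = None if labels is None else np.asarray(labels)[cohort_mask]
    else:
        calls_f = calls
        labels_f = None if labels is None else np.asarray(labels)
    total = calls_f.size
    if total == 0:
        raise ValueError("empty cohort after filtering")
    avoided = int(np.sum(~calls_f))
    missed = None
    if labels_f is not None:
        missed = int(np.sum((~calls_f) & (labels_f == "cs_PCa")))
    return BiopsyAvoidance(
        avoided=avoided,
        total=total,
        fraction_pct=100.0 * avoided / total,
        missed_cs=missed,
    )
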