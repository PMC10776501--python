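"""Statistics layer: ROC/AUC with DeLong confidence intervals, operating
points, confusion metrics, subgroup ROC, rank tests, ANOVA and heatmap
clustering orders.

The AUC is the trapezoid area under the ROC curve, which equals the
Mann-Whitney U statistic divided by n_pos * n_neg with ties counted as
one half. Its variance is estimated nonparametrically by the DeLong
structural-components method: with placement values

    V10_i = mean_j psi(X_i, Y_j),   V01_j = mean_i psi(X_i, Y_j),
    psi(x, y) = 1 if x > y, 1/2 if x = y, 0 if x < y,

Var(AUC) = S10 / n_pos + S01 / n_neg where S10, S01 are the sample
variances of the placements, and the 95% CI is the normal-theory
interval clamped to [0, 1].
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .cohort import SampleMeta
from .errors import EvaluationError

DEFAULT_STAGE_GROUPS: dict[str, tuple[str, ...]] = {"II-III": ("II", "III"), "IV": ("IV",)}


@dataclass
class ROCResult:
    """ROC curve with AUC and (optionally) a 95% CI.

    Arrays are aligned and ordered by increasing threshold, so
    sensitivity is non-increasing along the arrays.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts and the five derived statistics at one operating threshold.

    Ratios with a zero denominator are reported as NaN (not available),
    never as 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else math.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else math.nan

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def _scores_labels(scores, labels, positive_label=None) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    lab = np.asarray([str(v) for v in labels])
    classes = np.unique(lab)
    if len(classes) != 2:
        raise EvaluationError(f"need exactly two classes, got {list(classes)}")
    if positive_label is None:
        from .classifier import infer_positive_label

        positive_label = infer_positive_label(lab)
    y = lab == str(positive_label)
    if y.all() or not y.any():
        raise EvaluationError("both classes must be present")
    return s, y


def roc_curve(scores, labels, positive_label=None) -> ROCResult:
    """ROC over all distinct score cut points (plus the +inf boundary)."""
    s, y = _scores_labels(scores, labels, positive_label)
    fpr, tpr, thr = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    # sklearn orders by decreasing threshold; flip to increasing
    order = slice(None, None, -1)
    auc = auc_mann_whitney(s[y], s[~y])
    return ROCResult(
        thresholds=thr[order],
        sensitivity=tpr[order],
        specificity=(1 - fpr)[order],
        auc=auc,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
    )


def auc_mann_whitney(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC as the normalised U statistic via midranks (ties count half)."""
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    m, n = len(pos_scores), len(neg_scores)
    ranks = stats.rankdata(np.concatenate([pos_scores, neg_scores]))
    u = ranks[:m].sum() - m * (m + 1) / 2
    return float(u / (m * n))


def delong_components(
    pos_scores: np.ndarray, neg_scores: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-observation placement values (midrank computation)."""
    pos_scores = np.asarray(pos_scores, dtype=float)
    neg_scores = np.asarray(neg_scores, dtype=float)
    m, n = len(pos_scores), len(neg_scores)
    all_ranks = stats.rankdata(np.concatenate([pos_scores, neg_scores]))
    pos_ranks = stats.rankdata(pos_scores)
    neg_ranks = stats.rankdata(neg_scores)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float((all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n))
    return auc, v10, v01


def delong_variance(scores, labels, positive_label=None) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC)."""
    s, y = _scores_labels(scores, labels, positive_label)
    auc, v10, v01 = delong_components(s[y], s[~y])
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise EvaluationError("DeLong variance needs >= 2 samples per class")
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return auc, float(var)


def auc_ci_delong(scores, labels, level: float = 0.95, positive_label=None) -> tuple[float, float]:
    """Normal-theory DeLong CI for the AUC, clamped to [0, 1].

    A degenerate variance (e.g. perfect separation with a clear margin)
    yields a zero-width interval at the AUC, with a warning.
    """
    auc, var = delong_variance(scores, labels, positive_label)
    if var <= 0:
        warnings.warn("degenerate DeLong variance; returning zero-width CI")
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def auc_ci_bootstrap(
    scores,
    labels,
    level: float = 0.95,
    n_resamples: int = 2000,
    seed: int = 0,
    positive_label=None,
) -> tuple[float, float]:
    """Percentile-bootstrap CI (stratified resampling), seeded."""
    s, y = _scores_labels(scores, labels, positive_label)
    pos, neg = s[y], s[~y]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_resamples)
    for b in range(n_resamples):
        aucs[b] = auc_mann_whitney(
            pos[rng.integers(0, len(pos), len(pos))],
            neg[rng.integers(0, len(neg), len(neg))],
        )
    lo, hi = np.quantile(aucs, [(1 - level) / 2, 0.5 + level / 2])
    return float(lo), float(hi)


def youden_threshold(roc: ROCResult) -> float:
    """Threshold maximising J = sensitivity + specificity - 1.

    Ties go to the threshold with higher specificity; with all-tied
    scores J is 0 everywhere and the +inf boundary (predict all
    negative) is returned.
    """
    j = roc.sensitivity + roc.specificity - 1
    best = max(range(len(j)), key=lambda i: (j[i], roc.specificity[i]))
    return float(roc.thresholds[best])


def confusion_metrics(scores, labels, threshold: float, positive_label=None) -> ConfusionMetrics:
    """Counts at the operating point: predict positive iff score >= threshold."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray([str(v) for v in labels])
    if positive_label is None:
        from .classifier import infer_positive_label

        positive_label = infer_positive_label(lab)
    y = lab == str(positive_label)
    pred = s >= threshold
    return ConfusionMetrics(
        tp=int((pred & y).sum()),
        tn=int((~pred & ~y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        threshold=float(threshold),
    )


def subgroup_roc(
    scores: pd.Series,
    metas: Sequence[SampleMeta],
    group_by: str = "cancer_type",
    stage_groups: Mapping[str, tuple[str, ...]] | None = None,
    with_ci: bool = True,
) -> dict[str, ROCResult]:
    """Per-subgroup ROC: each cancer subgroup against *all* healthy controls.

    ``group_by`` is ``"cancer_type"`` or ``"stage"``; stages are pooled
    into II-III and IV by default. Empty subgroups are skipped with a
    warning. Only samples present in ``scores`` participate, so the
    caller controls whether train+test are combined.
    """
    if group_by not in ("cancer_type", "stage"):
        raise EvaluationError(f"group_by must be 'cancer_type' or 'stage', got {group_by!r}")
    by_id = {m.sample_id: m for m in metas}
    ids = [s for s in scores.index if s in by_id]
    healthy = [s for s in ids if by_id[s].label == "healthy"]
    cancer = [s for s in ids if by_id[s].label == "cancer"]
    if group_by == "stage":
        groups = stage_groups or DEFAULT_STAGE_GROUPS
        membership = {
            name: [s for s in cancer if by_id[s].stage in levels]
            for name, levels in groups.items()
        }
    else:
        values = sorted({by_id[s].cancer_type for s in cancer if by_id[s].cancer_type})
        membership = {
            v: [s for s in cancer if by_id[s].cancer_type == v] for v in values
        }
    out: dict[str, ROCResult] = {}
    for name, members in membership.items():
        if not members:
            warnings.warn(f"subgroup {name!r} is empty; skipped")
            continue
        sub_ids = members + healthy
        sub_scores = scores.loc[sub_ids]
        sub_labels = [by_id[s].label for s in sub_ids]
        roc = roc_curve(sub_scores, sub_labels, positive_label="cancer")
        if with_ci and roc.n_pos >= 2 and roc.n_neg >= 2:
            roc.ci_low, roc.ci_high = auc_ci_delong(
                sub_scores, sub_labels, positive_label="cancer"
            )
        out[name] = roc
    return out


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact distribution when both samples have n <= 12 and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections. Returns (U statistic of x, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EvaluationError("both groups must be nonempty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size <= 12 and y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def motif_group_tests(
    matrix: pd.DataFrame,
    labels: Sequence,
    positive_label: str = "cancer",
    motifs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-motif cancer-vs-healthy rank-sum tests.

    Raw p-values are not adjusted for multiplicity by default; a
    Benjamini-Hochberg column is always written alongside.
    """
    lab = np.asarray([str(v) for v in labels])
    pos = lab == positive_label
    motifs = list(motifs) if motifs is not None else list(matrix.columns)
    rows = []
    for m in motifs:
        u, p = wilcoxon_rank_sum(matrix.loc[pos, m], matrix.loc[~pos, m])
        direction = "up" if matrix.loc[pos, m].mean() > matrix.loc[~pos, m].mean() else "down"
        rows.append({"motif": m, "statistic": u, "p_value": p, "direction": direction})
    df = pd.DataFrame(rows)
    df["p_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def anova_scores(scores: Sequence[float], strata: Sequence) -> tuple[float, float]:
    """One-way ANOVA of scores across covariate strata."""
    scores = np.asarray(scores, dtype=float)
    strata = np.asarray([str(v) for v in strata])
    groups = [scores[strata == g] for g in np.unique(strata)]
    if len(groups) < 2:
        raise EvaluationError("ANOVA needs at least 2 strata")
    if any(len(g) < 2 for g in groups):
        raise EvaluationError("every stratum needs at least 2 samples")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def heatmap_order(
    matrix: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Clustering orders for a heatmap of selected-motif frequencies.

    Each motif column is z-scaled across samples (zero-variance columns
    become zeros, with a warning); rows and columns are clustered by
    agglomerative (complete-linkage, Euclidean) clustering. Returns
    (row leaf order, column leaf order, scaled matrix).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise EvaluationError("heatmap clustering needs >= 2 rows and >= 2 columns")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance motifs scaled to zeros: {list(matrix.columns[zero_var])}"
        )
    scaled = np.where(zero_var, 0.0, (values - mean) / np.where(zero_var, 1.0, sd))
    row_link = hierarchy.linkage(scaled, method="complete", metric="euclidean")
    col_link = hierarchy.linkage(scaled.T, method="complete", metric="euclidean")
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    scaled_df = pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
    return row_order, col_order, scaled_df


def roc_table(roc: ROCResult) -> pd.DataFrame:
    """ROC points as a TSV-serialisable table."""
    return pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }
    )
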