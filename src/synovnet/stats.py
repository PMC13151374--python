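"""Group-comparison statistics and ROC machinery for synovial-fluid markers.

Group comparisons follow the study's nonparametric scheme: Shapiro-Wilk
normality per group (descriptive), a Kruskal-Wallis omnibus across more
than two groups, and pairwise Mann-Whitney U tests with Bonferroni
correction over the number of pairs. Significance tiers: *** p <= 0.001,
** 0.001 < p <= 0.01, * 0.01 < p <= 0.05, else NS.

ROC analysis is fully nonparametric: the AUC is the Mann-Whitney
probability P(score_pos > score_neg) + 1/2 P(tie), its variance comes from
DeLong's placement-value components, and the operating cut-off maximises
Youden's J = sensitivity + specificity - 1. Combined marker panels are
scored with an L2-penalised (ridge) logistic regression whose linear score
feeds the same ROC machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from synovnet.cohort import CohortTable

SIGNIFICANCE_ALPHA = 0.050


def significance_tier(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


@dataclass
class GroupComparisonResult:
    marker: str
    groups: tuple[str, ...]
    test: str  # shapiro_wilk | mann_whitney | kruskal_wallis
    statistic: float
    p_raw: float
    p_adjusted: float
    tier: str
    significant: bool


@dataclass
class ROCResult:
    marker: str
    higher_is_positive: bool
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    delong_variance: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    youden_j: float | None = None
    cutoff: float | None = None
    cutoff_sensitivity: float | None = None
    cutoff_specificity: float | None = None


@dataclass
class CombinedModel:
    markers: tuple[str, ...]
    lam: float
    coefficients: np.ndarray
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    scores: np.ndarray
    roc: ROCResult
    cv_log_loss: dict[float, float] = field(default_factory=dict)
    cv_auc: float | None = None


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for small tie-free samples,
    tie-corrected normal approximation otherwise."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 12 and len(y) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    cohort: CohortTable, marker: str, grouping: list[str] | None = None
) -> list[GroupComparisonResult]:
    """Nonparametric group comparison for one marker.

    Reports Shapiro-Wilk per group (descriptive, unadjusted), a
    Kruskal-Wallis omnibus when more than two groups are compared, and all
    pairwise Mann-Whitney tests with Bonferroni adjustment over the number
    of pairs. Groups with fewer than 2 observations are dropped with a
    warning; Shapiro-Wilk needs at least 3.
    """
    df = cohort.df
    if grouping is None:
        grouping = sorted(df["group"].unique())
    samples: dict[str, np.ndarray] = {}
    for label in grouping:
        vals = df.loc[df["group"] == label, marker].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(
                f"group {label!r} has {len(vals)} observation(s); excluded",
                stacklevel=2,
            )
            continue
        samples[label] = vals
    if len(samples) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")

    results: list[GroupComparisonResult] = []
    for label, vals in samples.items():
        if len(vals) >= 3:
            stat, p = sps.shapiro(vals)
            results.append(
                GroupComparisonResult(
                    marker, (label,), "shapiro_wilk", float(stat), float(p),
                    float(p), significance_tier(p), p <= SIGNIFICANCE_ALPHA,
                )
            )
    labels = list(samples)
    if len(labels) > 2:
        stat, p = sps.kruskal(*samples.values())
        results.append(
            GroupComparisonResult(
                marker, tuple(labels), "kruskal_wallis", float(stat), float(p),
                float(p), significance_tier(p), p <= SIGNIFICANCE_ALPHA,
            )
        )
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    m = len(pairs)
    for a, b in pairs:
        stat, p = _mannwhitney(samples[a], samples[b])
        p_adj = min(1.0, p * m)
        results.append(
            GroupComparisonResult(
                marker, (a, b), "mann_whitney", stat, p, p_adj,
                significance_tier(p_adj), p_adj <= SIGNIFICANCE_ALPHA,
            )
        )
    return results


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------


def _check_binary(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be present")
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    return scores, labels


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U via midranks (ties count 1/2)."""
    ranks = sps.rankdata(scores)
    m = labels.sum()
    n = len(labels) - m
    u = ranks[labels == 1].sum() - m * (m + 1) / 2.0
    return float(u / (m * n))


def _roc_points(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds, sensitivity, specificity) over all candidate cut-offs.

    Candidates are the midpoints between adjacent distinct scores plus one
    extrapolated point below the minimum (classify everyone positive) and
    one above the maximum (classify everyone negative); a sample is called
    positive when its score >= threshold.
    """
    distinct = np.unique(scores)
    if len(distinct) == 1:
        gaps = np.array([1.0])
    else:
        gaps = np.diff(distinct)
    cand = np.concatenate(
        [
            [distinct[0] - gaps[0] / 2.0],
            (distinct[:-1] + distinct[1:]) / 2.0,
            [distinct[-1] + gaps[-1] / 2.0],
        ]
    )
    pos = labels == 1
    sens = np.array([(scores[pos] >= t).mean() for t in cand])
    spec = np.array([(scores[~pos] < t).mean() for t in cand])
    return cand, sens, spec


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    marker: str = "score",
    higher_is_positive: bool = True,
) -> ROCResult:
    """Empirical ROC curve and rank-based AUC.

    ``higher_is_positive=False`` flips the marker orientation (for markers
    where *low* values indicate infection); the reported ROC is then for
    the negated score, and the reported orientation flag says so.
    """
    scores, labels = _check_binary(scores, labels)
    oriented = scores if higher_is_positive else -scores
    thresholds, sens, spec = _roc_points(oriented, labels)
    return ROCResult(
        marker=marker,
        higher_is_positive=higher_is_positive,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=_auc_rank(oriented, labels),
    )


def delong_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    level: float = 0.95,
    higher_is_positive: bool = True,
) -> tuple[float, float, tuple[float, float]]:
    """DeLong nonparametric AUC variance and normal-approximation CI.

    Placement values: for each positive, the fraction of negatives it
    outranks (ties 1/2), and symmetrically for negatives. The variance is
    S10/m + S01/n with S the sample variances of the two component sets.
    Returns (auc, variance, (ci_low, ci_high)); the CI is clipped to [0,1]
    and collapses to a point when the variance is 0 (perfect separation).
    """
    scores, labels = _check_binary(scores, labels)
    if labels.sum() < 2 or (len(labels) - labels.sum()) < 2:
        raise ValueError("need at least 2 observations per class")
    x = scores if higher_is_positive else -scores
    pos = x[labels == 1]
    neg = x[labels == 0]
    m, n = len(pos), len(neg)
    cmp_matrix = (pos[:, None] > neg[None, :]).astype(float)
    cmp_matrix += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_matrix.mean(axis=1)  # per-positive placement
    v01 = cmp_matrix.mean(axis=0)  # per-negative placement
    auc = float(cmp_matrix.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    if var == 0.0:
        return auc, 0.0, (auc, auc)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, var, (max(0.0, auc - half), min(1.0, auc + half))


def youden_cutoff(
    scores: np.ndarray,
    labels: np.ndarray,
    higher_is_positive: bool = True,
) -> tuple[float, float, float, float]:
    """Youden-optimal cut-off: maximise J = sensitivity + specificity - 1.

    Scans all candidate thresholds (midpoints of adjacent distinct scores
    plus the two extrapolated extremes). Ties are resolved to the lowest
    cut-off achieving the maximal J, which favours sensitivity. Returns
    (cutoff, J, sensitivity, specificity); the cutoff is on the oriented
    scale (negated scores when ``higher_is_positive=False``).
    """
    scores, labels = _check_binary(scores, labels)
    oriented = scores if higher_is_positive else -scores
    thresholds, sens, spec = _roc_points(oriented, labels)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # argmax keeps the first (lowest) maximiser
    return float(thresholds[best]), float(j[best]), float(sens[best]), float(spec[best])


def full_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    marker: str = "score",
    higher_is_positive: bool = True,
    level: float = 0.95,
) -> ROCResult:
    """ROC curve + DeLong CI + Youden cut-off in one report."""
    res = roc_auc(scores, labels, marker=marker, higher_is_positive=higher_is_positive)
    auc, var, (lo, hi) = delong_ci(
        scores, labels, level=level, higher_is_positive=higher_is_positive
    )
    assert abs(auc - res.auc) < 1e-12
    cut, j, sens, spec = youden_cutoff(
        scores, labels, higher_is_positive=higher_is_positive
    )
    res.delong_variance = var
    res.ci_low, res.ci_high = lo, hi
    res.youden_j = j
    res.cutoff = cut
    res.cutoff_sensitivity = sens
    res.cutoff_specificity = spec
    return res


# ---------------------------------------------------------------------------
# Combined (ridge logistic) ROC
# ---------------------------------------------------------------------------

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-3, 3, 13))


def combined_roc(
    cohort: CohortTable | pd.DataFrame,
    markers: list[str],
    labels: np.ndarray,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> CombinedModel:
    """Ridge-logistic combination of a marker panel, scored by ROC.

    Features are z-standardised; the L2 penalty strength is chosen by
    stratified cross-validated log-loss over ``lambda_grid`` (fold count
    shrunk if a class is small); the final model is refit on all patients
    and its linear score is fed to the nonparametric ROC machinery. Both
    the in-sample AUC (the headline number) and the cross-validated AUC of
    out-of-fold scores at the chosen penalty are reported.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import log_loss
    from sklearn.model_selection import StratifiedKFold

    if len(markers) < 1:
        raise ValueError("need at least one marker")
    frame = cohort.marker_matrix(markers) if isinstance(cohort, CohortTable) else cohort[markers]
    x = frame.to_numpy(dtype=float)
    _, y = _check_binary(np.zeros(len(x)), labels)
    if np.isnan(x).any():
        raise ValueError("missing marker values in combined model input")

    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    xz = (x - mean) / sd_safe

    n_min = min(int(y.sum()), int(len(y) - y.sum()))
    k = max(2, min(folds, n_min))
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    cv_loss: dict[float, float] = {}
    oof_scores: dict[float, np.ndarray] = {}
    for lam in lambda_grid:
        losses = []
        oof = np.zeros(len(y))
        for train, test in cv.split(xz, y):
            model = LogisticRegression(C=1.0 / lam, solver="lbfgs", max_iter=5000)
            model.fit(xz[train], y[train])
            prob = model.predict_proba(xz[test])[:, 1]
            losses.append(log_loss(y[test], prob, labels=[0, 1]))
            oof[test] = xz[test] @ model.coef_[0] + model.intercept_[0]
        cv_loss[lam] = float(np.mean(losses))
        oof_scores[lam] = oof
    best_lam = min(cv_loss, key=lambda l: (cv_loss[l], l))

    final = LogisticRegression(C=1.0 / best_lam, solver="lbfgs", max_iter=5000)
    final.fit(xz, y)
    scores = xz @ final.coef_[0] + final.intercept_[0]
    roc = full_roc(scores, y, marker="+".join(markers))
    cv_auc = _auc_rank(oof_scores[best_lam], y)
    return CombinedModel(
        markers=tuple(markers),
        lam=best_lam,
        coefficients=final.coef_[0].copy(),
        intercept=float(final.intercept_[0]),
        feature_means=mean,
        feature_sds=sd_safe,
        scores=scores,
        roc=roc,
        cv_log_loss=cv_loss,
        cv_auc=float(cv_auc),
    )
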