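"""The study's statistical battery.

Group comparisons are rank-based (the ASP distributions are skewed):
Kruskal-Wallis across the four RECIST classes and Mann-Whitney U for the
responding/non-responding dichotomy. Discrimination is summarized by an
empirical ROC curve with the Youden-optimal cutoff (J = sensitivity +
specificity - 1), and method agreement between two ASP readings by
Spearman's rho plus Bland-Altman limits of agreement with a concordance
rule of at most 5 ASP percentage points of absolute difference.

Conventions (all deliberate, all tested):

* ROC positive class is the *non-responding* group — higher ASP predicts
  poorer response — and the direction is asserted, never auto-detected.
* Candidate cutoffs are midpoints of consecutive distinct scores plus
  +/- infinity; AUC is the trapezoid integral, which equals the
  Mann-Whitney estimator U/(n1*n2) with half credit for cross-class ties.
* Youden ties are broken toward the lowest cutoff (maximizes sensitivity,
  the screening-oriented choice); the cutoff is reported with the
  "greater than" convention: predict positive iff score > cutoff.
* Bland-Altman limits are mean +/- 1.96 * sample SD (n-1 denominator);
  a pair is discordant iff |difference| > 5 (strictly), i.e. a deviation
  of exactly 5 points still counts as concordant.
* p-values are two-sided; significance is conventionally read at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .synthetic.quantiles import FiveNumberSummary


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    p_value: float
    group_summaries: tuple[FiveNumberSummary, ...] = ()


@dataclass(frozen=True)
class ROCResult:
    points: np.ndarray  # (n, 2) array of (1 - specificity, sensitivity)
    auc: float
    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class AgreementResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    rho: float
    rho_p: float
    n_discordant: int
    n_total: int


def five_number_summary(values) -> FiveNumberSummary:
    v = np.asarray(values, float)
    q = np.percentile(v, [0, 25, 50, 75, 100])
    return FiveNumberSummary(*q)


def kruskal_wallis(*groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = k - 1).

    All-tied input returns H = 0 / p = 1 rather than the 0/0 of the tie
    correction (documented convention).
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("kruskal_wallis: empty group")
    summaries = tuple(five_number_summary(a) for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupTestResult(statistic=0.0, p_value=1.0, group_summaries=summaries)
    h, p = sps.kruskal(*arrays)
    return GroupTestResult(statistic=float(h), p_value=float(p), group_summaries=summaries)


def mann_whitney_u(x, y) -> GroupTestResult:
    """U statistic of y over x with tie-corrected, continuity-corrected normal p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u: empty input")
    res = sps.mannwhitneyu(y, x, alternative="two-sided", method="asymptotic")
    return GroupTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_summaries=(five_number_summary(x), five_number_summary(y)),
    )


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    # for near-adjacent floats the midpoint can round onto an endpoint and
    # merge two operating points; the lower value itself still separates
    # exactly under the strict "score > cutoff" rule
    bad = (mids >= distinct[1:]) | (mids <= distinct[:-1])
    mids[bad] = distinct[:-1][bad]
    return np.concatenate(([-np.inf], mids, [np.inf]))


def roc(scores, labels, positive: str = "NRL") -> ROCResult:
    """Empirical ROC of ``scores`` against binary ``labels``.

    ``positive`` names the positive class (non-responding lesions by
    default; higher score = more likely positive). Points are evaluated at
    every midpoint cutoff between consecutive distinct scores, plus the
    two trivial cutoffs; the Youden-optimal operating point is attached.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc: both classes must be present")
    cutoffs = _candidate_cutoffs(scores)
    # predict positive iff score > cutoff
    sens = np.array([(scores[pos] > c).mean() for c in cutoffs])
    spec = np.array([(scores[~pos] <= c).mean() for c in cutoffs])
    fpr = 1.0 - spec
    order = np.argsort(cutoffs)[::-1]  # from all-negative (0,0) to all-positive (1,1)
    points = np.column_stack([fpr[order], sens[order]])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    j = sens + spec - 1.0
    best = int(np.lexsort((cutoffs, -j))[0])  # max J; ties -> lowest cutoff
    return ROCResult(
        points=points,
        auc=auc,
        cutoff=float(cutoffs[best]),
        youden_j=float(j[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def youden_cutoff(roc_result: ROCResult) -> tuple[float, float, float, float]:
    """(cutoff, J, sensitivity, specificity) of the Youden-optimal point."""
    return (
        roc_result.cutoff,
        roc_result.youden_j,
        roc_result.sensitivity,
        roc_result.specificity,
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho (Pearson on tie-averaged ranks) with t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("spearman: inputs must be paired")
    if x.size < 3:
        raise ValueError("spearman: need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman: rank correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bland_altman(a, b, concordance_limit_pp: float = 5.0) -> AgreementResult:
    """Bland-Altman agreement of two paired readings, plus Spearman's rho.

    Differences are a - b; limits of agreement are mean +/- 1.96 * SD
    (sample SD, n-1); a pair is discordant iff |a - b| > the concordance
    limit (default 5 ASP percentage points, inclusive at the limit).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("bland_altman: inputs must be paired")
    n = a.size
    if n < 2:
        raise ValueError("bland_altman: need n >= 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    try:
        rho, rho_p = spearman(a, b)
    except ValueError:
        rho, rho_p = float("nan"), float("nan")
    return AgreementResult(
        mean_diff=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        rho=rho,
        rho_p=rho_p,
        n_discordant=int((np.abs(d) > concordance_limit_pp).sum()),
        n_total=int(n),
    )
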