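"""Cohort-level biomarker evaluation.

Group comparisons (Kruskal–Wallis with Dunn's post hoc), correlation and
age-adjusted partial correlation, ROC discrimination with a Youden operating
point, MMSE-based dementia severity binning, and analytic two-sample t-test
power — the statistical toolkit for judging a continuous blood biomarker
(here a promoter-CpG methylation percentage) against clinical groups.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "RocResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "correlation",
    "partial_correlation",
    "partial_correlation_from_r",
    "roc",
    "classify_severity",
    "ttest_power",
    "SEVERITY_BINS",
]


@dataclass(frozen=True)
class TestResult:
    """A labelled statistic with its p-value and context."""

    name: str
    statistic: float
    p_value: float
    df: float | None = None
    group_sizes: tuple[int, ...] | None = None
    adjustment: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0,1]: {self.p_value}")


@dataclass(frozen=True)
class RocResult:
    points: pd.DataFrame  # threshold, sensitivity, specificity (threshold-ordered)
    auc: float
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    direction: str
    n_positive: int
    n_negative: int


# ---------------------------------------------------------------------------
# rank-based group comparisons


def kruskal_wallis(*groups) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with a chi-square p (k-1 df).

    The degenerate case of all values identical across all groups returns
    H = 0, p = 1 rather than erroring.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate(groups)
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return TestResult(
            "kruskal_wallis", 0.0, 1.0, df=len(groups) - 1,
            group_sizes=tuple(len(g) for g in groups),
        )
    h, p = sps.kruskal(*groups)
    return TestResult(
        "kruskal_wallis", float(h), float(p), df=len(groups) - 1,
        group_sizes=tuple(len(g) for g in groups),
    )


def dunn_posthoc(
    groups: dict[str, np.ndarray] | list, adjustment: str = "bonferroni"
) -> list[TestResult]:
    """Dunn's pairwise post-hoc z tests on pooled ranks.

    Pairwise z = (mean rank_i - mean rank_j) / sqrt(sigma2 * (1/n_i + 1/n_j))
    with the tie-corrected pooled rank variance
    sigma2 = N(N+1)/12 - sum(t^3 - t) / (12 (N - 1)).
    Two-sided normal p-values are multiplied by the number of comparisons
    (Bonferroni, capped at 1); ``adjustment="none"`` reports raw p.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if isinstance(groups, dict):
        labels = list(groups)
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i}" for i in range(len(data))]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for lab, g in zip(labels, data):
        if g.size == 0:
            raise ValueError(f"group {lab!r} is empty")

    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [g.size for g in data])
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(data))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(range(len(data)), 2))
    m = len(pairs)
    results = []
    for i, j in pairs:
        se = math.sqrt(sigma2 * (1.0 / data[i].size + 1.0 / data[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p = min(1.0, p_raw * m) if adjustment == "bonferroni" else p_raw
        results.append(
            TestResult(
                f"dunn:{labels[i]}_vs_{labels[j]}",
                float(z),
                float(p),
                group_sizes=(data[i].size, data[j].size),
                adjustment=adjustment,
                extra={"p_unadjusted": float(p_raw), "n_comparisons": m},
            )
        )
    return results


# ---------------------------------------------------------------------------
# correlation


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson's r or Spearman's rho with its t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(method, float(r), float(p), df=x.size - 2)


def partial_correlation_from_r(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y controlling z."""
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        raise ValueError("degenerate conditioning: |r_xz| = 1 or |r_yz| = 1")
    return (r_xy - r_xz * r_yz) / math.sqrt(denom)


def partial_correlation(x, y, z) -> TestResult:
    """Partial Pearson correlation of x and y adjusting for z.

    p-value from t = r sqrt((n-3)/(1-r^2)) on n-3 degrees of freedom.
    Symmetric in x and y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    r = partial_correlation_from_r(r_xy, r_xz, r_yz)
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r**2))
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("partial_pearson", r, float(p), df=df)


# ---------------------------------------------------------------------------
# ROC


def roc(scores, labels, direction: str, positive_label="AD") -> RocResult:
    """ROC analysis of a continuous score against binary class labels.

    ``direction`` is mandatory and never inferred: ``"lower_is_positive"``
    means smaller scores indicate the positive class (e.g. hypomethylation
    marking disease); ``"higher_is_positive"`` the reverse.

    The curve sweeps every distinct score as a threshold; for
    lower_is_positive a sample is called positive when score <= threshold.
    AUC is the pairwise concordance probability (ties credited 1/2), which
    equals the trapezoidal area under the swept curve exactly.  The
    operating point maximizes Youden's J = sensitivity + specificity - 1,
    ties broken toward higher specificity.
    """
    if direction not in ("lower_is_positive", "higher_is_positive"):
        raise ValueError(f"direction must be explicit, got {direction!r}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == positive_label if labels.dtype.kind in "OUS" else labels.astype(bool)
    n_pos = int(np.sum(pos))
    n_neg = int(np.sum(~pos))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    # orient so that LOWER oriented score = more positive, uniformly
    s = scores if direction == "lower_is_positive" else -scores

    # AUC as concordance via the Mann-Whitney U statistic on oriented scores
    ranks = sps.rankdata(s)
    rank_sum_pos = float(np.sum(ranks[pos]))
    u_pos = rank_sum_pos - n_pos * (n_pos + 1) / 2.0  # pairs where pos > neg (+0.5 ties)
    auc = 1.0 - u_pos / (n_pos * n_neg)  # positive should score LOW

    thresholds = np.unique(s)
    sens = np.array([np.mean(s[pos] <= t) for t in thresholds])
    spec = np.array([np.mean(s[~pos] > t) for t in thresholds])

    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(np.isclose(j, best_j))
    best = tied[np.argmax(spec[tied])]

    if direction == "lower_is_positive":
        points = pd.DataFrame(
            {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
        )
        cutoff = float(thresholds[best])
    else:
        points = pd.DataFrame(
            {"threshold": -thresholds, "sensitivity": sens, "specificity": spec}
        )
        cutoff = float(-thresholds[best])

    return RocResult(
        points=points,
        auc=float(auc),
        youden_cutoff=cutoff,
        sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
        direction=direction,
        n_positive=n_pos,
        n_negative=n_neg,
    )


# ---------------------------------------------------------------------------
# severity & power

# MMSE severity bins.  The clinical scheme quotes mild 21-26, moderate 10-20,
# moderately severe 10-14 and severe <10; the finer "moderately severe" band
# carves 10-14 out of the coarser moderate band, leaving moderate = 15-20.
# Scores above 26 fall outside the quoted dementia bins and are labelled
# mild_or_above.
SEVERITY_BINS = (
    ("severe", 0, 9),
    ("moderately_severe", 10, 14),
    ("moderate", 15, 20),
    ("mild", 21, 26),
    ("mild_or_above", 27, 30),
)


def classify_severity(mmse: int) -> str:
    """Dementia severity label from an MMSE score (0-30)."""
    if not 0 <= mmse <= 30:
        raise ValueError(f"MMSE score out of range [0,30]: {mmse}")
    for label, lo, hi in SEVERITY_BINS:
        if lo <= mmse <= hi:
            return label
    raise AssertionError("unreachable")


def ttest_power(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    alpha: float = 0.05,
    method: str = "pooled",
) -> TestResult:
    """Analytic power of the two-sided two-sample t test.

    Power is evaluated from the noncentral t distribution with
    noncentrality ncp = (mean1 - mean2) / se and the df/se of the chosen
    variance treatment: ``"pooled"`` (classic equal-variance t) or
    ``"welch"`` (Satterthwaite df with the unpooled se).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if method == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif method == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown method {method!r}")
    ncp = (mean1 - mean2) / se
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    power = sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp)
    return TestResult(
        f"ttest_power_{method}",
        float(power),
        p_value=float(alpha),
        df=float(df),
        group_sizes=(n1, n2),
        extra={"noncentrality": float(ncp)},
    )
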