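"""Subject clustering and the between/within-group statistical battery.

Subjects are clustered on their response profiles (cell means in canonical
cell order) with centroid-linkage agglomerative clustering.  Effect sizes
follow the printed conventions: paired Cohen's d = t / sqrt(n), independent
d = t * sqrt(1/n1 + 1/n2), both with noncentral-t pivot confidence intervals.
Fiducial limits interpret the effect's post-data distribution as
mean_diff + se * T(df) (Lecoutre-style t-based fiducial distribution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.cluster import hierarchy


@dataclass
class ClusterSolution:
    linkage: np.ndarray  # scipy linkage matrix (centroid method)
    assignments: pd.Series  # subject -> cluster label (1..k)
    k: int

    @property
    def sizes(self) -> dict[int, int]:
        return self.assignments.value_counts().sort_index().to_dict()

    def members(self, label: int) -> list[str]:
        return sorted(self.assignments[self.assignments == label].index)

    def merge_heights(self) -> np.ndarray:
        """Agglomeration heights, ascending — supports the choice of k."""
        return self.linkage[:, 2]


def subject_profiles(table) -> pd.DataFrame:
    """Subject x cell matrix of means in the design's canonical cell order."""
    return table.wide()


def cluster_subjects(
    profiles: pd.DataFrame, k: int, standardize: bool = False
) -> ClusterSolution:
    """Centroid-linkage agglomerative clustering of subject profiles, cut at k.

    Deterministic given the profiles (ties resolved by scipy's stable order,
    i.e. lowest index first).  ``standardize`` z-scores each cell across
    subjects before clustering (off by default).
    """
    if profiles.isna().any().any():
        raise ValueError("profiles contain missing cells")
    n = len(profiles)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    X = profiles.to_numpy(float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X, method="centroid")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterSolution(
        linkage=Z, assignments=pd.Series(labels, index=profiles.index, name="cluster"), k=k
    )


# -- effect sizes ------------------------------------------------------------


@dataclass
class EffectSize:
    d: float
    ci_low: float
    ci_high: float
    design: str  # "paired" | "independent"
    n: int
    n2: int | None = None
    level: float = 0.95


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


@dataclass
class FiducialResult:
    limit: float
    level: float
    direction: str  # "two_sided_magnitude" | "one_sided_lower"


def cohen_d_paired(t_stat: float, n: int) -> float:
    """d = t / sqrt(n) for a paired/one-sample design with n pairs."""
    if n < 2:
        raise ValueError("paired design needs n >= 2")
    return t_stat / np.sqrt(n)


def cohen_d_independent(t_stat: float, n1: int, n2: int) -> float:
    """d = t * sqrt(1/n1 + 1/n2) for two independent groups."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    return t_stat * np.sqrt(1.0 / n1 + 1.0 / n2)


def _nct_ci(t_obs: float, df: float, level: float) -> tuple[float, float]:
    """Noncentrality-parameter CI by inverting the noncentral-t CDF."""
    alpha = (1.0 - level) / 2.0
    hi_bracket = abs(t_obs) * 5 + 50

    def cdf(nc):
        v = stats.nct.cdf(t_obs, df, nc)
        if np.isnan(v):  # extreme-nc underflow; cdf is decreasing in nc
            return 0.0 if nc > t_obs else 1.0
        return v

    def solve(target):
        return optimize.brentq(
            lambda nc: cdf(nc) - target, -hi_bracket, hi_bracket, xtol=1e-10
        )

    return solve(1.0 - alpha), solve(alpha)


def d_confidence_interval(
    d: float, design: str, n: int, n2: int | None = None, level: float = 0.95
) -> tuple[float, float]:
    """CI for Cohen's d via the noncentral-t pivot on the observed t."""
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    if design == "paired":
        scale = 1.0 / np.sqrt(n)
        df = n - 1
    elif design == "independent":
        if n2 is None:
            raise ValueError("independent design needs n2")
        scale = np.sqrt(1.0 / n + 1.0 / n2)
        df = n + n2 - 2
    else:
        raise ValueError(f"unknown design {design!r}")
    t_obs = d / scale
    lo, hi = _nct_ci(t_obs, df, level)
    return lo * scale, hi * scale


def effect_size(t_stat: float, design: str, n: int, n2: int | None = None,
                level: float = 0.95) -> EffectSize:
    """Cohen's d (from the t statistic) with its noncentral-t CI."""
    if design == "paired":
        d = cohen_d_paired(t_stat, n)
    else:
        d = cohen_d_independent(t_stat, n, n2)
    lo, hi = d_confidence_interval(d, design, n, n2, level)
    return EffectSize(d=float(d), ci_low=float(lo), ci_high=float(hi),
                      design=design, n=n, n2=n2, level=level)


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test; zero-variance differences flagged degenerate."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    d = x - y
    if len(d) < 2:
        raise ValueError("paired t needs n >= 2")
    if np.isclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(0.0, len(d) - 1, 1.0, degenerate=True)
        return TTestResult(float("inf") if d.mean() > 0 else float("-inf"),
                           len(d) - 1, 0.0, degenerate=True)
    t, p = stats.ttest_rel(x, y)
    return TTestResult(float(t), float(len(d) - 1), float(p))


def independent_t(x, y) -> TTestResult:
    """Two-sided pooled-variance t-test for independent samples."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("independent t needs n >= 2 per group")
    if np.isclose(x.std(ddof=1), 0.0) and np.isclose(y.std(ddof=1), 0.0):
        df = len(x) + len(y) - 2
        if np.isclose(x.mean(), y.mean()):
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(float("inf") if x.mean() > y.mean() else float("-inf"),
                           df, 0.0, degenerate=True)
    t, p = stats.ttest_ind(x, y)
    return TTestResult(float(t), float(len(x) + len(y) - 2), float(p))


def fiducial_limit(
    mean_diff: float, se: float, df: float, level: float = 0.95,
    direction: str = "two_sided_magnitude",
) -> FiducialResult:
    """Fiducial bound on the effect delta ~ mean_diff + se * T(df).

    ``two_sided_magnitude``: smallest L with P(|delta| < L) = level — "the
    effect is smaller than L in absolute value with `level` guarantee".
    ``one_sided_lower``: L with P(delta > L) = level — "the effect is greater
    than L with `level` guarantee".
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if direction == "one_sided_lower":
        L = mean_diff + se * stats.t.ppf(1.0 - level, df)
        return FiducialResult(float(L), level, direction)
    if direction != "two_sided_magnitude":
        raise ValueError(f"unknown direction {direction!r}")

    def coverage(L: float) -> float:
        return stats.t.cdf((L - mean_diff) / se, df) - stats.t.cdf((-L - mean_diff) / se, df)

    # coverage is 0 at L=0 and increases to 1; bracket then invert
    hi = abs(mean_diff) + se * (stats.t.ppf(0.5 + level / 2, df) + 1.0)
    while coverage(hi) < level:
        hi *= 2.0
    L = optimize.brentq(lambda v: coverage(v) - level, 0.0, hi, xtol=1e-10)
    return FiducialResult(float(L), level, direction)


def bonferroni_threshold(alpha: float, family_size: int) -> float:
    """Per-test threshold alpha / m; the family size is always explicit."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return alpha / family_size
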