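"""Repeated-measures ANOVA for balanced fully-within designs.

Implemented via orthonormal within-subject contrasts: for an effect with
contrast matrix M (columns orthonormal, spanning the effect subspace of the
cell dimension), the per-subject scores z_s = M' y_s give

    SS_effect = n * ||mean(z)||^2,      df1 = d
    SS_error  = sum_s ||z_s - mean(z)||^2,  df2 = d * (n - 1)

identical to the classical partitioning (effect x subject interaction as the
error term).  The Greenhouse-Geisser epsilon for the effect is
tr(S)^2 / (d * tr(S^2)) with S the sample covariance of the scores — the
standard sphericity correction; corrected p uses F at (eps*df1, eps*df2).
Huynh-Feldt is deliberately not implemented.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    epsilon: float
    p_uncorrected: float
    p_gg: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    degenerate: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return (not self.degenerate) and self.p_gg < alpha

    def marginal(self, alpha: float = 0.05, band: float = 0.01) -> bool:
        """p_gg within +/- band of alpha — reported, never auto-decided."""
        return abs(self.p_gg - alpha) <= band


@dataclass
class TrendResult:
    F: float
    df1: float
    df2: float
    p: float
    r_sq: float
    slope: float
    intercept: float


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta^2 from an F ratio: F*df1 / (F*df1 + df2)."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be nonnegative")
    return F * df1 / (F * df1 + df2)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) matrix with orthonormal columns, each orthogonal to the mean."""
    # QR of centered identity; drop the constant direction
    q, _ = np.linalg.qr(np.eye(k) - 1.0 / k)
    return q[:, : k - 1]


def _pivot_within(data: pd.DataFrame, dv: str, within: list[str], subject: str):
    """Subject x cell matrix in factor-product column order; checks balance."""
    levels = {f: list(pd.unique(data[f])) for f in within}
    for f in within:
        if len(levels[f]) < 2:
            raise ValueError(f"within factor {f!r} has fewer than 2 levels")
    pivot = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    cols = list(itertools.product(*(levels[f] for f in within)))
    if len(within) == 1:
        cols = [c[0] for c in cols]
    try:
        pivot = pivot[cols]
    except KeyError:
        raise ValueError("incomplete design: some subject lacks a cell") from None
    if pivot.isna().any().any():
        raise ValueError("incomplete design: some subject lacks a cell")
    if len(pivot) < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")
    return pivot.to_numpy(float), levels


def rm_anova(
    data: pd.DataFrame,
    dv: str = "mean",
    within: list[str] | str = ("audio", "tactile"),
    subject: str = "subject",
) -> list[AnovaResult]:
    """Main effects and interactions for 1 or 2 within-subject factors.

    ``data`` is long format (one row per subject x cell, e.g. cell means).
    Returns one :class:`AnovaResult` per effect, GG-corrected.
    """
    within = [within] if isinstance(within, str) else list(within)
    y, levels = _pivot_within(data, dv, within, subject)
    n = y.shape[0]

    contrasts = {f: _orthonormal_contrasts(len(levels[f])) for f in within}
    means = {f: np.full((len(levels[f]), 1), 1.0 / np.sqrt(len(levels[f]))) for f in within}

    results = []
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            m = np.ones((1, 1))
            for f in within:
                m = np.kron(m, contrasts[f] if f in combo else means[f])
            z = y @ m  # n x d scores
            d = z.shape[1]
            zbar = z.mean(axis=0)
            ss_eff = n * float(zbar @ zbar)
            dev = z - zbar
            ss_err = float((dev * dev).sum())
            df1, df2 = float(d), float(d * (n - 1))
            degenerate = ss_err <= 1e-12 * max(1.0, ss_eff)
            if degenerate:
                F = float("inf") if ss_eff > 1e-12 else 0.0
                eps, p, p_gg = 1.0, 0.0 if ss_eff > 1e-12 else 1.0, 0.0 if ss_eff > 1e-12 else 1.0
                eta = 1.0 if ss_eff > 1e-12 else 0.0
            else:
                F = (ss_eff / df1) / (ss_err / df2)
                S = dev.T @ dev / (n - 1)
                tr, tr2 = float(np.trace(S)), float(np.trace(S @ S))
                eps = 1.0 if d == 1 else min(1.0, max(tr * tr / (d * tr2), 1.0 / d))
                p = float(stats.f.sf(F, df1, df2))
                p_gg = float(stats.f.sf(F, eps * df1, eps * df2))
                eta = partial_eta_sq(F, df1, df2)
            results.append(
                AnovaResult(
                    effect=" * ".join(combo), F=float(F), df1=df1, df2=df2,
                    epsilon=float(eps), p_uncorrected=p, p_gg=p_gg,
                    partial_eta_sq=eta, ss_effect=ss_eff, ss_error=ss_err,
                    degenerate=degenerate,
                )
            )
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    """Exportable table: effect, F, df1, df2, epsilon, p_gg, eta_p2."""
    return pd.DataFrame(
        {
            "effect": [r.effect for r in results],
            "F": [r.F for r in results],
            "df1": [r.df1 for r in results],
            "df2": [r.df2 for r in results],
            "epsilon": [r.epsilon for r in results],
            "p_gg": [r.p_gg for r in results],
            "eta_p2": [r.partial_eta_sq for r in results],
        }
    )


def linear_trend(level_means: pd.DataFrame, predictor: np.ndarray | list) -> TrendResult:
    """Within-subject linear-contrast F plus a least-squares line on group means.

    ``level_means`` is subjects x ordered levels; ``predictor`` gives the
    abscissa value of each level (ordinals or physical units).  The F tests
    the linear contrast across subjects; slope/intercept/R^2 describe the
    group-level line in rating units per predictor unit.
    """
    x = np.asarray(predictor, float)
    y = level_means.to_numpy(float)
    if y.shape[1] < 3:
        raise ValueError("linear trend needs at least 3 ordered levels")
    if y.shape[1] != len(x):
        raise ValueError("predictor length must match number of levels")
    c = x - x.mean()
    c = c / np.sqrt(c @ c)
    scores = y @ c
    n = len(scores)
    sbar = scores.mean()
    ss_eff = n * sbar**2
    ss_err = float(((scores - sbar) ** 2).sum())
    if ss_err <= 1e-12 * max(1.0, ss_eff):
        F, p = (float("inf"), 0.0) if ss_eff > 1e-12 else (0.0, 1.0)
    else:
        F = ss_eff / (ss_err / (n - 1))
        p = float(stats.f.sf(F, 1, n - 1))
    gm = y.mean(axis=0)
    slope, intercept, r, _, _ = stats.linregress(x, gm)
    return TrendResult(
        F=float(F), df1=1.0, df2=float(n - 1), p=p,
        r_sq=float(r**2), slope=float(slope), intercept=float(intercept),
    )


@dataclass
class PairwiseComparison:
    level_a: str
    level_b: str
    t: float
    df: float
    p: float
    p_threshold: float  # Bonferroni-corrected alpha for this family
    significant: bool


def pairwise_posthoc(
    level_means: pd.DataFrame, alpha: float = 0.05, correction: str = "bonferroni"
) -> list[PairwiseComparison]:
    """All pairwise paired t-tests between levels, Bonferroni-corrected.

    The corrected threshold is alpha / number-of-pairs (5 levels -> alpha/10).
    """
    cols = list(level_means.columns)
    if len(cols) < 2:
        raise ValueError("post hoc comparisons need at least 2 levels")
    pairs = list(itertools.combinations(cols, 2))
    thr = alpha / len(pairs) if correction == "bonferroni" else alpha
    out = []
    for a, b in pairs:
        xa, xb = level_means[a].to_numpy(float), level_means[b].to_numpy(float)
        d = xa - xb
        if np.allclose(d.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(d, 0.0) else (float("inf"), 0.0)
        else:
            t, p = stats.ttest_rel(xa, xb)
        out.append(
            PairwiseComparison(str(a), str(b), float(t), float(len(d) - 1),
                               float(p), thr, bool(p < thr))
        )
    return out
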