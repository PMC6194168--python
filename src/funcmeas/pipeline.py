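"""End-to-end analysis pipeline mirroring the study's reporting order.

Stages: cell means -> unimodal ANOVAs (+ trend, post hocs) -> subjective
values and integration graphs -> bimodal ANOVAs, parallelism and crossover
diagnosis -> subject clustering -> per-cluster averaging-model fits with
residual goodness of fit -> modality-importance statistics (paired and
between-cluster t-tests, Cohen's d with CIs, fiducial limits).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import AnovaResult, anova_table, linear_trend, pairwise_posthoc, rm_anova
from .averaging import AveragingResults, fit_cohort, fit_table, residual_gof
from .design import ABSENT, CellMeansTable, StimulusDesign, TrialRecord, cell_means
from .diagnosis import diagnose_cohort
from .population import (
    ClusterSolution,
    cluster_subjects,
    effect_size,
    fiducial_limit,
    independent_t,
    paired_t,
    subject_profiles,
)
from .valuation import export_graph, integration_graph, marginal_psi


@dataclass
class RunConfig:
    """Analysis options; every threshold the pipeline uses is surfaced here."""

    alpha: float = 0.05
    psi_basis: str = "with_unimodal"
    crossover_tol: float = 1.0
    k_clusters: int = 2
    w0: float = 1.0
    fit_restarts: int = 20
    seed: int = 0
    min_cluster_size: int = 2

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        if self.crossover_tol < 0:
            raise ValueError("crossover_tol must be nonnegative")


@dataclass
class ClusterReport:
    label: int
    subjects: list[str]
    verdict: str
    parallelism: str
    crossover: str
    fits: dict[str, AveragingResults]
    gof: dict[str, list[AnovaResult]]
    gof_pass: bool


@dataclass
class RunReport:
    config: RunConfig
    version: str
    n_subjects: int
    psi: dict[str, dict[str, float]]
    unimodal_anovas: dict[str, list[AnovaResult]]
    trend: dict
    posthoc_audio: list
    bimodal_anovas: dict[str, list[AnovaResult]]
    verdict: str
    parallelism: str
    crossover: str
    clusters: ClusterSolution
    cluster_reports: list[ClusterReport]
    importance_stats: dict
    timings: dict[str, float] = field(default_factory=dict)
    graphs: dict = field(default_factory=dict)
    table: CellMeansTable | None = None

    def summary_dict(self) -> dict:
        return {
            "version": self.version,
            "config": dataclasses.asdict(self.config),
            "n_subjects": self.n_subjects,
            "psi": self.psi,
            "verdict": self.verdict,
            "parallelism": self.parallelism,
            "crossover": self.crossover,
            "cluster_sizes": {int(k): int(v) for k, v in self.clusters.sizes.items()},
            "clusters": [
                {
                    "label": c.label,
                    "n": len(c.subjects),
                    "verdict": c.verdict,
                    "gof_pass": c.gof_pass,
                }
                for c in self.cluster_reports
            ],
            "importance_stats": self.importance_stats,
            "timings": self.timings,
        }

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, results in {**self.unimodal_anovas, **self.bimodal_anovas}.items():
            anova_table(results).to_csv(out / f"anova_{name}.csv", index=False)
        for name, graph in self.graphs.items():
            export_graph(graph, out / f"graph_{name}.csv")
        self.clusters.assignments.to_csv(out / "clusters.csv")
        for c in self.cluster_reports:
            fit_table(c.fits).to_csv(out / f"fits_cluster{c.label}.csv", index=False)
        pd.DataFrame(self.psi).to_csv(out / "psi.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=1, default=_jsonable)


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)


def _unimodal_level_means(table: CellMeansTable, factor: str) -> pd.DataFrame:
    """Subject x level means over the factor's unimodal cells, in design order."""
    m = table.means
    if factor == "audio":
        sub = m[(m["tactile"] == ABSENT)]
        order = table.design.audio_codes
        pivot = sub.pivot_table(index="subject", columns="audio", values="mean")
    else:
        sub = m[(m["audio"] == ABSENT)]
        order = table.design.tactile_codes
        pivot = sub.pivot_table(index="subject", columns="tactile", values="mean")
    return pivot[order]


def analyze(
    records: list[TrialRecord], design: StimulusDesign, config: RunConfig | None = None
) -> RunReport:
    """Run the full pipeline on validated trial records."""
    config = config or RunConfig()
    config.validate()
    if not records:
        raise ValueError("no trial records to analyze")
    timings: dict[str, float] = {}

    def clock(name, fn):
        t0 = time.perf_counter()
        out = fn()
        timings[name] = round(time.perf_counter() - t0, 4)
        return out

    table = clock("cell_means", lambda: cell_means(records, design))

    # unimodal ANOVAs, post hocs, linear trend over the audio morph continuum
    def unimodal():
        out = {}
        for factor in ("audio", "tactile"):
            lm = _unimodal_level_means(table, factor)
            out[f"unimodal_{factor}"] = rm_anova(
                lm.reset_index().melt(id_vars="subject", var_name=factor, value_name="mean"),
                dv="mean", within=[factor],
            )
        return out

    unimodal_anovas = clock("unimodal_anova", unimodal)
    audio_lm = _unimodal_level_means(table, "audio")
    morph = [l.ordinal for l in design.audio_levels]
    trend = clock("trend", lambda: linear_trend(audio_lm, morph))
    posthoc = clock("posthoc", lambda: pairwise_posthoc(audio_lm, alpha=config.alpha))

    psi = {
        f: marginal_psi(table, f, basis=config.psi_basis).values
        for f in ("audio", "tactile")
    }
    graphs = {
        "audio_abscissa": integration_graph(table, "audio", "psi_scaled"),
        "tactile_abscissa": integration_graph(table, "tactile", "psi_scaled"),
    }

    # bimodal ANOVAs in the study's two factorial views + parallelism/crossover
    def bimodal():
        m = table.means
        audio_view = m[m["audio"] != ABSENT]  # 5 x (nt + 1) incl. no-TS level
        tactile_view = m[m["tactile"] != ABSENT]
        return {
            "audio_view": rm_anova(audio_view, within=["audio", "tactile"]),
            "tactile_view": rm_anova(tactile_view, within=["audio", "tactile"]),
        }

    bimodal_anovas = clock("bimodal_anova", bimodal)
    verdict, interaction, cross = clock(
        "diagnosis",
        lambda: diagnose_cohort(table, alpha=config.alpha, crossover_tol=config.crossover_tol),
    )
    bimodal_anovas["parallelism"] = [interaction]

    profiles = subject_profiles(table)
    clusters = clock(
        "clustering", lambda: cluster_subjects(profiles, k=min(config.k_clusters, len(profiles)))
    )

    # per-cluster diagnosis, averaging-model fits and residual GOF
    def per_cluster():
        reports = []
        for label in sorted(clusters.sizes):
            members = clusters.members(label)
            if len(members) < config.min_cluster_size:
                continue
            sub_table = CellMeansTable(
                design=design, means=table.means[table.means["subject"].isin(members)]
            )
            v, _, _ = diagnose_cohort(sub_table, alpha=config.alpha,
                                      crossover_tol=config.crossover_tol)
            fits = fit_cohort(sub_table, variant="equal", w0=config.w0,
                              n_restarts=config.fit_restarts, seed=config.seed)
            gof = residual_gof(fits, sub_table)
            gof_pass = all(
                not r.significant(config.alpha) for rs in gof.values() for r in rs
            )
            reports.append(
                ClusterReport(label, members, v.suggested_rule, v.parallelism,
                              v.crossover, fits, gof, gof_pass)
            )
        return reports

    cluster_reports = clock("cluster_fits", per_cluster)
    importance_stats = clock(
        "importance", lambda: _importance_stats(cluster_reports, config)
    )

    return RunReport(
        config=config, version=__version__, n_subjects=len(table.subjects),
        psi=psi, unimodal_anovas=unimodal_anovas,
        trend=dataclasses.asdict(trend), posthoc_audio=posthoc,
        bimodal_anovas=bimodal_anovas,
        verdict=verdict.suggested_rule, parallelism=verdict.parallelism,
        crossover=verdict.crossover,
        clusters=clusters, cluster_reports=cluster_reports,
        importance_stats=importance_stats, timings=timings, graphs=graphs,
        table=table,
    )


def _importance_stats(cluster_reports: list[ClusterReport], config: RunConfig) -> dict:
    """Weight comparisons within and between clusters.

    Within each cluster: are the audio and tactile weights nonzero (one-sample
    t), and do they differ (paired t)?  Between the two largest clusters:
    independent t on normalized importances.  Fiducial limits bound the
    population weight difference: one-sided lower when the observed difference
    is clear, two-sided magnitude when it is not.
    """
    out: dict = {"within": {}, "between": None}
    for c in cluster_reports:
        wa = np.array([r.params.w_audio for r in c.fits.values()], float)
        wt = np.array([r.params.w_tactile for r in c.fits.values()], float)
        n = len(wa)
        zeros = np.zeros(n)
        t_wa, t_wt = paired_t(wa, zeros), paired_t(wt, zeros)
        t_diff = paired_t(wa, wt)
        diff = wa - wt
        se = diff.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan")
        entry = {
            "n": n,
            "mean_w_audio": float(wa.mean()),
            "mean_w_tactile": float(wt.mean()),
            "mean_diff": float(diff.mean()),
            "t_audio_vs_zero": dataclasses.asdict(t_wa),
            "t_tactile_vs_zero": dataclasses.asdict(t_wt),
            "t_audio_vs_tactile": dataclasses.asdict(t_diff),
        }
        if n > 1 and not t_wa.degenerate:
            entry["d_audio_vs_zero"] = dataclasses.asdict(effect_size(t_wa.t, "paired", n))
            entry["d_tactile_vs_zero"] = dataclasses.asdict(effect_size(t_wt.t, "paired", n))
        if n > 1 and se > 0:
            direction = (
                "one_sided_lower"
                if not t_diff.degenerate and t_diff.p < config.alpha
                else "two_sided_magnitude"
            )
            entry["fiducial"] = dataclasses.asdict(
                fiducial_limit(float(diff.mean()), float(se), n - 1,
                               level=0.95, direction=direction)
            )
        out["within"][c.label] = entry

    big = sorted(cluster_reports, key=lambda c: -len(c.subjects))[:2]
    if len(big) == 2 and all(len(c.subjects) >= 2 for c in big):
        imp = {
            c.label: {
                "audio": [r.importance().factor("audio") for r in c.fits.values()],
                "tactile": [r.importance().factor("tactile") for r in c.fits.values()],
            }
            for c in big
        }
        a, b = big[0].label, big[1].label
        between = {}
        for modality in ("audio", "tactile"):
            t = independent_t(imp[a][modality], imp[b][modality])
            n1, n2 = len(imp[a][modality]), len(imp[b][modality])
            between[modality] = {
                "clusters": [a, b],
                "t": dataclasses.asdict(t),
                "d": dataclasses.asdict(effect_size(t.t, "independent", n1, n2))
                if not t.degenerate else None,
            }
        out["between"] = between
    return out


# -- recovery harness ---------------------------------------------------------


def recover(sim_config, fit_restarts: int = 20, fit_seed: int = 0) -> dict:
    """Simulate -> fit -> compare against ground truth.

    Returns per-subject weight-ratio and scale-value errors plus summary
    quantiles.  Deterministic given the simulation config and fit seed.
    """
    from .simulate import simulate_cohort

    cohort = simulate_cohort(sim_config)
    table = cell_means(cohort.records, sim_config.design)
    fits = fit_cohort(table, variant="equal", n_restarts=fit_restarts, seed=fit_seed)

    rows = []
    for subject, res in fits.items():
        truth = cohort.truth[subject]
        true_ratio = float(np.mean(np.atleast_1d(truth.weight_audio))) / float(
            np.mean(np.atleast_1d(truth.weight_tactile))
        )
        fitted_ratio = res.weight_ratio
        scale_err = np.abs(
            np.r_[np.array(res.params.s_audio) - np.array(truth.scale_audio),
                  np.array(res.params.s_tactile) - np.array(truth.scale_tactile)]
        )
        rows.append(
            {
                "subject": subject,
                "true_ratio": true_ratio,
                "fitted_ratio": fitted_ratio,
                "ratio_rel_error": abs(fitted_ratio - true_ratio) / true_ratio,
                "max_scale_abs_error": float(scale_err.max()),
                "sse": res.sse,
            }
        )
    df = pd.DataFrame(rows)
    return {
        "per_subject": df,
        "median_ratio_rel_error": float(df["ratio_rel_error"].median()),
        "median_max_scale_abs_error": float(df["max_scale_abs_error"].median()),
        "n_subjects": len(df),
    }
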