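"""Integration-rule diagnosis from parallelism and crossover signatures.

The decision table of functional measurement: a non-significant bimodal
interaction (parallelism) together with the unimodal line crossing the
bimodal fan indicates averaging; parallelism without a crossover indicates
adding; a significant interaction leaves the verdict inconclusive (with
differential weighting flagged as the likely cause).
"""

from __future__ import annotations

from dataclasses import dataclass

from .anova import AnovaResult, rm_anova
from .design import ABSENT, CellMeansTable
from .valuation import CrossoverResult, crossover_index, integration_graph


@dataclass
class RuleVerdict:
    parallelism: str  # "supported" | "rejected"
    crossover: str  # "present" | "absent"
    suggested_rule: str  # "averaging" | "adding" | "inconclusive"


def parallelism_test(
    table: CellMeansTable, alpha: float = 0.05
) -> tuple[AnovaResult, str]:
    """Interaction ANOVA on the bimodal cells only (unimodal levels dropped).

    Parallelism is supported iff the GG-corrected interaction p >= alpha.
    """
    bi = table.means[(table.means["audio"] != ABSENT) & (table.means["tactile"] != ABSENT)]
    results = rm_anova(bi, dv="mean", within=["audio", "tactile"])
    interaction = next(r for r in results if "*" in r.effect)
    verdict = "supported" if interaction.p_gg >= alpha else "rejected"
    return interaction, verdict


def diagnose_rule(parallelism_verdict: str, crossover_verdict: str) -> RuleVerdict:
    """Apply the functional-measurement decision table."""
    if parallelism_verdict not in ("supported", "rejected"):
        raise ValueError(f"unknown parallelism verdict {parallelism_verdict!r}")
    if crossover_verdict not in ("present", "absent"):
        raise ValueError(f"unknown crossover verdict {crossover_verdict!r}")
    if parallelism_verdict == "rejected":
        rule = "inconclusive"
    elif crossover_verdict == "present":
        rule = "averaging"
    else:
        rule = "adding"
    return RuleVerdict(parallelism_verdict, crossover_verdict, rule)


def diagnose_cohort(
    table: CellMeansTable,
    alpha: float = 0.05,
    crossover_tol: float = 1.0,
    abscissa_factor: str = "audio",
) -> tuple[RuleVerdict, AnovaResult, CrossoverResult]:
    """Full diagnosis of a cell-means table: parallelism ANOVA + crossover scan."""
    interaction, par = parallelism_test(table, alpha=alpha)
    graph = integration_graph(table, abscissa_factor=abscissa_factor, abscissa_mode="psi_scaled")
    cross = crossover_index(graph, tol=crossover_tol)
    verdict = diagnose_rule(par, "present" if cross.verdict == "crossover" else "absent")
    return verdict, interaction, cross
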