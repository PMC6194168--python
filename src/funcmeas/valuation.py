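"""Subjective-value (Psi) estimation and integration graphs.

Functional measurement approximates the subjective value of each stimulus
level by the marginal mean of the responses to every cell containing that
level.  Plotting one line per level of the second factor across the first
factor's levels — the integration graph — exposes the integration rule:
parallel bimodal lines indicate an adding-type rule, and the unimodal line
crossing the bimodal fan singles out averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ABSENT, CellMeansTable, DesignError


@dataclass
class PsiEstimates:
    """Marginal-mean subjective values for the non-absent levels of one factor."""

    factor: str
    values: dict[str, float]  # level code -> Psi, in rating units
    basis: str  # "with_unimodal" | "bimodal_only"

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=f"psi_{self.factor}")


@dataclass
class IntegrationGraph:
    """Tidy line data for a factorial plot.

    One row per (line, abscissa level): columns line, audio, tactile,
    abscissa_level, x, mean_ev.  Lines are the levels of the non-abscissa
    factor; the unimodal line (other factor ABSENT) is labelled "unimodal".
    """

    abscissa_factor: str
    abscissa_mode: str  # "physical_order" | "psi_scaled"
    data: pd.DataFrame

    def line(self, name: str) -> pd.DataFrame:
        return self.data[self.data["line"] == name].sort_values("x")

    @property
    def bimodal_lines(self) -> list[str]:
        return sorted(set(self.data["line"]) - {"unimodal"})

    @property
    def has_unimodal_line(self) -> bool:
        return (self.data["line"] == "unimodal").any()


def marginal_psi(
    table: CellMeansTable, factor: str, basis: str = "with_unimodal"
) -> PsiEstimates:
    """Psi(level) = unweighted mean of the group cell means containing the level.

    Default basis averages the bimodal cells plus the factor's own unimodal
    cell, matching the study's worked example (Psi_min = mean of the no-TS
    cell -60 with the three bimodal cells -40.4, -51.8, -70 = -55.55).
    """
    if factor not in ("audio", "tactile"):
        raise ValueError(f"unknown factor {factor!r}")
    if basis not in ("with_unimodal", "bimodal_only"):
        raise ValueError(f"unknown basis {basis!r}")
    own, other = ("audio", "tactile") if factor == "audio" else ("tactile", "audio")
    gm = table.group_means()
    codes = table.design.audio_codes if factor == "audio" else table.design.tactile_codes

    values = {}
    for code in codes:
        rows = gm[(gm[own] == code) & (gm[other] != ABSENT)]
        cells = list(rows["mean"])
        if basis == "with_unimodal":
            uni = gm[(gm[own] == code) & (gm[other] == ABSENT)]
            if uni.empty:
                raise DesignError(f"no unimodal cell for {code}; use basis='bimodal_only'")
            cells += list(uni["mean"])
        n_expected = len(table.design.tactile_codes if factor == "audio" else table.design.audio_codes)
        if len(rows) != n_expected:
            raise DesignError(f"incomplete bimodal cells for level {code}")
        values[code] = float(np.mean(cells))
    return PsiEstimates(factor=factor, values=values, basis=basis)


def integration_graph(
    table: CellMeansTable, abscissa_factor: str = "audio", abscissa_mode: str = "psi_scaled"
) -> IntegrationGraph:
    """Group-level factorial plot data (lines = levels of the other factor).

    ``psi_scaled`` places abscissa points at the marginal-mean Psi of each
    level; ``physical_order`` uses the design ordinals.
    """
    if abscissa_mode not in ("physical_order", "psi_scaled"):
        raise ValueError(f"unknown abscissa_mode {abscissa_mode!r}")
    own = abscissa_factor
    other = "tactile" if own == "audio" else "audio"
    design = table.design
    abscissa_codes = design.audio_codes if own == "audio" else design.tactile_codes
    line_codes = design.tactile_codes if own == "audio" else design.audio_codes

    if abscissa_mode == "psi_scaled":
        psi = marginal_psi(table, own)
        xs = {c: psi.values[c] for c in abscissa_codes}
    else:
        ords = design.audio_levels if own == "audio" else design.tactile_levels
        xs = {l.code: float(l.ordinal) for l in ords}

    gm = table.group_means()
    lut = {(r.audio, r.tactile): r.mean for r in gm.itertuples(index=False)}

    rows = []
    has_uni = design.unimodal_audio if own == "audio" else design.unimodal_tactile
    lines = list(line_codes) + ([ABSENT] if has_uni else [])
    for lc in lines:
        for ac in abscissa_codes:
            cell = (ac, lc) if own == "audio" else (lc, ac)
            if cell not in lut:
                raise DesignError(f"missing group mean for cell {cell}")
            rows.append(
                {
                    "line": "unimodal" if lc == ABSENT else lc,
                    "audio": cell[0],
                    "tactile": cell[1],
                    "abscissa_level": ac,
                    "x": xs[ac],
                    "mean_ev": lut[cell],
                }
            )
    return IntegrationGraph(own, abscissa_mode, pd.DataFrame(rows))


@dataclass
class CrossoverResult:
    sign_changes: int  # total over bimodal lines
    per_line: dict[str, int]
    verdict: str  # "crossover" | "no-crossover"


def crossover_index(graph: IntegrationGraph, tol: float = 1.0) -> CrossoverResult:
    """Count sign changes of (unimodal line - each bimodal line) along the abscissa.

    Differences within ``tol`` rating units of zero are treated as ties and
    skipped, absorbing noise.  A line counts as crossed only when its clear
    signs change exactly once — a single monotone crossing, which is the
    averaging signature; alternating signs (two or more changes) are noise
    around zero, not a crossover.  Verdict is "crossover" when any bimodal
    line shows such a clean crossing.
    """
    if not graph.has_unimodal_line:
        raise DesignError("graph has no unimodal line; crossover is undefined")
    uni = graph.line("unimodal")
    if len(uni) < 2:
        raise DesignError("crossover undefined with fewer than two abscissa points")
    per_line: dict[str, int] = {}
    for name in graph.bimodal_lines:
        bi = graph.line(name)
        diff = uni["mean_ev"].to_numpy() - bi["mean_ev"].to_numpy()
        signs = [np.sign(d) for d in diff if abs(d) > tol]
        per_line[name] = int(sum(s1 != s2 for s1, s2 in zip(signs, signs[1:])))
    total = sum(per_line.values())
    crossed = any(c == 1 for c in per_line.values())
    return CrossoverResult(
        sign_changes=total,
        per_line=per_line,
        verdict="crossover" if crossed else "no-crossover",
    )


def export_graph(graph: IntegrationGraph, path) -> None:
    """Tidy CSV (line, abscissa_level, psi_coordinate, mean_ev) for plotting."""
    out = graph.data.rename(columns={"x": "psi_coordinate"})
    out[["line", "abscissa_level", "psi_coordinate", "mean_ev"]].to_csv(path, index=False)
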