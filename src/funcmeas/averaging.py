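"""The averaging model of information integration: fitting and diagnostics.

The integrated response to a cell is a weighted mean of the active scale
values together with an initial state (w0, s0):

    R = (w0*s0 + sum_i w_i * s_i) / (w0 + sum_i w_i)

where the sum runs over the factors present in the cell.  Unimodal cells drop
the absent factor from numerator and denominator, which produces the set-size
effect and is what makes the weights identifiable at all: on bimodal cells
alone the denominator is constant and the model collapses to an additive one.

Weights are ratio-scale quantities — multiplying every weight (including w0)
by a positive constant changes nothing — so the fit pins w0 to a constant
(1 by default) and reports the other weights relative to it.  Weight ratios
and normalized importances are invariant to that choice.

Fitting exploits the model's conditional linearity: with the weights held
fixed, the scale values (s0, s_audio, s_tactile) enter linearly, so the
optimizer searches weight space only (2 dimensions for the equal-weight
model, one per level for the differential variant) with an exact linear
least-squares solve inside.  Multi-start from a seeded Latin hypercube guards
against local minima in the weight landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .anova import AnovaResult, rm_anova
from .design import ABSENT, CellMeansTable, DesignError, StimulusDesign

#: sse below this is treated as an exact fit when forming the Gaussian BIC,
#: so model selection on noiseless data is decided by parameter count alone
_SSE_FLOOR = 1e-8


@dataclass
class AveragingParams:
    """Parameters of the averaging model under an identification constraint.

    ``w_audio`` / ``w_tactile`` are scalars for the equal-weight model (EAM)
    and per-level vectors for the differential-weight model (DAM).
    """

    w0: float
    s0: float
    w_audio: float | list[float]
    w_tactile: float | list[float]
    s_audio: list[float]
    s_tactile: list[float]
    identification: str = "w0=1"

    def weight_for(self, factor: str, level_index: int) -> float:
        w = self.w_audio if factor == "audio" else self.w_tactile
        return float(w[level_index]) if isinstance(w, (list, tuple, np.ndarray)) else float(w)

    def weight_list(self, factor: str, n_levels: int) -> list[float]:
        w = self.w_audio if factor == "audio" else self.w_tactile
        if isinstance(w, (list, tuple, np.ndarray)):
            return [float(v) for v in w]
        return [float(w)] * n_levels


def predict_eam(params: AveragingParams, cell: tuple[str, str], design: StimulusDesign) -> float:
    """Model prediction for one cell; absent factors drop from both sums."""
    audio, tactile = cell
    if not design.is_cell(audio, tactile):
        raise DesignError(f"({audio!r}, {tactile!r}) is not a cell of the design")
    num = params.w0 * params.s0
    den = params.w0
    if audio != ABSENT:
        i = design.audio_codes.index(audio)
        w = params.weight_for("audio", i)
        num += w * params.s_audio[i]
        den += w
    if tactile != ABSENT:
        j = design.tactile_codes.index(tactile)
        w = params.weight_for("tactile", j)
        num += w * params.s_tactile[j]
        den += w
    if den <= 0:
        raise ZeroDivisionError("zero denominator in averaging prediction")
    return num / den


@dataclass
class ImportanceProfile:
    """Relative importance of each weight, normalized to sum to 1 (incl. w0)."""

    entries: dict[str, float]

    def factor(self, factor: str) -> float:
        return sum(v for k, v in self.entries.items() if k.startswith(factor))

    @property
    def w0(self) -> float:
        return self.entries["w0"]


def relative_importance(params: AveragingParams) -> ImportanceProfile:
    """Each weight (including w0) divided by the total of all weights."""
    entries: dict[str, float] = {"w0": params.w0}
    for factor in ("audio", "tactile"):
        w = params.w_audio if factor == "audio" else params.w_tactile
        if isinstance(w, (list, tuple, np.ndarray)):
            for i, v in enumerate(w):
                entries[f"{factor}_{i}"] = float(v)
        else:
            entries[factor] = float(w)
    total = sum(entries.values())
    if not np.isfinite(total) or total <= 0:
        raise ValueError("importance undefined: weights are all zero or non-finite")
    return ImportanceProfile({k: v / total for k, v in entries.items()})


class AveragingModel:
    """Averaging model for one subject's cell means (statsmodels-style).

    Parameters
    ----------
    cell_means : mapping ``(audio_code, tactile_code) -> mean rating``
        Must cover every cell of the design: the bimodal product and both
        unimodal margins (the margins identify the weights).
    design : StimulusDesign
    variant : "equal" (one weight per factor) or "differential" (per level)
    w0 : the identification constant the initial-state weight is pinned to
    """

    def __init__(
        self,
        cell_means: dict[tuple[str, str], float],
        design: StimulusDesign,
        variant: str = "equal",
        w0: float = 1.0,
    ):
        if variant not in ("equal", "differential"):
            raise ValueError(f"unknown variant {variant!r}")
        if not (design.unimodal_audio and design.unimodal_tactile):
            raise DesignError("both unimodal margins are required for weight identifiability")
        if w0 <= 0:
            raise ValueError("identification constant w0 must be positive")
        self.design = design
        self.variant = variant
        self.w0 = float(w0)
        self.cells = design.cells()
        missing = [c for c in self.cells if c not in cell_means]
        if missing:
            raise DesignError(f"incomplete cell means: missing {missing}")
        self.y = np.array([float(cell_means[c]) for c in self.cells])
        self.n_audio = len(design.audio_codes)
        self.n_tactile = len(design.tactile_codes)
        if variant == "differential" and (self.n_audio < 2 or self.n_tactile < 2):
            raise DesignError("differential weighting needs >= 2 levels per factor")
        self.n_weights = (
            2 if variant == "equal" else self.n_audio + self.n_tactile
        )
        # linear parameters: s0, s_audio (n_audio), s_tactile (n_tactile)
        self.n_linear = 1 + self.n_audio + self.n_tactile
        self.n_params = self.n_weights + self.n_linear

    # -- variable projection ------------------------------------------------

    def _split_weights(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.variant == "equal":
            return np.full(self.n_audio, w[0]), np.full(self.n_tactile, w[1])
        return w[: self.n_audio], w[self.n_audio:]

    def _design_matrix(self, w: np.ndarray) -> np.ndarray:
        wa, wt = self._split_weights(w)
        X = np.zeros((len(self.cells), self.n_linear))
        a_codes, t_codes = self.design.audio_codes, self.design.tactile_codes
        for r, (a, t) in enumerate(self.cells):
            den = self.w0
            if a != ABSENT:
                den += wa[a_codes.index(a)]
            if t != ABSENT:
                den += wt[t_codes.index(t)]
            X[r, 0] = self.w0 / den
            if a != ABSENT:
                i = a_codes.index(a)
                X[r, 1 + i] = wa[i] / den
            if t != ABSENT:
                j = t_codes.index(t)
                X[r, 1 + self.n_audio + j] = wt[j] / den
        return X

    #: scale values are subjective values tied to the response scale; bounding
    #: the inner solve removes the w->0, s->inf degeneracy under which the
    #: averaging model mimics a pure adding rule.  The bound is 1.5x the
    #: rating bound: wide enough that estimation noise around near-extreme
    #: true values is not truncated (which would bias residuals), tight
    #: enough that mimicking an adding pattern still forces a detectable
    #: set-size misfit.
    SCALE_BOUND = 150.0

    def _solve_scales(self, w: np.ndarray) -> tuple[np.ndarray, float]:
        X = self._design_matrix(w)
        beta, _, _, _ = np.linalg.lstsq(X, self.y, rcond=None)
        b = self.SCALE_BOUND
        if np.any(np.abs(beta) > b + 1e-9):
            res = optimize.lsq_linear(X, self.y, bounds=(-b, b), method="bvls")
            beta = res.x
        resid = self.y - X @ beta
        return beta, float(resid @ resid)

    def sse_at(self, w: np.ndarray) -> float:
        return self._solve_scales(np.asarray(w, float))[1]

    def predict(self, params: AveragingParams) -> dict[tuple[str, str], float]:
        return {c: predict_eam(params, c, self.design) for c in self.cells}

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_restarts: int = 20,
        seed: int = 0,
        weight_bound: float = 10.0,
        tol: float = 1e-10,
    ) -> "AveragingResults":
        """Multi-start bounded least squares over the weights.

        Deterministic given (data, seed).  Weights are box-constrained to
        [0, weight_bound] so boundary solutions (w = 0) are reportable.
        All-constant data leaves the weights unidentified and returns an
        explicitly degenerate result.
        """
        if float(np.ptp(self.y)) < 1e-9:
            params = self._params_from(np.full(self.n_weights, 1.0),
                                       np.r_[self.y[0], np.full(self.n_linear - 1, self.y[0])])
            return AveragingResults(
                model=self, params=params, sse=0.0, converged=False,
                n_restarts_used=0, degenerate=True,
            )
        k = self.n_weights
        sampler = qmc.LatinHypercube(d=k, seed=seed)
        starts = qmc.scale(sampler.random(n_restarts), 1e-3, weight_bound)
        bounds = [(0.0, weight_bound)] * k
        best = None
        for w0_start in starts:
            res = optimize.minimize(
                self.sse_at, w0_start, method="L-BFGS-B", bounds=bounds,
                options={"ftol": tol, "gtol": 1e-12, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - tol:
                best = res
        w = np.asarray(best.x, float)
        beta, sse = self._solve_scales(w)
        return AveragingResults(
            model=self, params=self._params_from(w, beta), sse=sse,
            converged=bool(best.success), n_restarts_used=n_restarts,
        )

    def _params_from(self, w: np.ndarray, beta: np.ndarray) -> AveragingParams:
        wa, wt = self._split_weights(w)
        return AveragingParams(
            w0=self.w0,
            s0=float(beta[0]),
            w_audio=float(wa[0]) if self.variant == "equal" else [float(v) for v in wa],
            w_tactile=float(wt[0]) if self.variant == "equal" else [float(v) for v in wt],
            s_audio=[float(v) for v in beta[1: 1 + self.n_audio]],
            s_tactile=[float(v) for v in beta[1 + self.n_audio:]],
            identification=f"w0={self.w0:g}",
        )


@dataclass
class AveragingResults:
    """Fit of an :class:`AveragingModel`: estimates, fit quality, diagnostics."""

    model: AveragingModel
    params: AveragingParams
    sse: float
    converged: bool
    n_restarts_used: int
    degenerate: bool = False
    predictions: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.predictions:
            self.predictions = self.model.predict(self.params)

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def nobs(self) -> int:
        return len(self.model.cells)

    @property
    def bic(self) -> float:
        """Gaussian BIC on cell means: n*ln(sse/n) + k*ln(n), sse floored."""
        n = self.nobs
        return n * np.log(max(self.sse, _SSE_FLOOR) / n) + self.n_params * np.log(n)

    @property
    def resid(self) -> dict[tuple[str, str], float]:
        return {
            c: self.model.y[i] - self.predictions[c]
            for i, c in enumerate(self.model.cells)
        }

    @property
    def weight_ratio(self) -> float:
        """w_audio / w_tactile (factor means for the differential variant)."""
        wa = np.mean(self.params.weight_list("audio", self.model.n_audio))
        wt = np.mean(self.params.weight_list("tactile", self.model.n_tactile))
        return float(wa / wt) if wt > 0 else float("inf")

    def importance(self) -> ImportanceProfile:
        return relative_importance(self.params)

    def summary(self) -> str:
        p = self.params
        lines = [
            f"Averaging model ({self.model.variant} weights), {p.identification}",
            f"  cells fitted: {self.nobs}   parameters: {self.n_params}",
            f"  sse: {self.sse:.6g}   bic: {self.bic:.4g}   converged: {self.converged}"
            + ("   DEGENERATE (weights unidentified)" if self.degenerate else ""),
            f"  s0: {p.s0:+.3f}",
            f"  w_audio:   {p.w_audio if isinstance(p.w_audio, float) else [round(v, 4) for v in p.w_audio]}",
            f"  w_tactile: {p.w_tactile if isinstance(p.w_tactile, float) else [round(v, 4) for v in p.w_tactile]}",
            f"  s_audio:   {[round(v, 2) for v in p.s_audio]}",
            f"  s_tactile: {[round(v, 2) for v in p.s_tactile]}",
        ]
        return "\n".join(lines)


def select_model(fits: list[AveragingResults]) -> AveragingResults:
    """Minimum-BIC model; ties (within 1e-9) go to the fewer-parameter fit."""
    if not fits:
        raise ValueError("no fits to select from")
    y0 = fits[0].model.y
    for f in fits[1:]:
        if f.model.y.shape != y0.shape or not np.allclose(f.model.y, y0):
            raise ValueError("fits were computed on different data")
    return min(fits, key=lambda f: (round(f.bic, 9), f.n_params))


def fit_cohort(
    table: CellMeansTable,
    variant: str = "equal",
    w0: float = 1.0,
    n_restarts: int = 20,
    seed: int = 0,
) -> dict[str, AveragingResults]:
    """Fit the averaging model to every complete subject of a cell-means table."""
    out: dict[str, AveragingResults] = {}
    incomplete = set(table.incomplete_subjects())
    for s_index, subject in enumerate(table.subjects):
        if subject in incomplete:
            raise DesignError(f"subject {subject} has incomplete cells; refusing to fit")
        cm = table.subject_cell_means(subject)
        model = AveragingModel(cm, table.design, variant=variant, w0=w0)
        out[subject] = model.fit(n_restarts=n_restarts, seed=seed + s_index)
    return out


def residual_gof(
    fits: dict[str, AveragingResults], table: CellMeansTable
) -> dict[str, list[AnovaResult]]:
    """Repeated-measures ANOVAs on the per-subject fit residuals.

    Follows the two factorial views of the study: the audio view treats the
    audio-unimodal margin as a fourth tactile level (5 x 4 factorial), the
    tactile view treats the tactile-unimodal margin as a sixth audio level
    (6 x 3).  The model fits well when every effect is non-significant.
    """
    rows = []
    for subject, res in fits.items():
        for cell, r in res.resid.items():
            rows.append({"subject": subject, "audio": cell[0], "tactile": cell[1], "resid": r})
    df = pd.DataFrame(rows)
    audio_view = df[df["audio"] != ABSENT]
    tactile_view = df[df["tactile"] != ABSENT]
    return {
        "audio_view": rm_anova(audio_view, dv="resid", within=["audio", "tactile"]),
        "tactile_view": rm_anova(tactile_view, dv="resid", within=["audio", "tactile"]),
    }


def fit_table(fits: dict[str, AveragingResults]) -> pd.DataFrame:
    """Per-subject fit summary: weights, scales, sse, bic, convergence."""
    rows = []
    for subject, r in fits.items():
        p = r.params
        na, nt = r.model.n_audio, r.model.n_tactile
        row = {
            "subject": subject,
            "model": r.model.variant,
            "w0": p.w0,
            "s0": p.s0,
            "w_audio": np.mean(p.weight_list("audio", na)),
            "w_tactile": np.mean(p.weight_list("tactile", nt)),
            "sse": r.sse,
            "bic": r.bic,
            "converged": r.converged,
            "degenerate": r.degenerate,
        }
        for i, code in enumerate(r.model.design.audio_codes):
            row[f"s_{code}"] = p.s_audio[i]
        for j, code in enumerate(r.model.design.tactile_codes):
            row[f"s_{code}"] = p.s_tactile[j]
        rows.append(row)
    return pd.DataFrame(rows)
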