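"""Synthetic cohorts with a known integration rule and retained ground truth.

Each simulated subject carries an algebraic integration rule (averaging with
equal or differential weights, adding, or multiplying), per-factor weights,
per-level scale values, an initial state (w0, s0) and a trial noise SD.
Ratings are the rule's latent response plus i.i.d. Gaussian noise, clipped to
the bounded response scale — emulating a track bar pinned at its ends.

``make_paper_like_config`` states the study-like world: 23 subjects, an 80/20
mixture of audio-dominant versus balanced integrators, equal-weight averaging,
scale values spanning the rating range with near-neutral unimodal net values
(so the crossover signature of averaging is expressible).  The population SDs
are package defaults — the study reports no subject-level variance components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .design import (
    ABSENT,
    DesignError,
    StimulusDesign,
    TrialRecord,
    build_design,
    enumerate_trials,
)

RULES = ("averaging_equal_weight", "averaging_differential", "adding", "multiplying")


@dataclass
class SubjectParams:
    """Ground-truth integration parameters of one simulated subject.

    For ``averaging_differential``, ``weight_audio`` / ``weight_tactile`` are
    per-level vectors; otherwise scalars.
    """

    rule: str
    w0: float
    s0: float
    weight_audio: float | list[float]
    weight_tactile: float | list[float]
    scale_audio: list[float]
    scale_tactile: list[float]
    noise_sd: float
    component: str = ""  # label of the population component the subject came from

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.w0 < 0 or self.noise_sd < 0:
            raise ValueError("w0 and noise_sd must be nonnegative")

    def weight_for(self, factor: str, level_index: int) -> float:
        w = self.weight_audio if factor == "audio" else self.weight_tactile
        return float(w[level_index]) if isinstance(w, (list, tuple, np.ndarray)) else float(w)


@dataclass
class PopulationComponent:
    """One mixture component: parameter means and between-subject SDs.

    For ``averaging_differential``, ``weight_*_mean`` may be per-level lists,
    giving every subject the same systematic level-weighting pattern (jittered
    by ``weight_*_sd``); scalar means draw each level around a common value.
    """

    proportion: float
    rule: str
    w0: float
    s0_mean: float
    s0_sd: float
    weight_audio_mean: float | list[float]
    weight_audio_sd: float
    weight_tactile_mean: float | list[float]
    weight_tactile_sd: float
    scale_audio_mean: list[float]
    scale_tactile_mean: list[float]
    scale_sd: float
    noise_sd: float
    label: str = ""


@dataclass
class SimulationConfig:
    n_subjects: int
    design: StimulusDesign
    population: list[PopulationComponent]
    seed: int
    clip: tuple[float, float] = (-100.0, 100.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        total = sum(c.proportion for c in self.population)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, not 1")


@dataclass
class Cohort:
    """Simulated trials plus the per-subject ground truth that produced them."""

    records: list[TrialRecord]
    truth: dict[str, SubjectParams]
    design: StimulusDesign


def predict_rule(params: SubjectParams, cell: tuple[str, str], design: StimulusDesign) -> float:
    """Latent (noise-free) response of a subject's rule for one design cell.

    Averaging: (w0*s0 + sum of active w_i*s_i) / (w0 + sum of active w_i);
    adding: w0*s0 + sum of active w_i*s_i; multiplying: w0*s0 +
    100 * product of active (s_i / 100) — a stated convention keeping the
    product in rating units.  Absent factors drop out of all sums/products.
    """
    audio, tactile = cell
    if not design.is_cell(audio, tactile):
        raise DesignError(f"({audio!r}, {tactile!r}) is not a cell of the design")

    terms: list[tuple[float, float]] = []  # (weight, scale) of active factors
    if audio != ABSENT:
        i = design.audio_codes.index(audio)
        terms.append((params.weight_for("audio", i), params.scale_audio[i]))
    if tactile != ABSENT:
        j = design.tactile_codes.index(tactile)
        terms.append((params.weight_for("tactile", j), params.scale_tactile[j]))

    if params.rule in ("averaging_equal_weight", "averaging_differential"):
        num = params.w0 * params.s0 + sum(w * s for w, s in terms)
        den = params.w0 + sum(w for w, _ in terms)
        if den <= 0:
            raise ZeroDivisionError("zero total weight in an averaging cell")
        return num / den
    if params.rule == "adding":
        return params.w0 * params.s0 + sum(w * s for w, s in terms)
    # multiplying
    prod = 100.0
    for _, s in terms:
        prod *= s / 100.0
    return params.w0 * params.s0 + prod


def _draw_subject(comp: PopulationComponent, rng: np.random.Generator) -> SubjectParams:
    def pos(x):
        return float(max(x, 0.05))  # keep weights identifiable

    n_a = len(comp.scale_audio_mean)
    n_t = len(comp.scale_tactile_mean)
    if comp.rule == "averaging_differential":
        wam = np.broadcast_to(np.atleast_1d(comp.weight_audio_mean), (n_a,))
        wtm = np.broadcast_to(np.atleast_1d(comp.weight_tactile_mean), (n_t,))
        wa = [pos(rng.normal(m, comp.weight_audio_sd)) for m in wam]
        wt = [pos(rng.normal(m, comp.weight_tactile_sd)) for m in wtm]
    else:
        wa = pos(rng.normal(float(comp.weight_audio_mean), comp.weight_audio_sd))
        wt = pos(rng.normal(float(comp.weight_tactile_mean), comp.weight_tactile_sd))
    clipv = lambda v: float(np.clip(v, -100.0, 100.0))
    return SubjectParams(
        rule=comp.rule,
        w0=comp.w0,
        s0=float(rng.normal(comp.s0_mean, comp.s0_sd)),
        weight_audio=wa,
        weight_tactile=wt,
        scale_audio=[clipv(rng.normal(m, comp.scale_sd)) for m in comp.scale_audio_mean],
        scale_tactile=[clipv(rng.normal(m, comp.scale_sd)) for m in comp.scale_tactile_mean],
        noise_sd=comp.noise_sd,
        component=comp.label,
    )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw subjects from the population mixture and simulate every trial.

    Deterministic given ``config.seed``: rating = clip(latent + N(0, noise_sd)).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.clip
    props = [c.proportion for c in config.population]
    comp_idx = rng.choice(len(config.population), size=config.n_subjects, p=props)

    records: list[TrialRecord] = []
    truth: dict[str, SubjectParams] = {}
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        params = _draw_subject(config.population[comp_idx[s]], rng)
        truth[sid] = params
        order_seed = int(rng.integers(0, 2**31 - 1))
        for stub in enumerate_trials(config.design, sid, order_seed):
            latent = predict_rule(params, (stub.audio_code, stub.tactile_code), config.design)
            rating = latent + rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else latent
            records.append(
                TrialRecord(
                    sid, stub.audio_code, stub.tactile_code, stub.repetition,
                    float(np.clip(rating, lo, hi)), stub.presentation_index,
                )
            )
    return Cohort(records=records, truth=truth, design=config.design)


# Scale-value means of the study-like world.  Scale values span the full
# rating range: the printed unimodal response spans (about -55..+58 audio,
# -53..+43 tactile) are averaging-attenuated by w/(w0+w), so the underlying
# subjective values reach the scale ends.  Symmetric around a near-neutral
# midpoint, which is what lets the unimodal lines cross the bimodal fan.
_AUDIO_SCALE = [-100.0, -50.0, 0.0, 50.0, 100.0]
_TACTILE_SCALE = [80.0, 0.0, -90.0]  # LO positive, ME neutral, HI negative


def make_paper_like_config(
    seed: int,
    n_subjects: int = 23,
    rule: str = "averaging_equal_weight",
    noise_sd: float = 10.0,
) -> SimulationConfig:
    """Study-like cohort: 80% audio-dominant vs 20% balanced integrators.

    Averaging-model weights are ratio-scale quantities: only their ratios are
    comparable across identifications, so the mixture anchors the audio:tactile
    weight RATIO — about 3:1 for the dominant component and 1:1.2 for the
    balanced one — at magnitudes of order 1 on the w0 = 1 scale.  For the
    adding rule — which has no denominator normalization — the weights are
    scaled down so latent responses stay inside the +/-100 response scale and
    clipping cannot distort the parallelism signature.
    """
    if rule == "adding":
        w_dom, w_bal = (0.6, 0.25), (0.35, 0.45)
    else:
        w_dom, w_bal = (1.5, 0.5), (1.0, 1.2)
    dominant = PopulationComponent(
        proportion=0.8, rule=rule, w0=1.0,
        s0_mean=0.0, s0_sd=5.0,
        weight_audio_mean=w_dom[0], weight_audio_sd=0.1 * w_dom[0],
        weight_tactile_mean=w_dom[1], weight_tactile_sd=0.1 * w_dom[1],
        scale_audio_mean=_AUDIO_SCALE, scale_tactile_mean=_TACTILE_SCALE,
        scale_sd=8.0, noise_sd=noise_sd, label="audio_dominant",
    )
    balanced = PopulationComponent(
        proportion=0.2, rule=rule, w0=1.0,
        s0_mean=0.0, s0_sd=5.0,
        weight_audio_mean=w_bal[0], weight_audio_sd=0.1 * w_bal[0],
        weight_tactile_mean=w_bal[1], weight_tactile_sd=0.1 * w_bal[1],
        scale_audio_mean=_AUDIO_SCALE, scale_tactile_mean=_TACTILE_SCALE,
        scale_sd=8.0, noise_sd=noise_sd, label="balanced",
    )
    return SimulationConfig(
        n_subjects=n_subjects, design=build_design(),
        population=[dominant, balanced], seed=seed,
    )


def make_null_config(seed: int, n_subjects: int = 23, noise_sd: float = 10.0) -> SimulationConfig:
    """No-effect cohort: all scale values 0, so cell means are pure noise."""
    null = PopulationComponent(
        proportion=1.0, rule="averaging_equal_weight", w0=1.0,
        s0_mean=0.0, s0_sd=0.0,
        weight_audio_mean=1.0, weight_audio_sd=0.0,
        weight_tactile_mean=1.0, weight_tactile_sd=0.0,
        scale_audio_mean=[0.0] * 5, scale_tactile_mean=[0.0] * 3,
        scale_sd=0.0, noise_sd=noise_sd, label="null",
    )
    return SimulationConfig(
        n_subjects=n_subjects, design=build_design(), population=[null], seed=seed
    )


def write_truth(cohort: Cohort, path) -> None:
    payload = {sid: asdict(p) for sid, p in cohort.truth.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> dict[str, SubjectParams]:
    with open(path) as fh:
        payload = json.load(fh)
    return {sid: SubjectParams(**p) for sid, p in payload.items()}
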