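"""Factorial stimulus designs, trial enumeration and long-format trial I/O.

A design crosses an audio factor (voice-morph levels) with a tactile factor
(air-jet intensity levels).  Beyond the full bimodal product, each factor may
contribute unimodal cells in which the other factor is absent (coded with the
literal ``ABSENT``).  The study layout is 5 audio x 3 tactile bimodal cells
plus both unimodal margins, 6 repetitions per cell: 23 cells, 138 trials per
subject.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ABSENT = "ABSENT"

#: canonical level codes of the study design
AUDIO_CODES = ("AS-100", "AS-50", "AS0", "AS+50", "AS+100")
TACTILE_CODES = ("TS_LO", "TS_ME", "TS_HI")

_CSV_COLUMNS = ["subject", "audio", "tactile", "rep", "ev"]
RATING_BOUNDS = (-100.0, 100.0)


class DesignError(ValueError):
    """Invalid design construction or a record inconsistent with the design."""


@dataclass(frozen=True)
class StimulusLevel:
    """One level of a stimulus factor.

    ``physical_meta`` documents physical calibration (morph fraction, flow
    rate, blowing force ...); it is never used in any computation.
    """

    factor: str  # "audio" | "tactile"
    code: str
    ordinal: int
    physical_meta: dict | None = None

    def __post_init__(self) -> None:
        if self.factor not in ("audio", "tactile"):
            raise DesignError(f"unknown factor {self.factor!r}")
        if self.code == ABSENT and self.physical_meta:
            raise DesignError("ABSENT level carries no physical metadata")


@dataclass(frozen=True)
class StimulusDesign:
    """An audio x tactile within-subject design with optional unimodal margins."""

    audio_levels: tuple[StimulusLevel, ...]
    tactile_levels: tuple[StimulusLevel, ...]
    reps_per_cell: int
    unimodal_audio: bool = True
    unimodal_tactile: bool = True

    def __post_init__(self) -> None:
        if self.reps_per_cell < 1:
            raise DesignError("reps_per_cell must be >= 1")
        for levels, name in ((self.audio_levels, "audio"), (self.tactile_levels, "tactile")):
            codes = [l.code for l in levels]
            if not codes:
                raise DesignError(f"{name} factor needs at least one level")
            if len(set(codes)) != len(codes):
                raise DesignError(f"duplicate level codes in {name} factor: {codes}")
            ords = [l.ordinal for l in levels]
            if any(b <= a for a, b in zip(ords, ords[1:])):
                raise DesignError(f"{name} ordinals must be strictly increasing")

    @property
    def audio_codes(self) -> list[str]:
        return [l.code for l in self.audio_levels]

    @property
    def tactile_codes(self) -> list[str]:
        return [l.code for l in self.tactile_levels]

    def cells(self) -> list[tuple[str, str]]:
        """All design cells as (audio_code, tactile_code), ABSENT-coded margins last."""
        out = list(itertools.product(self.audio_codes, self.tactile_codes))
        if self.unimodal_audio:
            out += [(a, ABSENT) for a in self.audio_codes]
        if self.unimodal_tactile:
            out += [(ABSENT, t) for t in self.tactile_codes]
        return out

    def bimodal_cells(self) -> list[tuple[str, str]]:
        return list(itertools.product(self.audio_codes, self.tactile_codes))

    @property
    def n_cells(self) -> int:
        na, nt = len(self.audio_levels), len(self.tactile_levels)
        return na * nt + na * self.unimodal_audio + nt * self.unimodal_tactile

    @property
    def trials_per_subject(self) -> int:
        return self.reps_per_cell * self.n_cells

    def is_cell(self, audio: str, tactile: str) -> bool:
        if audio == ABSENT and tactile == ABSENT:
            return False
        if audio == ABSENT:
            return self.unimodal_tactile and tactile in self.tactile_codes
        if tactile == ABSENT:
            return self.unimodal_audio and audio in self.audio_codes
        return audio in self.audio_codes and tactile in self.tactile_codes


@dataclass(frozen=True)
class TrialRecord:
    """One rating trial: which cell, which repetition, which EV rating."""

    subject_id: str
    audio_code: str
    tactile_code: str
    repetition: int
    ev_rating: float | None = None
    presentation_index: int | None = None


def build_design(
    audio_level_specs=AUDIO_CODES,
    tactile_level_specs=TACTILE_CODES,
    reps: int = 6,
    unimodal_audio: bool = True,
    unimodal_tactile: bool = True,
) -> StimulusDesign:
    """Assemble a design from level specs (codes, or (code, physical_meta) pairs).

    Defaults reproduce the study: 5 audio x 3 tactile x 6 reps with both
    unimodal margins -> 138 trials per subject.
    """

    def levels(specs, factor):
        out = []
        for i, spec in enumerate(specs):
            if isinstance(spec, StimulusLevel):
                out.append(spec)
            elif isinstance(spec, str):
                out.append(StimulusLevel(factor, spec, i))
            else:
                code, meta = spec
                out.append(StimulusLevel(factor, code, i, meta))
        return tuple(out)

    return StimulusDesign(
        audio_levels=levels(audio_level_specs, "audio"),
        tactile_levels=levels(tactile_level_specs, "tactile"),
        reps_per_cell=reps,
        unimodal_audio=unimodal_audio,
        unimodal_tactile=unimodal_tactile,
    )


def paper_design() -> StimulusDesign:
    """The study's 5 x 3 (+ margins) x 6 design."""
    return build_design()


def enumerate_trials(design: StimulusDesign, subject_id: str, order_seed: int) -> list[TrialRecord]:
    """Enumerate every (cell, repetition) once in a seeded random order.

    Ratings are left unset; same seed -> identical order.
    """
    stubs = [
        TrialRecord(subject_id, a, t, rep)
        for (a, t) in design.cells()
        for rep in range(1, design.reps_per_cell + 1)
    ]
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(stubs))
    return [
        TrialRecord(
            s.subject_id, s.audio_code, s.tactile_code, s.repetition,
            presentation_index=i + 1,
        )
        for i, s in enumerate(stubs[j] for j in order)
    ]


def _validate_row(audio: str, tactile: str, ev: float, design: StimulusDesign, row: int) -> None:
    lo, hi = RATING_BOUNDS
    if audio == ABSENT and tactile == ABSENT:
        raise DesignError(f"row {row}: both factors ABSENT")
    if not design.is_cell(audio, tactile):
        raise DesignError(f"row {row}: ({audio!r}, {tactile!r}) is not a cell of the design")
    if not (lo <= ev <= hi):
        raise DesignError(f"row {row}: rating {ev} outside [{lo:g}, {hi:g}]")


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Long-format frame with columns subject, audio, tactile, rep, ev."""
    return pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "audio": [r.audio_code for r in records],
            "tactile": [r.tactile_code for r in records],
            "rep": [r.repetition for r in records],
            "ev": [r.ev_rating for r in records],
        }
    )


def frame_to_records(df: pd.DataFrame, design: StimulusDesign) -> list[TrialRecord]:
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DesignError(f"missing columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        ev = float(row.ev)
        _validate_row(str(row.audio), str(row.tactile), ev, design, row=i + 1)
        records.append(TrialRecord(str(row.subject), str(row.audio), str(row.tactile), int(row.rep), ev))
    return records


def read_trials(path, design: StimulusDesign) -> list[TrialRecord]:
    """Read a long-format trial CSV, validating every row against the design."""
    df = pd.read_csv(path, dtype={"subject": str, "audio": str, "tactile": str})
    return frame_to_records(df, design)


def write_trials(records: list[TrialRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False, float_format="%.6f")


@dataclass
class CellMeansTable:
    """Per-subject mean rating and trial count for every design cell.

    ``means`` is a long frame (subject, audio, tactile, mean, n); the wide
    subject x cell matrix used by ANOVA and clustering comes from
    :meth:`wide`, whose column order is the design's canonical cell order.
    """

    design: StimulusDesign
    means: pd.DataFrame = field(repr=False)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.means["subject"].unique())

    def incomplete_subjects(self) -> list[str]:
        n_cells = self.design.n_cells
        counts = self.means.groupby("subject").size()
        return sorted(counts[counts < n_cells].index)

    def wide(self, cells: list[tuple[str, str]] | None = None) -> pd.DataFrame:
        """Subject x cell matrix of means; raises if any requested cell is missing."""
        cells = cells if cells is not None else self.design.cells()
        pivot = self.means.pivot_table(
            index="subject", columns=["audio", "tactile"], values="mean", aggfunc="first"
        )
        try:
            out = pivot[cells]
        except KeyError as e:
            raise DesignError(f"incomplete cell means: missing cells {e}") from None
        if out.isna().any().any():
            bad = out.index[out.isna().any(axis=1)].tolist()
            raise DesignError(f"incomplete cell means for subjects {bad}")
        out.columns = [f"{a}|{t}" for a, t in cells]
        return out.sort_index()

    def subject_cell_means(self, subject: str) -> dict[tuple[str, str], float]:
        sub = self.means[self.means["subject"] == subject]
        return {(r.audio, r.tactile): r.mean for r in sub.itertuples(index=False)}

    def group_means(self) -> pd.DataFrame:
        """Unweighted across-subject mean per cell (long frame: audio, tactile, mean)."""
        return (
            self.means.groupby(["audio", "tactile"], as_index=False)["mean"]
            .mean()
        )


def cell_means(records: list[TrialRecord], design: StimulusDesign) -> CellMeansTable:
    """Arithmetic mean and count per (subject, cell)."""
    if not records:
        raise DesignError("no trial records")
    df = records_to_frame(records)
    agg = (
        df.groupby(["subject", "audio", "tactile"], as_index=False)["ev"]
        .agg(["mean", "count"])
        .rename(columns={"count": "n"})
    )
    return CellMeansTable(design=design, means=agg)
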