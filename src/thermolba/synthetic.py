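"""Synthetic study generator.

Emulates the two behavioral tasks of a passive-hyperthermia study — an
interval-reproduction task around a learned 1 s target and a
two-alternative flicker-discrimination task under a 1 s response deadline
— across 2 water-temperature conditions (Neutral / Warm) x 3 measurement
moments (Baseline / Begin / End).

The timing task follows a pacemaker-accumulator clock: a pacemaker emits
pulses at a rate proportional to a `rate_ratio` (current rate over the
rate at which the 1 s target was learned).  When the pacemaker speeds up
(rate_ratio > 1, the hypothesized Warm-End effect), the learned pulse
count is reached sooner and the interval is under-reproduced:

    reproduction = target * bias / rate_ratio * LogNormal noise,

with the lognormal scaled to mean 1 and coefficient of variation `cv`
(scalar timing).  `bias` < 1 captures the general tendency to
underproduce even at baseline.

Choices are generated from the LBA (see :mod:`thermolba.lba`), with each
participant's Warm-cell threshold reduction linearly coupled — with noise
— to that participant's own clock speed-up.  A positive coupling makes
the across-participant correlation between timing change and threshold
change recoverable by the full pipeline.  Flicker stimulus frames are
generated for task fidelity but choices come from the LBA parameters,
not from a frame-level model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    ALL_CELLS,
    SESSION_OF_CONDITION,
    ChoiceTrial,
    DesignCell,
    TimingTrial,
)
from .lba import LBACellParams, sample_lba

__all__ = [
    "ClockParams",
    "StimulusFrames",
    "GroupTruth",
    "default_group_truth",
    "default_clock_truth",
    "simulate_reproductions",
    "simulate_flicker",
    "simulate_choices",
    "generate_study",
    "StudyData",
]

#: study task constants
TARGET_INTERVAL_S = 1.0
DEADLINE_S = 1.0
RATE_TARGET = 0.7
RATE_FOIL = 0.3
FLICKER_FRAME_RATE_HZ = 20.0  # unstated in the task description; configurable


@dataclass(frozen=True)
class ClockParams:
    """Pacemaker-clock generative parameters.

    rate_ratio : per-cell pacemaker rate relative to the learning rate
                 (1 in every Baseline cell; > 1 means the clock runs fast)
    bias       : multiplicative underproduction tendency, 0 < bias <= 1
    cv         : coefficient of variation of reproductions, >= 0
    """

    rate_ratio: dict = field(default_factory=dict)  # DesignCell -> float
    bias: float = 0.95
    cv: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.bias <= 1:
            raise ValueError("bias must be in (0, 1]")
        if self.cv < 0 or not np.isfinite(self.cv):
            raise ValueError("cv must be finite and >= 0")
        rr = {DesignCell.parse(c): float(r) for c, r in self.rate_ratio.items()}
        for cell, r in rr.items():
            if not np.isfinite(r) or r <= 0:
                raise ValueError(f"rate_ratio for {cell} must be finite and > 0")
            if cell.is_baseline and r != 1.0:
                raise ValueError(f"rate_ratio must be 1 in Baseline cell {cell}")
        object.__setattr__(self, "rate_ratio", rr)

    def ratio(self, cell) -> float:
        cell = DesignCell.parse(cell)
        if cell.is_baseline:
            return 1.0
        return self.rate_ratio.get(cell, 1.0)


@dataclass(frozen=True)
class StimulusFrames:
    """Frame-by-frame flicker stimulus of one 2AFC trial."""

    frames: np.ndarray  # (n_frames, 2) of {0, 1}; column 0 = target circle
    rate_target: float
    rate_foil: float
    side_of_target: str  # "left" or "right"


def _lognormal_sigma(cv: float) -> float:
    """sigma of a LogNormal with mean 1 and coefficient of variation cv."""
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_reproductions(clock: ClockParams, cell, target_s: float,
                           n: int, seed) -> list[TimingTrial]:
    """Draw n interval reproductions in one design cell.

    reproduction = target * bias / rate_ratio(cell) * LogNormal(mean 1,
    CV cv).  A faster clock (larger rate_ratio) shortens the noiseless
    mean — the learned pulse count is reached sooner.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not target_s > 0:
        raise ValueError("target_s must be > 0")
    cell = DesignCell.parse(cell)
    ratio = clock.ratio(cell)
    if ratio <= 0:
        raise ValueError("rate_ratio must be > 0")
    rng = np.random.default_rng(seed)
    mean = target_s * clock.bias / ratio
    if clock.cv == 0:
        reps = np.full(n, mean)
    else:
        sigma = _lognormal_sigma(clock.cv)
        reps = mean * rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)
    return [TimingTrial("p0", cell, target_s, float(r)) for r in reps]


def simulate_flicker(rate_target: float, rate_foil: float, n_frames: int,
                     seed) -> StimulusFrames:
    """Generate one trial's flicker stimulus: two independent Bernoulli
    frame streams (study defaults: 0.7 target, 0.3 foil) with the target
    side randomized per trial."""
    for r in (rate_target, rate_foil):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must be in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = np.column_stack([
        (rng.random(n_frames) < rate_target).astype(np.int8),
        (rng.random(n_frames) < rate_foil).astype(np.int8),
    ])
    side = "left" if rng.random() < 0.5 else "right"
    return StimulusFrames(frames, rate_target, rate_foil, side)


def simulate_choices(params: LBACellParams, n: int,
                     deadline_s: float = DEADLINE_S, seed=None,
                     participant_id: str = "p0",
                     cell=DesignCell("Neutral", "Baseline")) -> list[ChoiceTrial]:
    """Draw n LBA choice trials in one design cell.

    Trials slower than the deadline are flagged but retained (the
    deadline gated feedback in the task, not the response itself).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cell = DesignCell.parse(cell)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rt, is_target, _ = sample_lba(params, n, rng)
    out = []
    for r, t in zip(rt, is_target):
        resp = "target" if t else "foil"
        out.append(ChoiceTrial(participant_id, cell, float(r), resp, bool(t),
                               deadline_s, bool(r > deadline_s)))
    return out


# ---------------------------------------------------------------------------
# full-study generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTruth:
    """Group-level generative truth for the LBA parameters.

    means/sds map base parameter names to scalars; `B` means the Baseline
    threshold gap (Warm-cell thresholds are then derived per participant
    from the clock coupling).  Participant draws are normal around the
    means, clipped into the participant prior supports.
    """

    means: dict = field(default_factory=lambda: {
        "A": 0.5, "B": 0.7, "v_correct": 2.5, "delta_v": 1.0,
        "s_error": 0.8, "t0": 0.2,
    })
    sds: dict = field(default_factory=lambda: {
        "A": 0.10, "B": 0.15, "v_correct": 0.40, "delta_v": 0.30,
        "s_error": 0.10, "t0": 0.03,
    })

    def __post_init__(self) -> None:
        for k, v in self.sds.items():
            if v < 0:
                raise ValueError(f"negative SD for {k}")


def default_group_truth() -> GroupTruth:
    return GroupTruth()


def default_clock_truth() -> ClockParams:
    """Study-conditions clock: identity in Neutral and at Baseline, a
    modest speed-up at Warm-Begin and a stronger one at Warm-End."""
    return ClockParams(rate_ratio={
        DesignCell("Neutral", "Begin"): 1.0,
        DesignCell("Neutral", "End"): 1.0,
        DesignCell("Warm", "Begin"): 1.05,
        DesignCell("Warm", "End"): 1.12,
    })


#: across-participant SD of the Warm-cell rate ratios
RATE_RATIO_SD = 0.04
#: SD of the noise on the clock->threshold coupling (evidence units)
COUPLING_NOISE_SD = 0.05
#: default coupling slope: threshold drop per unit of (rate_ratio - 1)
DEFAULT_COUPLING = 1.5

_PARTICIPANT_BOUNDS = {
    "v_correct": (-5.0, 20.0), "delta_v": (0.0, 20.0), "s_error": (0.1, 10.0),
    "A": (0.01, 20.0), "B": (0.01, 20.0), "t0": (0.01, 0.5),
}


@dataclass
class StudyData:
    """A generated dataset plus its ground truth."""

    trials: pd.DataFrame
    truth: dict


def _draw_clipped_normal(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def generate_study(group_truth: GroupTruth | None = None,
                   clock_truth: ClockParams | None = None,
                   coupling: float = DEFAULT_COUPLING,
                   n_participants: int = 27,
                   n_trials_per_cell: int = 60,
                   seed: int = 0,
                   cells=ALL_CELLS,
                   deadline_s: float = DEADLINE_S,
                   rate_ratio_sd: float = RATE_RATIO_SD,
                   coupling_noise_sd: float = COUPLING_NOISE_SD) -> StudyData:
    """Generate a complete synthetic study (both tasks, all cells).

    Per participant: a clock (Warm rate ratios drawn around the group
    clock) and LBA parameters drawn from the group truth; the threshold
    gap in each Warm cell is B_baseline - coupling * (rate_ratio - 1)
    plus normal noise, so clock speed-up and threshold reduction are
    positively coupled across participants when `coupling` > 0.  One
    master seed; per-participant, per-cell, per-task child streams are
    spawned deterministically, so identical seeds give byte-identical
    datasets.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    if n_trials_per_cell < 1:
        raise ValueError("n_trials_per_cell must be >= 1")
    group_truth = group_truth or default_group_truth()
    clock_truth = clock_truth or default_clock_truth()
    cells = tuple(DesignCell.parse(c) for c in cells)

    master = np.random.SeedSequence(seed)
    part_seeds = master.spawn(n_participants)
    rows = []
    truth_participants = {}
    for i in range(n_participants):
        pid = f"p{i + 1:02d}"
        pseq = part_seeds[i]
        prng = np.random.default_rng(pseq)

        # participant clock: Warm-cell ratios around the group clock
        rr = {}
        for cell in ALL_CELLS:
            base = clock_truth.ratio(cell)
            if cell.is_baseline or base == 1.0:
                rr[cell] = base if cell.is_baseline else max(
                    0.5, prng.normal(base, rate_ratio_sd / 2)
                )
            else:
                rr[cell] = max(0.5, prng.normal(base, rate_ratio_sd))
        clock_i = ClockParams(
            rate_ratio={c: (1.0 if c.is_baseline else rr[c])
                        for c in ALL_CELLS},
            bias=clock_truth.bias, cv=clock_truth.cv,
        )

        # participant LBA parameters (shared across cells except B)
        base_params = {}
        for name in ("A", "B", "v_correct", "delta_v", "s_error", "t0"):
            lo, hi = _PARTICIPANT_BOUNDS[name]
            base_params[name] = _draw_clipped_normal(
                prng, group_truth.means[name], group_truth.sds[name], lo, hi)

        # per-cell threshold gap, coupled to the participant's clock
        B_cell = {}
        for cell in ALL_CELLS:
            if cell.condition == "Warm" and not cell.is_baseline:
                drop = coupling * (clock_i.ratio(cell) - 1.0)
                noise = prng.normal(0.0, coupling_noise_sd)
                B_cell[cell] = float(np.clip(
                    base_params["B"] - drop + noise, 0.01, 20.0))
            else:
                B_cell[cell] = base_params["B"]

        lba_cells = {
            cell: LBACellParams(
                A=base_params["A"], B=B_cell[cell],
                v_correct=base_params["v_correct"],
                delta_v=base_params["delta_v"],
                s_error=base_params["s_error"], t0=base_params["t0"],
            )
            for cell in cells
        }

        # one child stream per (cell, task)
        cell_seeds = pseq.spawn(2 * len(cells))
        for j, cell in enumerate(cells):
            trng = np.random.default_rng(cell_seeds[2 * j])
            crng = np.random.default_rng(cell_seeds[2 * j + 1])
            session = SESSION_OF_CONDITION[cell.condition]

            reps = simulate_reproductions(
                clock_i, cell, TARGET_INTERVAL_S, n_trials_per_cell, trng)
            for tr in reps:
                rows.append({
                    "participant_id": pid, "session": session,
                    "condition": cell.condition, "moment": cell.moment,
                    "task": "timing", "rt_s": np.nan, "response": "NA",
                    "correct": np.nan, "reproduction_s": tr.reproduction_s,
                    "deadline_s": np.nan, "missed_deadline": np.nan,
                })

            choices = simulate_choices(
                lba_cells[cell], n_trials_per_cell, deadline_s, crng,
                participant_id=pid, cell=cell)
            for tr in choices:
                rows.append({
                    "participant_id": pid, "session": session,
                    "condition": cell.condition, "moment": cell.moment,
                    "task": "choice", "rt_s": tr.rt_s,
                    "response": tr.response, "correct": float(tr.correct),
                    "reproduction_s": np.nan, "deadline_s": tr.deadline_s,
                    "missed_deadline": float(tr.missed_deadline),
                })

        truth_participants[pid] = {
            "clock": {
                "rate_ratio": {c.label: clock_i.ratio(c) for c in ALL_CELLS},
                "bias": clock_i.bias, "cv": clock_i.cv,
            },
            "lba": {**{k: base_params[k] for k in
                       ("A", "v_correct", "delta_v", "s_error", "t0")},
                    "B": {c.label: B_cell[c] for c in ALL_CELLS}},
        }

    trials = pd.DataFrame(rows)
    # implied group-level means of the per-cell thresholds (for recovery
    # checks against fitted hypermeans)
    implied_B = {}
    for cell in ALL_CELLS:
        if cell.condition == "Warm" and not cell.is_baseline:
            implied_B[cell.label] = (group_truth.means["B"]
                                     - coupling * (clock_truth.ratio(cell) - 1.0))
        else:
            implied_B[cell.label] = group_truth.means["B"]
    truth = {
        "seed": int(seed),
        "n_participants": int(n_participants),
        "n_trials_per_cell": int(n_trials_per_cell),
        "cells": [c.label for c in cells],
        "deadline_s": deadline_s,
        "coupling": coupling,
        "rate_ratio_sd": rate_ratio_sd,
        "coupling_noise_sd": coupling_noise_sd,
        "group": {
            "means": dict(group_truth.means),
            "sds": dict(group_truth.sds),
            "implied_B_per_cell": implied_B,
        },
        "clock": {
            "rate_ratio": {c.label: clock_truth.ratio(c) for c in ALL_CELLS},
            "bias": clock_truth.bias, "cv": clock_truth.cv,
        },
        "participants": truth_participants,
    }
    return StudyData(trials=trials, truth=truth)
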