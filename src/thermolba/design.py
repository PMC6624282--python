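"""Experimental design vocabulary shared by all modules.

The study crosses two water-temperature conditions (Neutral, Warm) with
three measurement moments (Baseline, Begin, End).  Baseline is the
out-of-tub measurement taken at the start of each session; Begin and End
are taken after 20 and 60 minutes of immersion.  Each participant performs
an interval-reproduction (timing) task and a two-alternative flicker
discrimination (choice) task in every cell.
"""

from __future__ import annotations

from dataclasses import dataclass

CONDITIONS = ("Neutral", "Warm")
MOMENTS = ("Baseline", "Begin", "End")
TASKS = ("timing", "choice")
RESPONSES = ("target", "foil")


@dataclass(frozen=True, order=True)
class DesignCell:
    """One condition x moment cell of the 2 x 3 design."""

    condition: str
    moment: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.moment not in MOMENTS:
            raise ValueError(f"unknown moment {self.moment!r}")

    @property
    def label(self) -> str:
        return f"{self.condition}:{self.moment}"

    @property
    def is_baseline(self) -> bool:
        return self.moment == "Baseline"

    @classmethod
    def parse(cls, value: "DesignCell | str | tuple") -> "DesignCell":
        if isinstance(value, DesignCell):
            return value
        if isinstance(value, tuple):
            return cls(*value)
        cond, _, mom = str(value).partition(":")
        return cls(cond, mom)

    def __str__(self) -> str:
        return self.label


#: All six cells, in a fixed canonical order.
ALL_CELLS = tuple(DesignCell(c, m) for c in CONDITIONS for m in MOMENTS)

#: Session number per condition (condition order is counterbalanced in the
#: real study; a fixed assignment is sufficient for synthetic data).
SESSION_OF_CONDITION = {"Neutral": 1, "Warm": 2}


@dataclass(frozen=True)
class TimingTrial:
    """One interval-reproduction trial: press-to-press reproduction of a
    previously learned target interval (1 s in this design)."""

    participant_id: str
    cell: DesignCell
    target_s: float
    reproduction_s: float

    def __post_init__(self) -> None:
        if not self.reproduction_s > 0:
            raise ValueError("reproduction_s must be > 0")


@dataclass(frozen=True)
class ChoiceTrial:
    """One 2AFC flicker-discrimination trial under a response deadline."""

    participant_id: str
    cell: DesignCell
    rt_s: float
    response: str
    correct: bool
    deadline_s: float
    missed_deadline: bool

    def __post_init__(self) -> None:
        if not self.rt_s > 0:
            raise ValueError("rt_s must be > 0")
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if self.correct != (self.response == "target"):
            raise ValueError("correct must equal (response == 'target')")
        if self.missed_deadline != (self.rt_s > self.deadline_s):
            raise ValueError("missed_deadline must equal (rt_s > deadline_s)")
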