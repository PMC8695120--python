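"""Prompted rest / movement / imagined-movement task schedules.

A schedule is the experimental ground truth for a session: a sorted list of
non-overlapping prompt intervals on ``[0, total_duration_s)``.  Only
non-rest prompts are stored; any gap is implicitly rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream

VALID_LABELS = ("rest", "movement", "imagined")


@dataclass(frozen=True)
class PromptInterval:
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"unknown prompt label {self.label!r}")
        if not self.end_s > self.start_s:
            raise ValueError(f"empty prompt interval [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class PromptSchedule:
    """Non-rest prompt intervals over a session of ``total_duration_s``."""

    intervals: tuple[PromptInterval, ...]
    total_duration_s: float

    def __post_init__(self) -> None:
        if self.total_duration_s <= 0:
            raise ValueError("total_duration_s must be positive")
        ivs = tuple(sorted(self.intervals, key=lambda iv: iv.start_s))
        object.__setattr__(self, "intervals", ivs)
        prev_end = 0.0
        for iv in ivs:
            if iv.start_s < prev_end - 1e-12:
                raise ValueError("prompt intervals overlap or start before 0")
            if iv.end_s > self.total_duration_s + 1e-12:
                raise ValueError("prompt interval extends past total_duration_s")
            prev_end = iv.end_s

    # -- queries ---------------------------------------------------------

    def intervals_with_label(self, label: str) -> list[PromptInterval]:
        return [iv for iv in self.intervals if iv.label == label]

    @property
    def movement_intervals(self) -> list[PromptInterval]:
        return self.intervals_with_label("movement")

    def rest_intervals(self) -> list[tuple[float, float]]:
        """Gaps between prompts (implicitly rest), as (start, end) pairs."""
        gaps = []
        cursor = 0.0
        for iv in self.intervals:
            if iv.start_s > cursor + 1e-12:
                gaps.append((cursor, iv.start_s))
            cursor = iv.end_s
        if cursor < self.total_duration_s - 1e-12:
            gaps.append((cursor, self.total_duration_s))
        return gaps

    def labels_at(self, times_s: np.ndarray) -> np.ndarray:
        """Label for each time; intervals are half-open [start, end)."""
        t = np.asarray(times_s, dtype=float)
        out = np.full(t.shape, "rest", dtype=object)
        for iv in self.intervals:
            out[(t >= iv.start_s) & (t < iv.end_s)] = iv.label
        return out

    def mask(self, times_s: np.ndarray, label: str) -> np.ndarray:
        """Boolean mask of samples whose prompt label equals ``label``."""
        if label not in VALID_LABELS:
            raise ValueError(f"unknown prompt label {label!r}")
        return self.labels_at(times_s) == label

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "total_duration_s": self.total_duration_s,
            "intervals": [
                {"start_s": iv.start_s, "end_s": iv.end_s, "label": iv.label}
                for iv in self.intervals
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PromptSchedule":
        ivs = tuple(
            PromptInterval(float(iv["start_s"]), float(iv["end_s"]), str(iv["label"]))
            for iv in d["intervals"]
        )
        return cls(intervals=ivs, total_duration_s=float(d["total_duration_s"]))


def make_prompt_schedule(
    duration_s: float,
    n_movements: int,
    duration_range_s: tuple[float, float] = (5.0, 10.0),
    seed: int = 0,
    label: str = "movement",
    min_gap_s: float = 2.0,
) -> PromptSchedule:
    """Interleave ``n_movements`` prompts of i.i.d. uniform length with rest.

    Prompt durations are drawn uniformly from ``duration_range_s``; the
    remaining session time is split into the n+1 rest gaps (each at least
    ``min_gap_s``) by a symmetric Dirichlet draw.  Deterministic for a fixed
    seed.  Raises if the requested prompts cannot fit in ``duration_s``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if n_movements < 0:
        raise ValueError("n_movements must be >= 0")
    if n_movements == 0:
        return PromptSchedule(intervals=(), total_duration_s=float(duration_s))
    lo, hi = duration_range_s
    if not (0 < lo <= hi < duration_s):
        raise ValueError("duration_range_s must satisfy 0 < lo <= hi < duration_s")
    rng = substream(seed, "schedule")
    durations = rng.uniform(lo, hi, size=n_movements)
    slack = duration_s - float(durations.sum())
    n_gaps = n_movements + 1
    if slack < n_gaps * min_gap_s:
        raise ValueError(
            f"infeasible schedule: {n_movements} prompts totalling "
            f"{durations.sum():.1f} s plus {n_gaps} rest gaps of >= {min_gap_s} s "
            f"do not fit in {duration_s} s"
        )
    gaps = min_gap_s + (slack - n_gaps * min_gap_s) * rng.dirichlet(np.ones(n_gaps))
    intervals = []
    cursor = 0.0
    for i in range(n_movements):
        cursor += gaps[i]
        intervals.append(PromptInterval(cursor, cursor + durations[i], label))
        cursor += durations[i]
    return PromptSchedule(intervals=tuple(intervals), total_duration_s=float(duration_s))
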