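"""Typed time intervals and the four-tier segmentation container.

A segmentation of a recording is a partition of [0, duration) into
voiced speech, unvoiced speech and pause intervals, plus respiration
intervals that each lie inside a pause ("pauses include all
respirations").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASSES = ("voiced", "unvoiced", "pause", "respiration")

FRAME_STEP_S = 0.005


@dataclass(frozen=True)
class LabeledInterval:
    """Half-open interval [start_s, end_s) with a class label."""

    start_s: float
    end_s: float
    klass: str

    def __post_init__(self):
        if self.klass not in CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")
        if not (self.end_s > self.start_s >= 0):
            raise ValueError(
                f"invalid interval [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def mid_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def _check_sorted_disjoint(ivs, name):
    prev_end = -1.0
    for iv in ivs:
        if iv.start_s < prev_end - 1e-9:
            raise ValueError(f"{name} tier has overlapping/unsorted intervals")
        prev_end = iv.end_s


@dataclass
class SegmentTiers:
    """Ordered interval lists per class for one recording."""

    voiced: list = field(default_factory=list)
    unvoiced: list = field(default_factory=list)
    pause: list = field(default_factory=list)
    respiration: list = field(default_factory=list)
    duration_s: float = 0.0

    def tier(self, klass: str) -> list:
        return getattr(self, klass)

    def all_speech_intervals(self) -> list:
        """Voiced, unvoiced and pause intervals in time order."""
        ivs = list(self.voiced) + list(self.unvoiced) + list(self.pause)
        return sorted(ivs, key=lambda iv: iv.start_s)

    def validate(self, strict_tiling: bool = True, atol: float = 1e-6) -> None:
        """Raise ValueError unless the structural invariants hold."""
        for name in CLASSES:
            _check_sorted_disjoint(sorted(self.tier(name),
                                          key=lambda iv: iv.start_s), name)
        ivs = self.all_speech_intervals()
        if strict_tiling:
            if not ivs:
                raise ValueError("empty segmentation")
            t = 0.0
            for iv in ivs:
                if abs(iv.start_s - t) > atol:
                    raise ValueError(
                        f"gap/overlap at {t:.4f}s vs interval start {iv.start_s:.4f}s")
                t = iv.end_s
            if abs(t - self.duration_s) > atol:
                raise ValueError(
                    f"tiling ends at {t:.4f}s, duration {self.duration_s:.4f}s")
        for r in self.respiration:
            host = [p for p in self.pause
                    if p.start_s <= r.start_s + atol and r.end_s <= p.end_s + atol]
            if not host:
                raise ValueError(
                    f"respiration [{r.start_s:.3f},{r.end_s:.3f}) outside any pause")

    def to_flat(self) -> list:
        """All intervals (voiced/unvoiced/pause/respiration) time-ordered."""
        out = []
        for name in CLASSES:
            out.extend(self.tier(name))
        return sorted(out, key=lambda iv: (iv.start_s, iv.klass))

    def class_at(self, times: np.ndarray, with_respiration: bool = False) -> np.ndarray:
        """Class index per query time (0 voiced, 1 unvoiced, 2 pause[, 3 resp])."""
        times = np.asarray(times, dtype=float)
        out = np.full(len(times), 2, dtype=int)  # default pause
        order = ["voiced", "unvoiced"] + (["respiration"] if with_respiration else [])
        codes = {"voiced": 0, "unvoiced": 1, "pause": 2, "respiration": 3}
        for name in order:
            for iv in self.tier(name):
                sel = (times >= iv.start_s) & (times < iv.end_s)
                out[sel] = codes[name]
        return out
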