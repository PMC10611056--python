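"""Opt-in per-stage wall-clock accounting for the sifting pipeline.

The sifting process decomposes into a fixed sequence of stages (extrema
detection, tridiagonal solve, spline coefficients, interpolation, envelope
mean, residue update).  A :class:`StageProfiler`, when installed, accumulates
wall-clock time per stage across an entire run; when none is installed the
timers are no-ops with negligible overhead.
"""

from __future__ import annotations

import time
from contextlib import contextmanager

STAGES = (
    "extrema",
    "tridiagonal_solve",
    "spline_coefficients",
    "interpolation",
    "envelope_mean",
    "residue_update",
)

_active: "StageProfiler | None" = None


class StageProfiler:
    """Accumulates wall-clock seconds and call counts per sifting stage."""

    def __init__(self) -> None:
        self.seconds: dict[str, float] = {s: 0.0 for s in STAGES}
        self.calls: dict[str, int] = {s: 0 for s in STAGES}

    def add(self, stage: str, dt: float) -> None:
        self.seconds[stage] = self.seconds.get(stage, 0.0) + dt
        self.calls[stage] = self.calls.get(stage, 0) + 1

    def as_dict(self) -> dict:
        return {
            s: {"seconds": self.seconds[s], "calls": self.calls[s]}
            for s in self.seconds
        }


def set_profiler(profiler: StageProfiler | None) -> None:
    """Install (or clear, with None) the process-wide stage profiler."""
    global _active
    _active = profiler


@contextmanager
def stage_timer(stage: str):
    if _active is None:
        yield
        return
    t0 = time.perf_counter()
    try:
        yield
    finally:
        _active.add(stage, time.perf_counter() - t0)
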