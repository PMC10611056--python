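"""Sifting, the local-mean operator M(.), and plain empirical mode decomposition.

EMD peels a signal into intrinsic mode functions (IMFs) by repeated
*sifting*: subtract the midline of the upper/lower spline envelopes from a
working copy until it behaves like a narrow-band oscillation, store it as a
mode, subtract it from the running signal, and repeat until the residue has
too few extrema to oscillate.  The decomposition telescopes, so the modes
plus the final residue always sum back to the input exactly (to rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._profile import stage_timer
from .envelopes import (
    InsufficientExtremaError,
    SignalChannel,
    _as_samples,
    build_envelope_pair,
    find_extrema,
    mean_envelope,
)

__all__ = ["Mode", "Decomposition", "SiftConfig", "sift", "local_mean", "emd"]


@dataclass
class SiftConfig:
    """Controls the inner sifting loop.

    Parameters
    ----------
    n_iterations : int
        Number of sifting rounds S under the default fixed-count stop
        (also the cap under the threshold stop).  Fixed-count sifting is
        the reproducible choice and the package default.
    stop_mode : {"fixed", "threshold"}
        "fixed" always runs S rounds; "threshold" additionally stops when
        the relative change of the candidate between consecutive rounds,
        ||prev - cur||^2 / ||prev||^2, drops below ``threshold`` (a
        Cauchy-style criterion).
    threshold : float
        Relative-change tolerance for the threshold stop.
    """

    n_iterations: int = 10
    stop_mode: str = "fixed"
    threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.stop_mode not in ("fixed", "threshold"):
            raise ValueError(f"unknown stop_mode: {self.stop_mode!r}")


@dataclass
class Mode:
    """One extracted intrinsic mode function (or a flagged monotonic remnant)."""

    samples: np.ndarray
    monotonic: bool = False


@dataclass
class Decomposition:
    """Ordered modes plus the final residue of one channel.

    Invariant: sum(modes) + residue reconstructs the input to rounding.
    """

    modes: list[Mode]
    residue: np.ndarray
    signal: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def mode_matrix(self) -> np.ndarray:
        """Modes stacked as a K x N array."""
        if not self.modes:
            return np.empty((0, self.residue.size))
        return np.stack([m.samples for m in self.modes])

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for m in self.modes:
            out += m.samples
        return out


def sift(signal, config: SiftConfig | None = None) -> Mode:
    """Extract one candidate IMF by iterative envelope-mean subtraction.

    Runs up to S rounds of (extrema -> envelopes -> midline -> subtract)
    on a working copy of the signal.  If at any round the working copy has
    fewer than 2 maxima or 2 minima, it is returned as-is with
    ``monotonic=True`` — a valid outcome, not an error.
    """
    if config is None:
        config = SiftConfig()
    x = _as_samples(signal)
    work = x.copy()
    for _ in range(config.n_iterations):
        extrema = find_extrema(work)
        if extrema.n_maxima < 2 or extrema.n_minima < 2:
            return Mode(samples=work, monotonic=True)
        m = mean_envelope(build_envelope_pair(work, extrema))
        with stage_timer("residue_update"):
            # Store each stage's output at the working dtype (float32 under
            # the single-precision pipeline, float64 otherwise).
            candidate = (work - m).astype(work.dtype, copy=False)
        if config.stop_mode == "threshold":
            denom = float(np.dot(work, work))
            change = float(np.dot(m, m)) / denom if denom > 0 else 0.0
            work = candidate
            if change < config.threshold:
                break
        else:
            work = candidate
    return Mode(samples=work, monotonic=False)


def local_mean(signal, config: SiftConfig | None = None) -> np.ndarray:
    """The local-mean operator M(x): what sifting removes from the signal.

    Defined as ``x - sift(x)``, so ``local_mean(x) == x - sift(x)`` holds
    bitwise by construction (note that re-adding, ``sift(x) + M(x)``, can
    differ from x in the last ulp, as any floating-point round trip can).
    For a monotonic signal M(x) is zero.
    """
    x = _as_samples(signal)
    return x - sift(x, config).samples


def emd(signal, max_modes: int = 12, config: SiftConfig | None = None) -> Decomposition:
    """Full empirical mode decomposition.

    Repeatedly sifts the running residue and subtracts each extracted mode,
    stopping when the residue has fewer than 2 maxima or 2 minima (no
    further oscillation) or ``max_modes`` modes have been extracted.

    Parameters
    ----------
    signal : SignalChannel or array_like
        Input time series.
    max_modes : int
        Upper bound K on the number of extracted modes.
    config : SiftConfig, optional
        Inner-loop settings; defaults to 10 fixed sifting rounds.

    Returns
    -------
    Decomposition
        Modes in extraction order (fast to slow) plus the final residue.
    """
    if max_modes < 1:
        raise ValueError("max_modes must be >= 1")
    if config is None:
        config = SiftConfig()
    x = _as_samples(signal)
    residue = x.copy()
    modes: list[Mode] = []
    while len(modes) < max_modes:
        extrema = find_extrema(residue)
        if extrema.n_maxima < 2 or extrema.n_minima < 2:
            break
        mode = sift(residue, config)
        modes.append(mode)
        with stage_timer("residue_update"):
            residue = (residue - mode.samples).astype(x.dtype, copy=False)
    return Decomposition(modes=modes, residue=residue, signal=x)
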