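"""Validation metrics: similarity index, reconstruction error, IMF checks.

The similarity index between a recovered mode and a reference component is
the normalized covariance rho = |cov(x, y)| / sqrt(var(x) var(y)).  Since a
mode's polarity is sign-ambiguous, the absolute value maps the Pearson-type
ratio onto [0, 1]; the raw signed value is available via ``signed=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envelopes import InsufficientExtremaError, _as_samples, build_envelope_pair, find_extrema, mean_envelope

__all__ = [
    "SimilarityReport",
    "IMFValidity",
    "similarity_index",
    "reconstruction_error",
    "imf_validity",
    "match_modes",
]


@dataclass
class SimilarityPair:
    """One (mode, reference) match with its similarity rho in [0, 1]."""

    mode_index: int
    reference_index: int
    rho: float


@dataclass
class SimilarityReport:
    """Best-matching mode per reference component."""

    pairs: list[SimilarityPair]

    @property
    def mean_similarity(self) -> float:
        return float(np.mean([p.rho for p in self.pairs])) if self.pairs else float("nan")

    def to_dict(self) -> dict:
        return {
            "pairs": [
                {"mode": p.mode_index, "reference": p.reference_index, "rho": p.rho}
                for p in self.pairs
            ],
            "mean_similarity": self.mean_similarity,
        }


@dataclass
class IMFValidity:
    """Counts behind the two defining IMF conditions.

    A well-formed IMF has (i) extrema and zero-crossing counts differing
    by at most one and (ii) a near-zero local mean; ``mean_envelope_rms``
    quantifies (ii) and is NaN when the mode has too few extrema for an
    envelope to exist.
    """

    n_extrema: int
    n_zero_crossings: int
    mean_envelope_rms: float

    @property
    def extrema_zero_crossing_gap(self) -> int:
        return abs(self.n_extrema - self.n_zero_crossings)


def similarity_index(x, y, signed: bool = False) -> float:
    """Normalized covariance of two equal-length signals.

    Parameters
    ----------
    x, y : array_like
        Equal-length vectors, both nonconstant.
    signed : bool
        Return the raw Pearson-type value in [-1, 1] instead of its
        absolute value.

    Raises
    ------
    ValueError
        On length mismatch or a (near-)constant input, whose variance is
        zero and leaves the index undefined.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 2:
        raise ValueError("similarity index needs two equal-length vectors of length >= 2")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    var_x = float(np.dot(xc, xc))
    var_y = float(np.dot(yc, yc))
    if var_x == 0.0 or var_y == 0.0:
        raise ValueError("similarity index undefined for a constant input (zero variance)")
    rho = float(np.dot(xc, yc)) / np.sqrt(var_x * var_y)
    return rho if signed else abs(rho)


def reconstruction_error(original, decomposition) -> float:
    """Max-abs reconstruction error of a decomposition, relative to the input.

    ``max |x - (sum modes + residue)| / max |x|``; for an identically zero
    input the absolute error is returned instead.
    """
    x = _as_samples(original)
    recon = decomposition.reconstruct()
    if recon.shape != x.shape:
        raise ValueError("decomposition length does not match the original signal")
    err = float(np.max(np.abs(x - recon)))
    scale = float(np.max(np.abs(x)))
    return err if scale == 0.0 else err / scale


def count_zero_crossings(x) -> int:
    """Strict sign changes, ignoring exactly-zero samples."""
    v = np.asarray(x, dtype=float)
    s = np.sign(v)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def imf_validity(mode) -> IMFValidity:
    """Measure how closely a mode satisfies the IMF conditions."""
    x = _as_samples(mode) if not hasattr(mode, "samples") else np.asarray(mode.samples)
    ext = find_extrema(x)
    n_extrema = ext.n_maxima + ext.n_minima
    nzc = count_zero_crossings(x)
    try:
        m = mean_envelope(build_envelope_pair(x, ext))
        rms = float(np.sqrt(np.mean(m**2)))
    except InsufficientExtremaError:
        rms = float("nan")
    return IMFValidity(n_extrema=n_extrema, n_zero_crossings=nzc, mean_envelope_rms=rms)


def match_modes(decomposition, references) -> SimilarityReport:
    """Match each reference component to its most similar extracted mode.

    For every reference vector, reports the single mode maximizing the
    similarity index; ties break toward the lower mode index.  Modes with
    zero variance (e.g. zero-padded levels) are skipped.
    """
    mode_arrays = [np.asarray(m.samples, dtype=float) for m in decomposition.modes]
    if not mode_arrays:
        raise ValueError("decomposition has no modes to match")
    refs = [np.asarray(r, dtype=float) for r in references]
    if not refs:
        raise ValueError("need at least one reference component")
    pairs: list[SimilarityPair] = []
    for j, ref in enumerate(refs):
        best_rho, best_idx = -1.0, -1
        for i, m in enumerate(mode_arrays):
            if np.ptp(m) == 0.0:
                continue
            rho = similarity_index(m, ref)
            if rho > best_rho:
                best_rho, best_idx = rho, i
        if best_idx < 0:
            raise ValueError("all modes are constant; nothing to match")
        pairs.append(SimilarityPair(mode_index=best_idx, reference_index=j, rho=best_rho))
    return SimilarityReport(pairs=pairs)
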