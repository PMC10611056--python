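"""Sifting-stage primitives: extrema detection and cubic-spline envelopes.

Each sifting iteration of empirical mode decomposition is built from a
fixed pipeline of stages: detect the local extrema of the working signal,
fit a natural cubic spline through the maxima (upper envelope) and another
through the minima (lower envelope), evaluate both at every sample
position, and average them.  The spline fit reduces to a diagonally
dominant tridiagonal linear system per envelope, solved here with the
Thomas algorithm (no pivoting required).

These primitives are deliberately implemented from first principles —
they are the computational core of the package, and the higher-level
decomposers are thin loops over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._profile import stage_timer

__all__ = [
    "SignalChannel",
    "ExtremaSet",
    "TridiagonalSystem",
    "SplineSegmentCoefficients",
    "EnvelopePair",
    "InsufficientExtremaError",
    "find_extrema",
    "solve_tridiagonal",
    "natural_spline_coefficients",
    "evaluate_spline",
    "build_envelope_pair",
    "mean_envelope",
]


class InsufficientExtremaError(ValueError):
    """Raised when a signal has too few extrema to build both envelopes.

    The EMD outer loop consumes this as the "residue is monotonic" signal:
    envelope construction needs at least two maxima and two minima.
    """


@dataclass
class SignalChannel:
    """One real-valued, uniformly sampled time series.

    Parameters
    ----------
    samples : array_like of float, shape (N,)
        Signal amplitudes; must be finite and non-empty.  Decomposition
        additionally needs enough samples to host interior extrema; the
        extrema detector enforces N >= 3 at that point.
    sampling_rate : float, optional
        Sampling rate in Hz.  Only used to express results in physical
        frequency units; the decomposition itself is rate-agnostic.
    label : str, optional
        Channel name (e.g. an EEG electrode label).
    """

    samples: np.ndarray
    sampling_rate: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if not np.issubdtype(self.samples.dtype, np.floating):
            self.samples = self.samples.astype(float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 1:
            raise ValueError("signal is empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains NaN or infinite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class ExtremaSet:
    """Interior local maxima and minima of a signal.

    Positions are 0-based sample indices, strictly increasing; values are
    the signal amplitudes at those positions.  Runs of equal samples
    (plateaus) count as a single extremum at the run's first index.
    """

    max_positions: np.ndarray
    max_values: np.ndarray
    min_positions: np.ndarray
    min_values: np.ndarray

    @property
    def n_maxima(self) -> int:
        return self.max_positions.size

    @property
    def n_minima(self) -> int:
        return self.min_positions.size


@dataclass
class TridiagonalSystem:
    """A tridiagonal linear system A x = rhs.

    ``main_diagonal`` has length n, ``sub_diagonal`` and ``super_diagonal``
    length n - 1.  The natural-spline construction yields a strictly
    diagonally dominant system, so the Thomas algorithm needs no pivoting.
    """

    sub_diagonal: np.ndarray
    main_diagonal: np.ndarray
    super_diagonal: np.ndarray
    rhs: np.ndarray

    def __post_init__(self) -> None:
        def _f(v):
            a = np.atleast_1d(np.asarray(v))
            return a if np.issubdtype(a.dtype, np.floating) else a.astype(float)

        self.sub_diagonal = _f(self.sub_diagonal)
        self.main_diagonal = _f(self.main_diagonal)
        self.super_diagonal = _f(self.super_diagonal)
        self.rhs = _f(self.rhs)
        n = self.main_diagonal.size
        if self.rhs.size != n:
            raise ValueError("rhs length must equal main diagonal length")
        if n >= 1 and (self.sub_diagonal.size != max(n - 1, 0) or self.super_diagonal.size != max(n - 1, 0)):
            # Allow the degenerate 1x1 system with empty off-diagonals.
            if not (n == 1 and self.sub_diagonal.size == 0 and self.super_diagonal.size == 0):
                raise ValueError("off-diagonals must have length n - 1")

    def to_dense(self) -> np.ndarray:
        n = self.main_diagonal.size
        a = np.zeros((n, n))
        a[np.arange(n), np.arange(n)] = self.main_diagonal
        if n > 1:
            a[np.arange(1, n), np.arange(n - 1)] = self.sub_diagonal
            a[np.arange(n - 1), np.arange(1, n)] = self.super_diagonal
        return a


@dataclass
class SplineSegmentCoefficients:
    """Piecewise-cubic coefficients of an interpolating spline.

    Segment ``j`` covers ``[knot_positions[j], knot_positions[j+1])`` and
    evaluates as ``a[j] + b[j] dt + c[j] dt^2 + d[j] dt^3`` with
    ``dt = t - knot_positions[j]``.
    """

    knot_positions: np.ndarray
    a: np.ndarray  # constant terms (= knot values at left knots)
    b: np.ndarray  # linear terms
    c: np.ndarray  # quadratic terms
    d: np.ndarray  # cubic terms
    knot_values: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_segments(self) -> int:
        return self.a.size


@dataclass
class EnvelopePair:
    """Upper and lower spline envelopes evaluated at every sample."""

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self) -> None:
        if self.upper.shape != self.lower.shape:
            raise ValueError("upper and lower envelopes must have equal length")


def _as_samples(signal) -> np.ndarray:
    """Extract a floating-point sample array, preserving float32 inputs."""
    if isinstance(signal, SignalChannel):
        return signal.samples
    x = np.asarray(signal)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    return x


def find_extrema(signal) -> ExtremaSet:
    """Locate the interior local maxima and minima of a signal.

    A sample (or plateau of equal samples) is a maximum when it exceeds
    both neighbouring runs, a minimum when it is below both; plateaus are
    reported at their first index.  Endpoints never count as extrema.

    Parameters
    ----------
    signal : SignalChannel or array_like
        The signal; at least 3 samples, all finite.

    Returns
    -------
    ExtremaSet
        Sorted positions and values.  A constant signal yields empty sets.
    """
    x = _as_samples(signal)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 samples to detect extrema, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("cannot detect extrema: signal contains NaN or infinite samples")

    with stage_timer("extrema"):
        # Compress plateaus: keep the first index of each run of equal values.
        keep = np.empty(n, dtype=bool)
        keep[0] = True
        np.not_equal(x[1:], x[:-1], out=keep[1:])
        run_starts = np.flatnonzero(keep)
        v = x[run_starts]
        if v.size < 3:
            empty_i = np.empty(0, dtype=np.intp)
            empty_f = np.empty(0, dtype=float)
            return ExtremaSet(empty_i, empty_f, empty_i.copy(), empty_f.copy())
        mid = v[1:-1]
        is_max = (mid > v[:-2]) & (mid > v[2:])
        is_min = (mid < v[:-2]) & (mid < v[2:])
        max_pos = run_starts[1:-1][is_max]
        min_pos = run_starts[1:-1][is_min]
    return ExtremaSet(max_pos, x[max_pos], min_pos, x[min_pos])


def solve_tridiagonal(system: TridiagonalSystem) -> np.ndarray:
    """Solve a tridiagonal system with the Thomas algorithm (no pivoting).

    Assumes diagonal dominance, as guaranteed by the natural-spline
    construction; a (near-)zero pivot raises with the offending row index.
    """
    with stage_timer("tridiagonal_solve"):
        lower = system.sub_diagonal
        diag = system.main_diagonal
        upper = system.super_diagonal
        n = diag.size
        dtype = diag.dtype
        cp = np.empty(max(n - 1, 0), dtype=dtype)
        dp = np.empty(n, dtype=dtype)
        tiny = np.finfo(dtype).tiny
        piv = diag[0]
        if abs(piv) <= tiny:
            raise ZeroDivisionError("zero pivot in tridiagonal solve at row 0")
        dp[0] = system.rhs[0] / piv
        if n > 1:
            cp[0] = upper[0] / piv
        for i in range(1, n):
            piv = diag[i] - lower[i - 1] * cp[i - 1]
            if abs(piv) <= tiny:
                raise ZeroDivisionError(f"zero pivot in tridiagonal solve at row {i}")
            dp[i] = (system.rhs[i] - lower[i - 1] * dp[i - 1]) / piv
            if i < n - 1:
                cp[i] = upper[i] / piv
        x = np.empty(n, dtype=dtype)
        x[-1] = dp[-1]
        for i in range(n - 2, -1, -1):
            x[i] = dp[i] - cp[i] * x[i + 1]
    return x


def natural_spline_coefficients(knot_positions, knot_values) -> SplineSegmentCoefficients:
    """Fit a natural cubic spline through the given knots.

    The second derivatives at the interior knots solve a strictly
    diagonally dominant tridiagonal system; natural boundary conditions
    set the second derivative to zero at both end knots.  With two knots
    the spline degenerates to the connecting straight line.

    Parameters
    ----------
    knot_positions : array_like
        Strictly increasing positions (sample indices; need not be
        equispaced, since boundary-mirrored knots are irregular).
    knot_values : array_like
        Signal values at the knots.

    Returns
    -------
    SplineSegmentCoefficients
        Per-segment cubic coefficients in the local variable
        ``t - knot_positions[j]``.
    """
    t = np.asarray(knot_positions, dtype=float)
    y = np.asarray(knot_values)
    if not np.issubdtype(y.dtype, np.floating):
        y = y.astype(float)
    m = t.size
    if m < 2:
        raise ValueError(f"need at least 2 knots for spline interpolation, got {m}")
    if y.size != m:
        raise ValueError("knot_positions and knot_values must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knot positions must be strictly increasing")

    with stage_timer("spline_coefficients"):
        h = np.diff(t)
        slopes = np.diff(y) / h
        # Second derivatives M at the knots; natural boundary M[0] = M[-1] = 0.
        second = np.zeros(m, dtype=y.dtype)
        if m > 2:
            sys = TridiagonalSystem(
                sub_diagonal=h[1:-1],
                main_diagonal=2.0 * (h[:-1] + h[1:]),
                super_diagonal=h[1:-1],
                rhs=6.0 * np.diff(slopes),
            )
            second[1:-1] = solve_tridiagonal(sys)
        a = y[:-1].copy()
        b = slopes - h * (2.0 * second[:-1] + second[1:]) / 6.0
        c = second[:-1] / 2.0
        d = np.diff(second) / (6.0 * h)
    return SplineSegmentCoefficients(
        knot_positions=t, a=a, b=b, c=c, d=d, knot_values=y
    )


def evaluate_spline(
    coeffs: SplineSegmentCoefficients,
    query_positions,
    boundary_policy: str = "extrapolate",
) -> np.ndarray:
    """Evaluate a piecewise cubic at the given positions.

    Positions inside the knot span use their segment's cubic; positions
    outside are handled by ``boundary_policy``:

    - ``"extrapolate"``: continue the first/last segment's cubic (the
      default; envelopes built with mirrored boundary knots never hit it).
    - ``"clamp"``: hold the end-knot values constant.
    """
    q = np.asarray(query_positions, dtype=float)
    with stage_timer("interpolation"):
        t = coeffs.knot_positions
        seg = np.clip(np.searchsorted(t, q, side="right") - 1, 0, coeffs.n_segments - 1)
        dt = q - t[seg]
        out = coeffs.a[seg] + dt * (coeffs.b[seg] + dt * (coeffs.c[seg] + dt * coeffs.d[seg]))
        if boundary_policy == "clamp":
            out = np.where(q < t[0], coeffs.knot_values[0], out)
            out = np.where(q > t[-1], coeffs.knot_values[-1], out)
        elif boundary_policy != "extrapolate":
            raise ValueError(f"unknown boundary policy: {boundary_policy!r}")
    return out


def _mirror_knots(positions: np.ndarray, values: np.ndarray, n: int):
    """Mirror the two extrema nearest each end across the signal boundary."""
    k = min(2, positions.size)
    left_pos = -positions[:k][::-1]
    left_val = values[:k][::-1]
    right_pos = 2 * (n - 1) - positions[-k:][::-1]
    right_val = values[-k:][::-1]
    ext_pos = np.concatenate([left_pos, positions, right_pos])
    ext_val = np.concatenate([left_val, values, right_val])
    return ext_pos, ext_val


def _reflect(positions: np.ndarray, values: np.ndarray, about: float):
    """Reflect knots about a pivot position, reversing their order."""
    return (2 * about - positions)[::-1], values[::-1]


def _extend_extrema(x: np.ndarray, extrema: "ExtremaSet", n_mirror: int = 2):
    """Symmetric boundary extension of the extrema, endpoint-aware.

    Extrema are reflected about the outermost extremum at each end — which
    preserves the local inter-extrema spacing — unless the record endpoint
    pokes outside the implied envelope (e.g. the signal keeps rising past
    the last maximum), in which case the endpoint itself is adopted as an
    extremum and reflection happens about it.  If reflection about an
    extremum fails to cover the record, it falls back to reflecting about
    the endpoint.  This is the standard end-effect mitigation used by the
    widely circulated reference EMD codes.

    Returns extended (max_positions, max_values, min_positions, min_values)
    whose spans cover [0, n-1].
    """
    n = x.size
    mxp = extrema.max_positions.astype(float)
    mxv = extrema.max_values
    mnp = extrema.min_positions.astype(float)
    mnv = extrema.min_values
    k = n_mirror

    # Left end.
    if mxp[0] < mnp[0]:  # first extremum is a maximum
        if x[0] > mnv[0]:  # signal starts above the first minimum: pivot on the max
            lmax = _reflect(mxp[1 : k + 1], mxv[1 : k + 1], mxp[0])
            lmin = _reflect(mnp[:k], mnv[:k], mxp[0])
        else:  # endpoint is the effective minimum
            lmax = _reflect(mxp[:k], mxv[:k], 0.0)
            lmin = _reflect(
                np.concatenate([[0.0], mnp[: k - 1]]),
                np.concatenate([[x[0]], mnv[: k - 1]]),
                0.0,
            )
    else:  # first extremum is a minimum
        if x[0] < mxv[0]:
            lmin = _reflect(mnp[1 : k + 1], mnv[1 : k + 1], mnp[0])
            lmax = _reflect(mxp[:k], mxv[:k], mnp[0])
        else:
            lmin = _reflect(mnp[:k], mnv[:k], 0.0)
            lmax = _reflect(
                np.concatenate([[0.0], mxp[: k - 1]]),
                np.concatenate([[x[0]], mxv[: k - 1]]),
                0.0,
            )
    # Fallback: the pivot was too far in; reflect about the endpoint instead.
    if lmax[0].size == 0 or lmax[0][0] > 0:
        lmax = _reflect(mxp[:k], mxv[:k], 0.0)
    if lmin[0].size == 0 or lmin[0][0] > 0:
        lmin = _reflect(mnp[:k], mnv[:k], 0.0)

    # Right end (mirror image of the logic above).
    end = float(n - 1)
    if mxp[-1] > mnp[-1]:  # last extremum is a maximum
        if x[-1] > mnv[-1]:
            rmax = _reflect(mxp[-k - 1 : -1], mxv[-k - 1 : -1], mxp[-1])
            rmin = _reflect(mnp[-k:], mnv[-k:], mxp[-1])
        else:
            rmax = _reflect(mxp[-k:], mxv[-k:], end)
            rmin = _reflect(
                np.concatenate([mnp[len(mnp) - (k - 1) :], [end]]),
                np.concatenate([mnv[len(mnv) - (k - 1) :], [x[-1]]]),
                end,
            )
    else:
        if x[-1] < mxv[-1]:
            rmin = _reflect(mnp[-k - 1 : -1], mnv[-k - 1 : -1], mnp[-1])
            rmax = _reflect(mxp[-k:], mxv[-k:], mnp[-1])
        else:
            rmin = _reflect(mnp[-k:], mnv[-k:], end)
            rmax = _reflect(
                np.concatenate([mxp[len(mxp) - (k - 1) :], [end]]),
                np.concatenate([mxv[len(mxv) - (k - 1) :], [x[-1]]]),
                end,
            )
    if rmax[0].size == 0 or rmax[0][-1] < end:
        rmax = _reflect(mxp[-k:], mxv[-k:], end)
    if rmin[0].size == 0 or rmin[0][-1] < end:
        rmin = _reflect(mnp[-k:], mnv[-k:], end)

    def _assemble(left, mid_p, mid_v, right):
        pos = np.concatenate([left[0], mid_p, right[0]])
        val = np.concatenate([left[1], mid_v, right[1]])
        # Drop any duplicate/non-increasing positions introduced by pivoting
        # on an extremum that coincides with a reflected knot.
        keep = np.ones(pos.size, dtype=bool)
        keep[1:] = np.diff(pos) > 0
        return pos[keep], val[keep]

    up_pos, up_val = _assemble(lmax, mxp, mxv, rmax)
    lo_pos, lo_val = _assemble(lmin, mnp, mnv, rmin)
    return up_pos, up_val, lo_pos, lo_val


def build_envelope_pair(
    signal,
    extrema: ExtremaSet | None = None,
    boundary_policy: str = "mirror",
) -> EnvelopePair:
    """Build the upper and lower cubic-spline envelopes of a signal.

    The upper envelope interpolates the maxima, the lower the minima, each
    evaluated at all N integer sample positions.  Under the default
    ``"mirror"`` policy the two extrema nearest each end are reflected
    across the signal boundary before fitting, so both envelopes are
    defined (without extrapolation) over the whole record.

    Raises
    ------
    InsufficientExtremaError
        If the signal has fewer than 2 maxima or fewer than 2 minima;
        the EMD driver treats this as a monotonic residue.
    """
    x = _as_samples(signal)
    n = x.size
    if extrema is None:
        extrema = find_extrema(x)
    if extrema.n_maxima < 2 or extrema.n_minima < 2:
        raise InsufficientExtremaError(
            f"envelope needs >=2 maxima and >=2 minima, got "
            f"{extrema.n_maxima} maxima / {extrema.n_minima} minima"
        )
    if boundary_policy == "mirror":
        up_pos, up_val, lo_pos, lo_val = _extend_extrema(x, extrema)
        eval_policy = "extrapolate"
    elif boundary_policy == "mirror-endpoint":
        up_pos, up_val = _mirror_knots(extrema.max_positions, extrema.max_values, n)
        lo_pos, lo_val = _mirror_knots(extrema.min_positions, extrema.min_values, n)
        eval_policy = "extrapolate"
    elif boundary_policy in ("extrapolate", "clamp"):
        up_pos, up_val = extrema.max_positions, extrema.max_values
        lo_pos, lo_val = extrema.min_positions, extrema.min_values
        eval_policy = boundary_policy
    else:
        raise ValueError(f"unknown boundary policy: {boundary_policy!r}")

    grid = np.arange(n)
    upper = evaluate_spline(natural_spline_coefficients(up_pos, up_val), grid, eval_policy)
    lower = evaluate_spline(natural_spline_coefficients(lo_pos, lo_val), grid, eval_policy)
    return EnvelopePair(upper=upper, lower=lower)


def mean_envelope(pair: EnvelopePair) -> np.ndarray:
    """Elementwise midline (upper + lower) / 2 of an envelope pair."""
    if pair.upper.shape != pair.lower.shape:
        raise ValueError("envelope length mismatch")
    with stage_timer("envelope_mean"):
        out = 0.5 * (pair.upper + pair.lower)
    return out
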