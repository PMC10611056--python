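"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the dumb way — per-sample scans,
dense linear algebra, two-pass statistics — and shares no code with the
package under test.
"""

from __future__ import annotations

import numpy as np


def brute_force_extrema(x):
    """Interior extrema by per-sample neighbour scan with plateau compression.

    Runs of equal samples count once, at the run's first index; endpoints
    never qualify.  Returns (max_positions, min_positions) as lists.
    """
    x = np.asarray(x, dtype=float)
    runs = [0]
    for j in range(1, len(x)):
        if x[j] != x[j - 1]:
            runs.append(j)
    v = [x[r] for r in runs]
    maxima, minima = [], []
    for j in range(1, len(runs) - 1):
        if v[j] > v[j - 1] and v[j] > v[j + 1]:
            maxima.append(runs[j])
        elif v[j] < v[j - 1] and v[j] < v[j + 1]:
            minima.append(runs[j])
    return maxima, minima


def dense_tridiagonal_solve(sub, main, sup, rhs):
    """Materialize the full matrix and solve densely."""
    n = len(main)
    a = np.zeros((n, n))
    for i in range(n):
        a[i, i] = main[i]
        if i > 0:
            a[i, i - 1] = sub[i - 1]
        if i < n - 1:
            a[i, i + 1] = sup[i]
    return np.linalg.solve(a, np.asarray(rhs, dtype=float))


def horner_spline_eval(knot_positions, a, b, c, d, queries):
    """Direct per-point Horner evaluation of piecewise cubic coefficients."""
    t = np.asarray(knot_positions, dtype=float)
    out = np.empty(len(queries))
    for idx, q in enumerate(queries):
        seg = int(np.searchsorted(t, q, side="right")) - 1
        seg = min(max(seg, 0), len(a) - 1)
        dt = q - t[seg]
        out[idx] = ((d[seg] * dt + c[seg]) * dt + b[seg]) * dt + a[seg]
    return out


def two_pass_std(x):
    """Population standard deviation via an explicit two-pass formula."""
    x = np.asarray(x, dtype=float)
    mu = sum(x) / len(x)
    return float(np.sqrt(sum((v - mu) ** 2 for v in x) / len(x)))


def two_pass_similarity(x, y):
    """abs(cov) / sqrt(var var) with explicit two-pass moments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = sum(x) / len(x), sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
    vx = sum((a - mx) ** 2 for a in x) / len(x)
    vy = sum((b - my) ** 2 for b in y) / len(y)
    return abs(cov) / np.sqrt(vx * vy)


def count_zero_crossings_oracle(x):
    """Sign changes, skipping exact zeros, by explicit scan."""
    signs = [1 if v > 0 else -1 for v in x if v != 0]
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def iterated_local_mean_decomposition(x, local_mean_fn, max_modes, has_oscillation_fn):
    """Sequential zero-noise oracle for the ensemble recursion.

    Repeatedly applies the supplied local-mean operator to the running
    residue and records the differences as modes — the reduction of the
    noise-assisted recursion when the noise amplitude is zero.
    """
    residue = np.asarray(x, dtype=float).copy()
    modes = []
    for _ in range(max_modes):
        if not has_oscillation_fn(residue):
            break
        nxt = local_mean_fn(residue)
        modes.append(residue - nxt)
        residue = nxt
    return modes, residue
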