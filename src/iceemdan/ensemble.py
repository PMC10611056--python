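"""Noise-assisted ensemble decompositions: EEMD and Improved CEEMDAN.

Plain EMD suffers from mode mixing on intermittent signals: one mode ends
up carrying several distinct oscillation scales.  Ensemble variants fight
this by decomposing many noise-contaminated copies (realizations) of the
signal and averaging.  EEMD averages complete independent decompositions,
which breaks exact invertibility.  Improved CEEMDAN (ICEEMDAN) instead
averages *inside* the recursion — at level k it perturbs the running
residue with the k-th EMD mode of white noise, scaled by
``beta_k = eps0 * std(residue)``, takes the ensemble-averaged local mean as
the next residue, and defines the mode as the difference of consecutive
residues.  The construction telescopes, so invertibility is exact by
design.

Batch operations are specified semantically: a batch call must be
observationally identical to the per-realization sequential loop.  The
realization matrix (I x N), noise-mode tensor (K x I x N) and output mode
matrix (K x N) layouts follow that data-parallel formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envelopes import _as_samples, find_extrema
from .sifting import Decomposition, Mode, SiftConfig, emd, local_mean

__all__ = [
    "RealizationBatch",
    "NoiseModeTensor",
    "EnsembleConfig",
    "ICEEMDANResult",
    "precompute_noise_modes",
    "noise_amplitude",
    "make_realizations",
    "batch_local_mean",
    "ensemble_average",
    "eemd",
    "iceemdan",
]


@dataclass
class RealizationBatch:
    """An I x N matrix of signal-plus-noise realizations, one per row."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(float)
        if self.values.ndim != 2:
            raise ValueError("realization batch must be a 2-D (I x N) array")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one realization")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("realization batch contains non-finite values")

    @property
    def n_realizations(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class NoiseModeTensor:
    """K x I x N tensor of precomputed noise modes.

    Entry ``[k, i]`` is the (k+1)-th EMD mode of white-noise realization i;
    realizations with fewer than K modes are zero-padded.  Each
    realization's noise stream derives from (seed, i), so the tensor is
    reproducible row-by-row independently of I.
    """

    values: np.ndarray
    seed: int | None = None

    @property
    def max_modes(self) -> int:
        return self.values.shape[0]

    @property
    def n_realizations(self) -> int:
        return self.values.shape[1]

    def level(self, k: int) -> np.ndarray:
        """The I x N slice of mode index k (0-based; mode k+1 of the noise)."""
        return self.values[k]


@dataclass
class EnsembleConfig:
    """All tunables of the ensemble algorithms.

    Parameters
    ----------
    n_realizations : int
        Ensemble size I.  A few hundred is typical; 500 by default.
    max_modes : int
        Mode cap K (12 by default, ample for 1000-sample records).
    sift : SiftConfig
        Inner sifting settings (default: 10 fixed rounds).
    noise_strength : float
        eps0, the scale factor for the added noise (0.2 by default).
    seed : int
        Master seed; realization i draws from the stream (seed, i).
    beta_rule : {"plain", "normalized-first-mode"}
        How the first-level noise amplitude beta_0 is formed:
        ``"plain"`` uses eps0 * std(x); ``"normalized-first-mode"``
        additionally divides by the standard deviation of each
        realization's first noise mode, equalising the effective
        signal-to-noise ratio across realizations.  Later levels always
        use beta_k = eps0 * std(r_k).
    precision : {"double", "single"}
        Working dtype of the pipeline.  "single" emulates an FP32 pipeline
        by storing every stage output in float32; "double" (the default)
        is what the numerical guarantees and tests assume.
    """

    n_realizations: int = 500
    max_modes: int = 12
    sift: SiftConfig = field(default_factory=SiftConfig)
    noise_strength: float = 0.2
    seed: int = 0
    beta_rule: str = "plain"
    precision: str = "double"

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.float32 if self.precision == "single" else np.float64)

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.max_modes < 1:
            raise ValueError("max_modes must be >= 1")
        if self.noise_strength < 0:
            raise ValueError("noise_strength must be >= 0")
        if self.beta_rule not in ("plain", "normalized-first-mode"):
            raise ValueError(f"unknown beta_rule: {self.beta_rule!r}")
        if self.precision not in ("double", "single"):
            raise ValueError(f"unknown precision: {self.precision!r}")


@dataclass
class ICEEMDANResult:
    """Output of the ICEEMDAN recursion for one channel.

    Satisfies ``d_k = r_{k-1} - r_k`` (with r_0 the input) and therefore
    ``sum(d_k) + r_K == input`` to rounding, for every configuration.
    """

    modes: list[Mode]
    residue: np.ndarray
    residues: list[np.ndarray]
    betas: list[float]
    signal: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def mode_matrix(self) -> np.ndarray:
        if not self.modes:
            return np.empty((0, self.residue.size))
        return np.stack([m.samples for m in self.modes])

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for m in self.modes:
            out += m.samples
        return out


def _noise_stream(seed: int, i: int) -> np.random.Generator:
    # Stream keyed on (seed, realization): independent of batch size and order.
    return np.random.default_rng([seed, i])


def precompute_noise_modes(config: EnsembleConfig, n_samples: int) -> NoiseModeTensor:
    """Decompose I seeded white-noise realizations into their first K modes.

    Draws w(i) ~ N(0, 1) of length N from the stream (seed, i), runs plain
    EMD with the configured sifting on each, and stacks the first K modes
    into a K x I x N tensor, zero-padding realizations that produce fewer
    than K modes.
    """
    k, i_total = config.max_modes, config.n_realizations
    tensor = np.zeros((k, i_total, n_samples), dtype=config.dtype)
    for i in range(i_total):
        w = _noise_stream(config.seed, i).standard_normal(n_samples).astype(config.dtype, copy=False)
        dec = emd(w, max_modes=k, config=config.sift)
        for j, mode in enumerate(dec.modes):
            tensor[j, i] = mode.samples
    return NoiseModeTensor(values=tensor, seed=config.seed)


def noise_amplitude(
    residue,
    noise_strength: float,
    beta_rule: str = "plain",
    noise_mode_std: float | None = None,
) -> float:
    """Noise amplitude beta = eps0 * std(residue), optionally normalized.

    Uses the population standard deviation.  Under the
    ``"normalized-first-mode"`` rule the result is further divided by
    ``noise_mode_std`` (the standard deviation of the corresponding noise
    mode), which must then be supplied.
    """
    r = np.asarray(residue, dtype=float)
    if r.size == 0:
        raise ValueError("cannot compute noise amplitude of an empty residue")
    beta = noise_strength * float(np.std(r))
    if beta_rule == "plain":
        return beta
    if beta_rule == "normalized-first-mode":
        if noise_mode_std is None:
            raise ValueError("normalized-first-mode rule requires noise_mode_std")
        return beta / noise_mode_std
    raise ValueError(f"unknown beta_rule: {beta_rule!r}")


def make_realizations(residue, noise_modes: np.ndarray, beta) -> RealizationBatch:
    """Form the batch r + beta * E_k(w(i)), one realization per row.

    ``beta`` may be a scalar or a per-realization vector of length I (the
    latter arises under the normalized first-mode rule).
    """
    r = _as_samples(residue)
    e = np.asarray(noise_modes)
    if e.ndim != 2 or e.shape[1] != r.size:
        raise ValueError(
            f"noise mode slice shape {e.shape} incompatible with residue length {r.size}"
        )
    beta = np.asarray(beta, dtype=float)
    if beta.ndim == 1:
        if beta.size != e.shape[0]:
            raise ValueError("per-realization beta length must equal I")
        beta = beta[:, None]
    values = (r[None, :] + beta * e).astype(r.dtype, copy=False)
    return RealizationBatch(values=values)


def batch_local_mean(batch: RealizationBatch, sift: SiftConfig | None = None) -> np.ndarray:
    """Local mean M(.) of every realization in a batch.

    Row i of the result equals ``local_mean(batch.values[i])`` exactly:
    the batch contract is observational equivalence with the sequential
    per-realization loop, which is also how it is implemented.
    """
    out = np.empty_like(batch.values)
    for i in range(batch.n_realizations):
        out[i] = local_mean(batch.values[i], sift)
    return out


def ensemble_average(matrix: np.ndarray) -> np.ndarray:
    """Columnwise arithmetic mean across realizations."""
    m = np.asarray(matrix)
    if not np.issubdtype(m.dtype, np.floating):
        m = m.astype(float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("ensemble average expects a non-empty I x N matrix")
    return m.mean(axis=0)


def eemd(signal, config: EnsembleConfig | None = None) -> Decomposition:
    """Ensemble EMD: average independent decompositions of noisy copies.

    Each realization decomposes ``x + eps0 * w(i)`` with plain EMD; mode j
    is averaged across realizations (zero-padding realizations that
    produced fewer modes), and the residue is defined as the input minus
    the summed averaged modes, so the reported decomposition reconstructs
    the input even though EEMD itself is not exactly invertible.
    """
    if config is None:
        config = EnsembleConfig()
    x = _as_samples(signal).astype(config.dtype, copy=False)
    n = x.size
    i_total, k = config.n_realizations, config.max_modes
    mode_sum = np.zeros((k, n))
    n_modes_max = 0
    for i in range(i_total):
        if config.noise_strength > 0:
            w = _noise_stream(config.seed, i).standard_normal(n)
            xi = (x + config.noise_strength * w).astype(config.dtype, copy=False)
        else:
            xi = x
        dec = emd(xi, max_modes=k, config=config.sift)
        n_modes_max = max(n_modes_max, dec.n_modes)
        for j, mode in enumerate(dec.modes):
            mode_sum[j] += mode.samples
    averaged = (mode_sum[:n_modes_max] / i_total).astype(config.dtype, copy=False)
    modes = [Mode(samples=row) for row in averaged]
    residue = x - averaged.sum(axis=0) if n_modes_max else x.copy()
    return Decomposition(modes=modes, residue=residue, signal=x)


def iceemdan(
    signal,
    config: EnsembleConfig | None = None,
    noise_modes: NoiseModeTensor | None = None,
) -> ICEEMDANResult:
    """Improved CEEMDAN of one channel.

    The recursion, with ``<.>`` the ensemble average over realizations and
    ``M(.)`` the local-mean operator:

    - ``r_1 = < M(x + beta_0 E_1(w(i))) >``, ``d_1 = x - r_1``
    - for k >= 2: ``r_k = < M(r_{k-1} + beta_{k-1} E_k(w(i))) >``,
      ``d_k = r_{k-1} - r_k``

    with ``beta_k = eps0 * std(r_k)`` (and ``beta_0 = eps0 * std(x)``,
    optionally normalized by each realization's first-noise-mode standard
    deviation).  Stops when the running residue has too few extrema to
    oscillate or K modes have been produced.

    When ``beta`` is zero at some level, every realization is identical,
    and the level reduces (bitwise) to a single local-mean application —
    the zero-noise path and the ensemble path are the same computation.

    Parameters
    ----------
    signal : SignalChannel or array_like
        Input channel.
    config : EnsembleConfig, optional
        Ensemble tunables; defaults are I=500, K=12, S=10, eps0=0.2.
    noise_modes : NoiseModeTensor, optional
        Precomputed tensor (reusable across channels of equal length);
        computed on demand when omitted and eps0 > 0.
    """
    if config is None:
        config = EnsembleConfig()
    x = _as_samples(signal).astype(config.dtype, copy=False)
    n = x.size

    need_noise = config.noise_strength > 0
    if need_noise and noise_modes is None:
        noise_modes = precompute_noise_modes(config, n)
    if noise_modes is not None and noise_modes.values.shape[2] != n:
        raise ValueError("noise-mode tensor length does not match the signal")

    modes: list[Mode] = []
    residues: list[np.ndarray] = []
    betas: list[float] = []
    prev = x
    for k in range(config.max_modes):
        ext = find_extrema(prev)
        if ext.n_maxima < 2 or ext.n_minima < 2:
            break
        beta_scalar = noise_amplitude(prev, config.noise_strength, "plain")
        betas.append(beta_scalar)
        if beta_scalar == 0.0 or noise_modes is None:
            rk = local_mean(prev, config.sift)
        else:
            ek = noise_modes.level(k)
            if k == 0 and config.beta_rule == "normalized-first-mode":
                stds = ek.std(axis=1)
                stds[stds == 0] = 1.0  # degenerate noise mode: leave unscaled
                beta = beta_scalar / stds
            else:
                beta = beta_scalar
            batch = make_realizations(prev, ek, beta)
            rk = ensemble_average(batch_local_mean(batch, config.sift))
        modes.append(Mode(samples=prev - rk))
        residues.append(rk)
        prev = rk
    return ICEEMDANResult(
        modes=modes, residue=prev, residues=residues, betas=betas, signal=x
    )
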