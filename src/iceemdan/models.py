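"""Modelling-object interface: decomposer models and their fitted results.

Mirrors the familiar estimator idiom: a model object is constructed from
the data plus its tunables, ``fit()`` runs the decomposition, and the
returned :class:`DecompositionResults` carries the modes, residue and
diagnostics with ``summary()``, ``match()`` and ``plot()`` attached.

    >>> from iceemdan import ICEEMDAN, make_dual_tone
    >>> fx = make_dual_tone()
    >>> res = ICEEMDAN(fx.composite, n_realizations=100, seed=1).fit()
    >>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np

from .ensemble import EnsembleConfig, ICEEMDANResult
from .ensemble import eemd as _eemd
from .ensemble import iceemdan as _iceemdan
from .envelopes import SignalChannel, _as_samples
from .metrics import count_zero_crossings, imf_validity, match_modes, reconstruction_error
from .sifting import Decomposition, SiftConfig
from .sifting import emd as _emd

__all__ = ["EMD", "EEMD", "ICEEMDAN", "DecompositionResults"]


def _dominant_frequency(x: np.ndarray, sampling_rate: float, n_fft: int = 4096) -> float:
    """Peak frequency of the zero-padded magnitude spectrum, in Hz."""
    n_fft = max(n_fft, 4 * x.size)
    spec = np.abs(np.fft.rfft(x - x.mean(), n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate)
    return float(freqs[int(np.argmax(spec))])


class _DecomposerBase:
    """Shared construction logic of the decomposer models."""

    algorithm: str = ""

    def __init__(self, endog, sampling_rate: float | None = None, **config):
        if isinstance(endog, SignalChannel):
            self.signal = endog
            if sampling_rate is not None:
                self.signal.sampling_rate = sampling_rate
        else:
            self.signal = SignalChannel(
                samples=_as_samples(endog), sampling_rate=sampling_rate
            )
        sift_kwargs = {
            k: config.pop(k) for k in ("n_iterations", "stop_mode", "threshold")
            if k in config
        }
        sift = config.pop("sift", None) or SiftConfig(**sift_kwargs)
        self.config = EnsembleConfig(sift=sift, **config)

    @classmethod
    def from_dataframe(cls, data, column, sampling_rate=None, **config):
        """Build a model from one column of a DataFrame (or mapping of arrays)."""
        return cls(np.asarray(data[column], dtype=float), sampling_rate=sampling_rate, **config)

    def fit(self) -> "DecompositionResults":
        raise NotImplementedError


class EMD(_DecomposerBase):
    """Plain empirical mode decomposition of one channel.

    Parameters
    ----------
    endog : array_like or SignalChannel
        The signal to decompose.
    sampling_rate : float, optional
        Hz; enables frequency columns in the summary.
    max_modes, n_iterations, ... :
        Tunables forwarded to :class:`EnsembleConfig` / :class:`SiftConfig`
        (ensemble-only settings are accepted and ignored by the fit).
    """

    algorithm = "emd"

    def fit(self) -> "DecompositionResults":
        dec = _emd(self.signal, max_modes=self.config.max_modes, config=self.config.sift)
        return DecompositionResults(self, dec)


class EEMD(_DecomposerBase):
    """Ensemble EMD: averaged decompositions of noise-perturbed copies."""

    algorithm = "eemd"

    def fit(self) -> "DecompositionResults":
        dec = _eemd(self.signal, self.config)
        return DecompositionResults(self, dec)


class ICEEMDAN(_DecomposerBase):
    """Improved CEEMDAN: noise-mode-assisted recursion with exact invertibility.

    The workhorse model.  Accepts every :class:`EnsembleConfig` field as a
    keyword (``n_realizations``, ``max_modes``, ``noise_strength``,
    ``seed``, ``beta_rule``, ``precision``) plus the sifting tunables.
    """

    algorithm = "iceemdan"

    def fit(self, noise_modes=None) -> "DecompositionResults":
        dec = _iceemdan(self.signal, self.config, noise_modes=noise_modes)
        return DecompositionResults(self, dec)


class DecompositionResults:
    """Fitted decomposition: modes, residue, diagnostics and reporting.

    Attributes
    ----------
    modes : ndarray, shape (K, N)
        Extracted modes, fastest first.
    residue : ndarray, shape (N,)
        Final low-frequency remainder.
    betas : list of float or None
        Per-level noise amplitudes (ICEEMDAN only).
    """

    def __init__(self, model: _DecomposerBase, decomposition: Decomposition | ICEEMDANResult):
        self.model = model
        self.decomposition = decomposition
        self.modes = decomposition.mode_matrix()
        self.residue = np.asarray(decomposition.residue)
        self.betas = getattr(decomposition, "betas", None)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def reconstruction_error(self) -> float:
        """Relative max-abs error of (sum of modes + residue) vs the input."""
        return reconstruction_error(self.model.signal, self.decomposition)

    def match(self, references) -> "SimilarityReport":
        """Best-matching mode per reference component (similarity index)."""
        return match_modes(self.decomposition, references)

    def mode_frequencies(self) -> np.ndarray:
        """Per-mode dominant frequency (Hz if the sampling rate is known,
        cycles/sample otherwise)."""
        fs = self.model.signal.sampling_rate or 1.0
        return np.array([
            _dominant_frequency(m, fs) if np.ptp(m) > 0 else 0.0 for m in self.modes
        ])

    def summary(self) -> str:
        """Plain-text per-mode table: energy share, oscillation counts, frequency."""
        x = self.model.signal.samples
        fs = self.model.signal.sampling_rate
        total_energy = float(np.sum((x - x.mean()) ** 2)) or 1.0
        unit = "Hz" if fs else "cyc/sample"
        lines = [
            f"{type(self.model).__name__} decomposition results",
            f"  N = {x.size} samples, {self.n_modes} modes"
            + (f", fs = {fs:g} Hz" if fs else ""),
            f"  reconstruction error = {self.reconstruction_error:.3e} (relative max abs)",
            "",
            f"  {'mode':>4} {'energy %':>9} {'extrema':>8} {'zero-cross':>10} {'freq ' + unit:>12}",
        ]
        freqs = self.mode_frequencies()
        for i, m in enumerate(self.modes):
            v = imf_validity(m)
            energy = 100.0 * float(np.sum((m - m.mean()) ** 2)) / total_energy
            lines.append(
                f"  {i + 1:>4} {energy:>9.2f} {v.n_extrema:>8d} "
                f"{v.n_zero_crossings:>10d} {freqs[i]:>12.3f}"
            )
        res_energy = 100.0 * float(np.sum((self.residue - self.residue.mean()) ** 2)) / total_energy
        lines.append(
            f"  {'res':>4} {res_energy:>9.2f} {'-':>8} "
            f"{count_zero_crossings(self.residue):>10d} {'-':>12}"
        )
        return "\n".join(lines)

    def plot(self, max_modes: int | None = None):
        """Stacked plot of the input, each mode, and the residue.

        Returns the matplotlib Figure; requires matplotlib at call time.
        """
        import matplotlib.pyplot as plt

        k = self.n_modes if max_modes is None else min(max_modes, self.n_modes)
        fig, axes = plt.subplots(k + 2, 1, sharex=True, figsize=(8, 1.2 * (k + 2)))
        x = self.model.signal.samples
        fs = self.model.signal.sampling_rate
        t = np.arange(x.size) / fs if fs else np.arange(x.size)
        axes[0].plot(t, x, lw=0.8)
        axes[0].set_ylabel("input")
        for i in range(k):
            axes[i + 1].plot(t, self.modes[i], lw=0.8)
            axes[i + 1].set_ylabel(f"d{i + 1}")
        axes[-1].plot(t, self.residue, lw=0.8)
        axes[-1].set_ylabel("residue")
        axes[-1].set_xlabel("time [s]" if fs else "sample")
        fig.tight_layout()
        return fig

    def simulate(self, mode_indices=None) -> np.ndarray:
        """Partial reconstruction from a subset of modes (plus the residue
        when ``mode_indices`` is None, i.e. the full reconstruction)."""
        if mode_indices is None:
            return self.decomposition.reconstruct()
        out = np.zeros_like(self.residue)
        for i in mode_indices:
            out = out + self.modes[i]
        return out
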