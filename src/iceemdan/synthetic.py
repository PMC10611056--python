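"""Synthetic fixtures: the dual-tone benchmark signal, seeded noise, EEG surrogates.

The dual-tone fixture is the standard mode-mixing benchmark for ensemble
decompositions: a continuous slow sinusoid (65 Hz at the nominal 1 kHz
rate, i.e. 0.065 cycles/sample) plus a fast sinusoid (255 Hz, 0.255
cycles/sample) that is switched on only for a quarter of the record.  The
intermittency makes plain EMD mix the two scales into one mode, which the
noise-assisted variants are designed to prevent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import RealizationBatch
from .envelopes import SignalChannel

__all__ = [
    "DualToneFixture",
    "make_dual_tone",
    "gaussian_noise_matrix",
    "make_synthetic_eeg",
    "DEFAULT_BAND_FREQUENCIES",
]

# Intermittent fast tone: active on 1-based samples 501..750 (0-based 500..749).
_N = 1000
_ACTIVE_START = 500  # 0-based, inclusive
_ACTIVE_STOP = 750   # 0-based, exclusive
_F_FAST = 0.255      # cycles/sample -> 255 Hz at 1 kHz
_F_SLOW = 0.065      # cycles/sample -> 65 Hz at 1 kHz
_FS_NOMINAL = 1000.0


@dataclass
class DualToneFixture:
    """The 1000-sample dual-tone benchmark with its ground-truth components.

    ``composite = component_s1 + component_s2`` elementwise (bitwise);
    ``component_s1`` is the intermittent 255 Hz tone (zero outside samples
    500..749, 0-based), ``component_s2`` the continuous 65 Hz tone.
    """

    composite: SignalChannel
    component_s1: np.ndarray
    component_s2: np.ndarray
    sampling_rate: float = _FS_NOMINAL
    active_window: tuple[int, int] = (_ACTIVE_START, _ACTIVE_STOP)
    carrier_frequencies_hz: tuple[float, float] = (
        _F_FAST * _FS_NOMINAL,
        _F_SLOW * _FS_NOMINAL,
    )


def make_dual_tone() -> DualToneFixture:
    """Build the dual-tone benchmark signal.

    With 1-based sample index n = 1..1000:

    - ``s1[n] = sin(2 pi 0.255 (n - 501))`` for 501 <= n <= 750, else 0
    - ``s2[n] = sin(2 pi 0.065 (n - 1))``

    stored 0-based.  The fast component starts and the slow component
    begins the record at phase zero.
    """
    j = np.arange(_N)  # 0-based; the conventional 1-based sample index is j + 1
    s1 = np.zeros(_N)
    active = slice(_ACTIVE_START, _ACTIVE_STOP)
    s1[active] = np.sin(2 * np.pi * _F_FAST * (j[active] - _ACTIVE_START))
    s2 = np.sin(2 * np.pi * _F_SLOW * j)
    composite = SignalChannel(
        samples=s1 + s2, sampling_rate=_FS_NOMINAL, label="dual-tone"
    )
    return DualToneFixture(composite=composite, component_s1=s1, component_s2=s2)


def gaussian_noise_matrix(n_realizations: int, n_samples: int, seed: int) -> RealizationBatch:
    """Seeded zero-mean unit-variance Gaussian noise, one realization per row.

    Row i draws from the stream keyed on (seed, i), so any given row is
    identical no matter how many realizations the batch holds.
    """
    if n_realizations < 1 or n_samples < 1:
        raise ValueError("matrix dimensions must be >= 1")
    rows = np.empty((n_realizations, n_samples))
    for i in range(n_realizations):
        rows[i] = np.random.default_rng([seed, i]).standard_normal(n_samples)
    return RealizationBatch(values=rows)


DEFAULT_BAND_FREQUENCIES = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0}


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n)
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def make_synthetic_eeg(
    n_channels: int,
    n_samples: int,
    sampling_rate: float = 250.0,
    band_amplitudes: dict[str, float] | None = None,
    noise_amplitude: float = 1.0,
    seed: int = 0,
) -> list[SignalChannel]:
    """Multichannel EEG-like surrogate: band oscillations plus pink noise.

    Each channel sums one slowly amplitude-modulated sinusoid per
    requested band (delta/theta/alpha/beta centre frequencies by default,
    random phase per channel) and 1/f background noise.  This captures the
    oscillations-on-pink-noise structure of resting EEG but none of its
    nonstationarity, artifacts or cross-channel covariance.

    Parameters
    ----------
    n_channels, n_samples : int
        Output shape; channels are generated independently.
    sampling_rate : float
        Hz; band centre frequencies are interpreted against it.
    band_amplitudes : dict, optional
        Amplitude per band name (unknown names need a matching entry in
        ``DEFAULT_BAND_FREQUENCIES``-style "name" -> Hz; a numeric name is
        read directly as a frequency in Hz).  Defaults to amplitude 1.0
        for alpha and 0.5 for the other three canonical bands.
    noise_amplitude : float
        Standard deviation of the pink-noise floor (0 disables it).
    seed : int
        Master seed; channel c uses the stream (seed, c).
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if band_amplitudes is None:
        band_amplitudes = {"delta": 0.5, "theta": 0.5, "alpha": 1.0, "beta": 0.5}
    t = np.arange(n_samples) / sampling_rate
    channels = []
    for c in range(n_channels):
        rng = np.random.default_rng([seed, c])
        x = np.zeros(n_samples)
        for band, amp in band_amplitudes.items():
            if amp == 0:
                continue
            try:
                f0 = DEFAULT_BAND_FREQUENCIES[band]
            except KeyError:
                f0 = float(band)
            phase = rng.uniform(0, 2 * np.pi)
            # Gentle amplitude modulation at ~0.3 Hz keeps each band narrow.
            envelope = 1.0 + 0.2 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))
            x += amp * envelope * np.sin(2 * np.pi * f0 * t + phase)
        if noise_amplitude > 0:
            x += noise_amplitude * _pink_noise(rng, n_samples)
        channels.append(
            SignalChannel(samples=x, sampling_rate=sampling_rate, label=f"ch{c}")
        )
    return channels
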