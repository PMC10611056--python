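import numpy as np
import pytest

from iceemdan.synthetic import make_dual_tone


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def dual_tone():
    return make_dual_tone()


@pytest.fixture
def tone_1000():
    """50-cycle unit sinusoid, 0.05 cycles/sample."""
    return np.sin(2 * np.pi * 0.05 * np.arange(1000))


def make_edf_bytes(signals, sampling_rate=100.0, labels=None):
    """Construct a minimal valid 16-bit EDF byte stream (synthetic, for tests).

    One data record per second; signals must share a common length that is
    a multiple of ``sampling_rate``.
    """
    signals = [np.asarray(s, dtype=float) for s in signals]
    ns = len(signals)
    spr = int(sampling_rate)
    n_records = len(signals[0]) // spr
    labels = labels or [f"EEG ch{i}" for i in range(ns)]

    def pad(text, width):
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("synthetic patient", 80), pad("synthetic recording", 80),
        pad("01.01.20", 8), pad("00.00.00", 8), pad(str(256 * (1 + ns)), 8),
        pad("", 44), pad(str(n_records), 8), pad("1", 8), pad(str(ns), 4),
    ])
    phys_min, phys_max = [], []
    digitized = []
    for s in signals:
        lo, hi = float(s.min()), float(s.max())
        if hi == lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((s - lo) / (hi - lo) * 65535 - 32768).astype("<i2")
        digitized.append(dig)
    sig_header = b"".join(
        [b"".join(pad(lbl, 16) for lbl in labels)]
        + [b"".join(pad("", 80) for _ in signals)]
        + [b"".join(pad("uV", 8) for _ in signals)]
        + [b"".join(pad(f"{v:.3f}", 8) for v in phys_min)]
        + [b"".join(pad(f"{v:.3f}", 8) for v in phys_max)]
        + [b"".join(pad("-32768", 8) for _ in signals)]
        + [b"".join(pad("32767", 8) for _ in signals)]
        + [b"".join(pad("", 80) for _ in signals)]
        + [b"".join(pad(str(spr), 8) for _ in signals)]
        + [b"".join(pad("", 32) for _ in signals)]
    )
    records = b""
    for r in range(n_records):
        for dig in digitized:
            records += dig[r * spr : (r + 1) * spr].tobytes()
    return header + sig_header + records
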