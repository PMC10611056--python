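"""File formats, run manifests, and reproducibility helpers.

Supported input formats:

- delimited text (CSV/TSV/whitespace), laid out samples x channels with an
  optional header row of channel labels;
- raw binary float matrix with a JSON sidecar (``<file>.json``) describing
  shape, dtype, memory order and sampling rate;
- European Data Format (EDF) recordings, read-only, via a minimal
  self-contained parser (16-bit continuous EDF, the common case for the
  EEG exports this package targets).

Decomposition outputs are written per channel as a K x N mode matrix plus
a residue vector (delimited or binary), alongside a ``manifest.json``
:class:`RunManifest` that pins down algorithm, configuration and seed well
enough to reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ensemble import EnsembleConfig
from .envelopes import SignalChannel
from .sifting import SiftConfig

__all__ = [
    "RunManifest",
    "read_signal_file",
    "write_signal_file",
    "write_decomposition",
    "read_decomposition",
    "run_from_manifest",
]


class SignalFileError(ValueError):
    """A file could not be parsed or a selection was out of range."""


# --------------------------------------------------------------------------
# manifests


@dataclass
class RunManifest:
    """Everything needed to reproduce a decomposition run.

    ``timings`` optionally carries the per-stage wall-clock breakdown of
    the sifting pipeline (extrema, tridiagonal solve, spline coefficients,
    interpolation, envelope mean, residue update).
    """

    algorithm: str  # "emd" | "eemd" | "iceemdan"
    config: dict
    input: dict  # {"path": ..., "format": ..., "channels": [...]} or {"synthetic": ...}
    seed: int
    package_version: str = __version__
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def ensemble_config(self) -> EnsembleConfig:
        cfg = dict(self.config)
        sift = SiftConfig(**cfg.pop("sift"))
        return EnsembleConfig(sift=sift, **cfg)

    @staticmethod
    def config_dict(config: EnsembleConfig) -> dict:
        return dataclasses.asdict(config)


# --------------------------------------------------------------------------
# delimited text


def _sniff_delimiter(path: Path) -> str | None:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix == ".tsv":
        return "\t"
    with open(path) as fh:
        first = fh.readline()
    if "," in first:
        return ","
    if "\t" in first:
        return "\t"
    return None  # whitespace


def _read_delimited(path: Path) -> tuple[np.ndarray, list[str] | None]:
    delim = _sniff_delimiter(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first:
        raise SignalFileError(f"{path}: empty file")
    tokens = first.split(delim) if delim else first.split()
    try:
        [float(t) for t in tokens]
        header = None
        skip = 0
    except ValueError:
        header = [t.strip() for t in tokens]
        skip = 1
    try:
        data = np.loadtxt(path, delimiter=delim, skiprows=skip, ndmin=2)
    except ValueError as exc:
        raise SignalFileError(f"{path}: malformed delimited file ({exc})") from exc
    return data, header


def _write_delimited(matrix: np.ndarray, path: Path, header: list[str] | None = None) -> None:
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    hdr = delim.join(header) if header else ""
    np.savetxt(path, matrix, delimiter=delim, header=hdr, comments="", fmt="%.17g")


# --------------------------------------------------------------------------
# binary matrix + sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_binary_matrix(path: Path) -> tuple[np.ndarray, dict]:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SignalFileError(f"{path}: missing sidecar metadata file {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    try:
        n, c = int(meta["n_samples"]), int(meta["n_channels"])
        dtype = np.dtype(meta.get("dtype", "float64"))
        order = meta.get("order", "C")
    except (KeyError, TypeError) as exc:
        raise SignalFileError(f"{sidecar}: invalid sidecar metadata ({exc})") from exc
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != n * c:
        raise SignalFileError(
            f"{path}: expected {n * c} values ({n} samples x {c} channels), found {raw.size}"
        )
    return raw.reshape((n, c), order=order), meta


def _write_binary_matrix(matrix: np.ndarray, path: Path, sampling_rate=None, labels=None) -> None:
    m = np.ascontiguousarray(matrix)
    m.tofile(path)
    meta = {
        "n_samples": int(m.shape[0]),
        "n_channels": int(m.shape[1]),
        "dtype": str(m.dtype),
        "order": "C",
        "sampling_rate": sampling_rate,
    }
    if labels:
        meta["labels"] = list(labels)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


# --------------------------------------------------------------------------
# EDF (read-only)

_EDF_HEADER = 256


def _read_edf(path: Path) -> tuple[list[np.ndarray], list[str], list[float]]:
    """Minimal EDF reader: continuous recordings, 16-bit samples.

    Returns per-signal sample arrays (physically calibrated), labels, and
    per-signal sampling rates.
    """
    with open(path, "rb") as fh:
        head = fh.read(_EDF_HEADER)
        if len(head) < _EDF_HEADER:
            raise SignalFileError(f"{path}: truncated EDF header")

        def _ascii(b: bytes) -> str:
            return b.decode("ascii", errors="replace").strip()

        try:
            n_records = int(_ascii(head[236:244]))
            record_seconds = float(_ascii(head[244:252]))
            n_signals = int(_ascii(head[252:256]))
        except ValueError as exc:
            raise SignalFileError(f"{path}: malformed EDF header ({exc})") from exc
        if n_signals < 1:
            raise SignalFileError(f"{path}: EDF header reports no signals")

        sig_head = fh.read(256 * n_signals)
        if len(sig_head) < 256 * n_signals:
            raise SignalFileError(f"{path}: truncated EDF signal headers")

        def _fields(offset: int, width: int) -> list[str]:
            base = offset * n_signals
            return [
                _ascii(sig_head[base + s * width : base + (s + 1) * width])
                for s in range(n_signals)
            ]

        labels = _fields(0, 16)
        try:
            phys_min = [float(v) for v in _fields(16 + 80 + 8, 8)]
            phys_max = [float(v) for v in _fields(16 + 80 + 8 + 8, 8)]
            dig_min = [int(v) for v in _fields(16 + 80 + 8 + 8 + 8, 8)]
            dig_max = [int(v) for v in _fields(16 + 80 + 8 + 8 + 8 + 8, 8)]
            spr = [int(v) for v in _fields(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]
        except ValueError as exc:
            raise SignalFileError(f"{path}: malformed EDF signal header ({exc})") from exc

        samples_per_record = sum(spr)
        raw = np.fromfile(fh, dtype="<i2")
    if raw.size < n_records * samples_per_record:
        raise SignalFileError(
            f"{path}: EDF data too short ({raw.size} samples, "
            f"expected {n_records * samples_per_record})"
        )
    raw = raw[: n_records * samples_per_record].reshape(n_records, samples_per_record)

    signals, rates = [], []
    offset = 0
    for s in range(n_signals):
        dig = raw[:, offset : offset + spr[s]].reshape(-1).astype(float)
        offset += spr[s]
        dspan = dig_max[s] - dig_min[s]
        gain = (phys_max[s] - phys_min[s]) / dspan if dspan else 1.0
        signals.append((dig - dig_min[s]) * gain + phys_min[s])
        rates.append(spr[s] / record_seconds if record_seconds > 0 else float("nan"))
    return signals, labels, rates


# --------------------------------------------------------------------------
# public reader / writer


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".csv", ".tsv", ".txt", ".dat"):
        return "delimited"
    if suffix == ".edf":
        return "edf"
    if suffix in (".bin", ".raw", ".f32", ".f64"):
        return "binary-matrix"
    raise SignalFileError(f"{path}: cannot infer format from suffix {suffix!r}")


def read_signal_file(path, format: str | None = None, channels=None) -> list[SignalChannel]:
    """Read one or more channels from a signal file.

    Parameters
    ----------
    path : path-like
        Input file.
    format : {"delimited", "binary-matrix", "edf"}, optional
        Inferred from the suffix when omitted.
    channels : sequence of int, optional
        0-based channel indices to keep (all channels by default).

    Returns
    -------
    list of SignalChannel
    """
    path = Path(path)
    if not path.exists():
        raise SignalFileError(f"{path}: no such file")
    fmt = format or _infer_format(path)

    if fmt == "delimited":
        data, header = _read_delimited(path)
        labels = header or [f"ch{i}" for i in range(data.shape[1])]
        rates = [None] * data.shape[1]
        columns = [data[:, i] for i in range(data.shape[1])]
    elif fmt == "binary-matrix":
        data, meta = _read_binary_matrix(path)
        labels = meta.get("labels") or [f"ch{i}" for i in range(data.shape[1])]
        rates = [meta.get("sampling_rate")] * data.shape[1]
        columns = [data[:, i] for i in range(data.shape[1])]
    elif fmt == "edf":
        columns, labels, rates = _read_edf(path)
    else:
        raise SignalFileError(f"unknown format: {fmt!r}")

    n_channels = len(columns)
    if channels is None:
        selected = range(n_channels)
    else:
        selected = list(channels)
        bad = [c for c in selected if not 0 <= c < n_channels]
        if bad:
            raise SignalFileError(
                f"{path}: channel index {bad[0]} out of range (file has {n_channels})"
            )
    return [
        SignalChannel(samples=columns[c], sampling_rate=rates[c], label=labels[c])
        for c in selected
    ]


def write_signal_file(channels: list[SignalChannel], path, format: str | None = None) -> None:
    """Write channels to delimited text or a binary matrix (fixture export)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    matrix = np.column_stack([c.samples for c in channels])
    labels = [c.label or f"ch{i}" for i, c in enumerate(channels)]
    rate = channels[0].sampling_rate
    if fmt == "delimited":
        _write_delimited(matrix, path, header=labels)
    elif fmt == "binary-matrix":
        _write_binary_matrix(matrix, path, sampling_rate=rate, labels=labels)
    else:
        raise SignalFileError(f"cannot write format: {fmt!r}")


def write_decomposition(result, out_dir, stem: str = "channel0",
                        format: str = "delimited",
                        manifest: RunManifest | None = None) -> dict[str, Path]:
    """Write one channel's modes and residue, plus an optional manifest.

    Produces ``<stem>_modes`` (K x N, one mode per row) and
    ``<stem>_residue`` files in the requested format, and
    ``manifest.json`` when a manifest is given.  File content is a pure
    function of the decomposition, so identical runs produce identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    modes = result.mode_matrix()
    residue = np.asarray(result.residue)
    written: dict[str, Path] = {}
    if format == "delimited":
        modes_path = out_dir / f"{stem}_modes.csv"
        residue_path = out_dir / f"{stem}_residue.csv"
        _write_delimited(modes.T if modes.size else modes.reshape(0, 0), modes_path)
        _write_delimited(residue[:, None], residue_path)
    elif format == "binary-matrix":
        modes_path = out_dir / f"{stem}_modes.bin"
        residue_path = out_dir / f"{stem}_residue.bin"
        _write_binary_matrix(modes.T if modes.size else np.empty((residue.size, 0)), modes_path)
        _write_binary_matrix(residue[:, None], residue_path)
    else:
        raise SignalFileError(f"cannot write format: {format!r}")
    written["modes"] = modes_path
    written["residue"] = residue_path
    if manifest is not None:
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(manifest.to_json())
        written["manifest"] = manifest_path
    return written


def read_decomposition(out_dir, stem: str = "channel0", format: str = "delimited"):
    """Read back a written decomposition as (modes K x N, residue N)."""
    out_dir = Path(out_dir)
    if format == "delimited":
        modes, _ = _read_delimited(out_dir / f"{stem}_modes.csv")
        residue, _ = _read_delimited(out_dir / f"{stem}_residue.csv")
    elif format == "binary-matrix":
        modes, _ = _read_binary_matrix(out_dir / f"{stem}_modes.bin")
        residue, _ = _read_binary_matrix(out_dir / f"{stem}_residue.bin")
    else:
        raise SignalFileError(f"unknown format: {format!r}")
    return modes.T, residue[:, 0]


def run_from_manifest(manifest: RunManifest, signal=None):
    """Re-execute the decomposition a manifest describes.

    ``signal`` may be supplied directly; otherwise the manifest's input
    descriptor is re-read (file inputs) or re-generated (the synthetic
    fixtures).  Returns the per-channel results list.
    """
    from .ensemble import eemd, iceemdan
    from .sifting import emd

    cfg = manifest.ensemble_config()
    if signal is not None:
        channels = [signal]
    elif "synthetic" in manifest.input:
        from .synthetic import make_dual_tone

        name = manifest.input["synthetic"]
        if name != "dual-tone":
            raise ValueError(f"unknown synthetic input: {name!r}")
        channels = [make_dual_tone().composite]
    else:
        channels = read_signal_file(
            manifest.input["path"],
            format=manifest.input.get("format"),
            channels=manifest.input.get("channels"),
        )
    out = []
    for ch in channels:
        if manifest.algorithm == "emd":
            out.append(emd(ch, max_modes=cfg.max_modes, config=cfg.sift))
        elif manifest.algorithm == "eemd":
            out.append(eemd(ch, cfg))
        elif manifest.algorithm == "iceemdan":
            out.append(iceemdan(ch, cfg))
        else:
            raise ValueError(f"unknown algorithm: {manifest.algorithm!r}")
    return out
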