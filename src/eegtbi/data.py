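"""Recordings, segments, and the raw-signal-to-matrix preparation chain.

A :class:`Recording` is a channels-by-samples amplitude matrix in microvolts
with its sampling rate and ordered 10-10 channel labels.  Preparation for the
classifier follows the acquisition protocol: drop the EOG channel (CPz),
discard the unsettled first portion of the recording, optionally reject
high-amplitude windows, then cut the remainder into consecutive one-second
matrices.  Each such matrix ``M`` satisfies ``M[i, t] = x_i(t)`` — the
amplitude of retained channel ``i`` at the ``t``-th sample of the window —
so a 63-channel, 1000 Hz recording yields 63 x 1000 segment matrices.

Two interchange formats are supported: European Data Format (EDF, 16-bit)
and a plain tab-separated matrix (channels as rows) with a ``.meta`` sidecar
of ``key: value`` lines carrying labels, sampling rate, subject id and class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, InsufficientDataError, MontageError
from .montage import Montage

CLASS_LABELS = ("healthy", "tbi", "unknown")


@dataclass
class Recording:
    """A labeled multichannel EEG time series.

    ``signal`` is channels x samples in microvolts; row ``i`` is channel
    ``channel_labels[i]``.
    """

    signal: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    subject_id: str = "unknown"
    class_label: str = "unknown"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.channel_labels = tuple(self.channel_labels)
        if self.signal.ndim != 2:
            raise FormatError("signal must be a 2-D channels x samples array")
        if self.signal.shape[0] != len(self.channel_labels):
            raise FormatError(
                f"{self.signal.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.shape[1] < 1:
            raise FormatError("recording must contain at least one sample")
        if self.class_label not in CLASS_LABELS:
            raise FormatError(f"class_label must be one of {CLASS_LABELS}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One windowed amplitude matrix, the classifier's input unit."""

    matrix: np.ndarray
    subject_id: str
    index: int
    class_label: str = "unknown"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise FormatError("segment matrix must be 2-D")


@dataclass
class RejectionReport:
    """Outcome of amplitude-threshold artifact rejection."""

    dropped_windows: list[int]
    n_windows: int
    threshold: float

    def to_tsv(self) -> str:
        lines = ["window_index\tdropped"]
        dropped = set(self.dropped_windows)
        for i in range(self.n_windows):
            lines.append(f"{i}\t{int(i in dropped)}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# preparation operations
# ---------------------------------------------------------------------------

def apply_montage(rec: Recording, montage: Montage) -> Recording:
    """Drop the montage's excluded channels, preserving the stored order."""
    labels = set(rec.channel_labels)
    missing = set(montage.excluded_labels) - labels
    if missing:
        raise MontageError(f"cannot exclude absent channels: {sorted(missing)}")
    keep = [i for i, c in enumerate(rec.channel_labels)
            if c not in montage.excluded_labels]
    return replace(
        rec,
        signal=rec.signal[keep],
        channel_labels=tuple(rec.channel_labels[i] for i in keep),
    )


def discard_initial(rec: Recording, seconds: float) -> Recording:
    """Remove the first ``seconds`` of the recording (settling period)."""
    if seconds < 0:
        raise ValueError("seconds must be nonnegative")
    n_drop = int(round(seconds * rec.fs))
    if n_drop >= rec.n_samples:
        raise InsufficientDataError(
            f"cannot discard {seconds} s from a {rec.duration:.1f} s recording"
        )
    if n_drop == 0:
        return rec
    return replace(rec, signal=rec.signal[:, n_drop:])


def reject_artifacts(
    rec: Recording, amplitude_threshold: float, window_seconds: float = 1.0
) -> tuple[Recording, RejectionReport]:
    """Drop whole windows containing any sample beyond the threshold.

    A deterministic surrogate for manual artifact inspection: any
    ``window_seconds`` window with ``|amplitude| > amplitude_threshold``
    (microvolts) is removed and the survivors are re-concatenated.  Returns
    the cleaned recording and a report of dropped window indices.
    """
    if not amplitude_threshold > 0:
        raise ValueError("amplitude_threshold must be positive")
    win = int(round(window_seconds * rec.fs))
    n_windows = rec.n_samples // win
    dropped: list[int] = []
    kept_blocks = []
    for w in range(n_windows):
        block = rec.signal[:, w * win:(w + 1) * win]
        if np.any(np.abs(block) > amplitude_threshold):
            dropped.append(w)
        else:
            kept_blocks.append(block)
    tail = rec.signal[:, n_windows * win:]
    if tail.shape[1]:
        kept_blocks.append(tail)
    if not kept_blocks:
        raise InsufficientDataError("all windows rejected as artifacts")
    cleaned = replace(rec, signal=np.concatenate(kept_blocks, axis=1))
    return cleaned, RejectionReport(dropped, n_windows, amplitude_threshold)


def segment_recording(
    rec: Recording,
    window_seconds: float = 1.0,
    max_segments: int | None = None,
) -> list[Segment]:
    """Cut the recording into consecutive non-overlapping windows.

    The trailing partial window is discarded; output is truncated at
    ``max_segments`` when given.
    """
    win = int(round(window_seconds * rec.fs))
    if win < 1 or win > rec.n_samples:
        raise InsufficientDataError(
            f"recording of {rec.n_samples} samples cannot yield a "
            f"{window_seconds} s window at fs={rec.fs}"
        )
    n = rec.n_samples // win
    if max_segments is not None:
        n = min(n, max_segments)
    return [
        Segment(
            matrix=rec.signal[:, w * win:(w + 1) * win].copy(),
            subject_id=rec.subject_id,
            index=w,
            class_label=rec.class_label,
        )
        for w in range(n)
    ]


# ---------------------------------------------------------------------------
# matrix + sidecar interchange format
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta")


def save_matrix(rec: Recording, path: str | Path) -> None:
    """Write a recording as TSV (channels as rows) plus a ``.meta`` sidecar."""
    path = Path(path)
    np.savetxt(path, rec.signal, fmt="%.6g", delimiter="\t")
    meta = (
        f"fs: {rec.fs}\n"
        f"subject_id: {rec.subject_id}\n"
        f"class_label: {rec.class_label}\n"
        f"channels: {','.join(rec.channel_labels)}\n"
    )
    _sidecar_path(path).write_text(meta)


def _load_matrix(path: Path) -> Recording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata file {sidecar}")
    meta: dict[str, str] = {}
    for line in sidecar.read_text().splitlines():
        if ":" in line:
            key, _, value = line.partition(":")
            meta[key.strip()] = value.strip()
    for key in ("fs", "channels"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key '{key}'")
    signal = np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=np.float64))
    labels = tuple(c.strip() for c in meta["channels"].split(",") if c.strip())
    if signal.shape[0] != len(labels):
        raise FormatError(
            f"{signal.shape[0]} matrix rows but {len(labels)} channel labels"
        )
    return Recording(
        signal=signal,
        fs=float(meta["fs"]),
        channel_labels=labels,
        subject_id=meta.get("subject_id", "unknown"),
        class_label=meta.get("class_label", "unknown"),
    )


# ---------------------------------------------------------------------------
# European Data Format
# ---------------------------------------------------------------------------

def save_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as a 16-bit EDF file with one-second data records.

    Amplitudes are stored under the ``uV`` physical dimension with per-channel
    physical ranges, so the round-trip error is bounded by the 16-bit
    quantization step.  The recording identification field carries the
    subject id and class label.  The duration must be a whole number of
    seconds and the sampling rate an integer.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    if rec.n_samples % fs != 0:
        raise FormatError("EDF writer requires a whole number of seconds")
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii", errors="replace")[:width]
        return b + b" " * (width - len(b))

    phys_min = rec.signal.min(axis=1)
    phys_max = rec.signal.max(axis=1)
    flat = phys_max - phys_min < 1e-9
    phys_min = np.where(flat, phys_min - 1.0, phys_min)
    phys_max = np.where(flat, phys_max + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {rec.subject_id}", 80),
        pad(f"subject={rec.subject_id} class={rec.class_label}", 80),
        pad("01.01.20", 8),
        pad("00.00.00", 8),
        pad(str(256 * (ns + 1)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(ns), 4),
    ])
    fields = []
    for spec_width, values in [
        (16, rec.channel_labels),
        (80, [""] * ns),
        (8, ["uV"] * ns),
        (8, [f"{v:.6g}"[:8] for v in phys_min]),
        (8, [f"{v:.6g}"[:8] for v in phys_max]),
        (8, [str(dig_min)] * ns),
        (8, [str(dig_max)] * ns),
        (80, [""] * ns),
        (8, [str(fs)] * ns),
        (32, [""] * ns),
    ]:
        fields.append(b"".join(pad(v, spec_width) for v in values))
    header += b"".join(fields)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint(
        (rec.signal - phys_min[:, None]) * scale[:, None] + dig_min
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())


def _parse_edf_recording_id(path: Path) -> tuple[str, str]:
    """Recover subject id and class label from the EDF recording-id field."""
    with open(path, "rb") as fh:
        fh.seek(88)
        field_text = fh.read(80).decode("ascii", errors="replace").strip()
    subject, label = "unknown", "unknown"
    for token in field_text.split():
        if token.startswith("subject="):
            subject = token[len("subject="):]
        elif token.startswith("class="):
            value = token[len("class="):]
            if value in CLASS_LABELS:
                label = value
    return subject, label


def _load_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - normalize reader failures
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    signal_uv = raw.get_data() * 1e6  # MNE returns volts
    subject, label = _parse_edf_recording_id(path)
    return Recording(
        signal=signal_uv,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        subject_id=subject,
        class_label=label,
    )


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF or the matrix+sidecar format.

    ``format`` is ``"edf"`` or ``"matrix"``; when omitted it is inferred from
    the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return _load_edf(path)
    if format == "matrix":
        return _load_matrix(path)
    raise ValueError(f"unknown format {format!r}; expected 'edf' or 'matrix'")


def save_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        save_edf(rec, path)
    elif format == "matrix":
        save_matrix(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'edf' or 'matrix'")
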