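"""Spectral band power and envelope-connectivity feature primitives.

Band ranges follow conventional clinical definitions (delta 0.5-4, theta
4-8, alpha 8-13, beta 13-30 with beta1/2/3 subdivisions, gamma 30-70 Hz;
the gamma cap matches a DC-to-70 Hz acquisition chain).  Band power is the
integral of a Welch periodogram-average spectrum over the band.  Envelope
connectivity band-filters two channels, removes the zero-lag parallel
component of one from the other (orthogonalization in the analytic-signal
domain), and correlates the log-transformed amplitude envelopes — a
connectivity measure insensitive to volume conduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import FrequencyError, UndefinedMetricError


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 <= self.low_hz < self.high_hz:
            raise FrequencyError(
                f"degenerate band {self.name}: [{self.low_hz}, {self.high_hz})"
            )


BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in (
        BandDefinition("delta", 0.5, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta", 13.0, 30.0),
        BandDefinition("beta1", 13.0, 18.0),
        BandDefinition("beta2", 18.0, 24.0),
        BandDefinition("beta3", 24.0, 30.0),
        BandDefinition("gamma", 30.0, 70.0),
    )
}


def _as_band(band) -> BandDefinition:
    return BANDS[band] if isinstance(band, str) else band


def welch_psd(x: np.ndarray, fs: float, nperseg: int | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density along the last axis (uV^2/Hz)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    if nperseg is None:
        nperseg = min(n, int(round(fs)))
    return sps.welch(x, fs=fs, nperseg=min(nperseg, n), axis=-1)


def band_power(x: np.ndarray, fs: float, band, channels=None) -> np.ndarray:
    """Average power within ``[low, high)`` Hz per channel (uV^2).

    ``x`` is (channels, samples) or (samples,); ``channels`` optionally
    selects rows by index.  Integrates the Welch spectrum over the band.
    """
    band = _as_band(band)
    if band.high_hz > fs / 2:
        raise FrequencyError(
            f"band {band.name} ([{band.low_hz}, {band.high_hz}) Hz) exceeds "
            f"the Nyquist frequency {fs / 2} Hz"
        )
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    if channels is not None:
        x = x[np.asarray(channels)]
    freqs, psd = welch_psd(x, fs)
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    if not mask.any():
        raise FrequencyError(
            f"no spectral bins fall inside band {band.name} at fs={fs}"
        )
    df = freqs[1] - freqs[0]
    return psd[..., mask].sum(axis=-1) * df


def bandpass_filter(x: np.ndarray, fs: float, low_hz: float, high_hz: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Edges at or beyond Nyquist degrade gracefully: the high edge is clipped
    to 0.99 * Nyquist, and a low edge of 0 turns the filter into a low-pass.
    """
    nyq = fs / 2
    high = min(high_hz, 0.99 * nyq)
    low = max(low_hz, 0.0)
    if low >= high:
        raise FrequencyError(f"cannot band-pass [{low_hz}, {high_hz}) at fs={fs}")
    if low <= 0:
        sos = sps.butter(order, high / nyq, btype="low", output="sos")
    else:
        sos = sps.butter(order, [low / nyq, high / nyq], btype="band",
                         output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def notch_filter(x: np.ndarray, fs: float, freq_hz: float = 50.0,
                 quality: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch (mains removal) along the last axis."""
    if freq_hz >= fs / 2:
        return np.asarray(x, dtype=np.float64)
    b, a = sps.iirnotch(freq_hz, quality, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=np.float64), axis=-1)


def highpass_filter(x: np.ndarray, fs: float, cutoff_hz: float,
                    order: int = 4) -> np.ndarray:
    sos = sps.butter(order, cutoff_hz / (fs / 2), btype="high", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def lowpass_filter(x: np.ndarray, fs: float, cutoff_hz: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase low-pass; a no-op when the cutoff reaches Nyquist."""
    if cutoff_hz >= fs / 2:
        return np.asarray(x, dtype=np.float64)
    sos = sps.butter(order, cutoff_hz / (fs / 2), btype="low", output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=np.float64), axis=-1)


def _log_envelope(env: np.ndarray) -> np.ndarray:
    floor = 1e-12 * max(1.0, float(np.max(env)))
    return np.log(np.maximum(env, floor))


def envelope_connectivity(x: np.ndarray, y: np.ndarray, band, fs: float
                          ) -> float:
    """Orthogonalized log-envelope correlation of two channels in a band.

    Both channels are band-filtered; the analytic signal of ``y`` is
    orthogonalized against ``x`` (its zero-lag parallel component removed),
    then the Pearson correlation of the log amplitude envelopes is returned,
    bounded in [-1, 1].  Identical inputs orthogonalize to (numerically)
    nothing shared and return 0.  A constant reference envelope (e.g. a pure
    sinusoid) makes the correlation undefined and raises.
    """
    band = _as_band(band)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    xa = sps.hilbert(bandpass_filter(x, fs, band.low_hz, band.high_hz))
    ya = sps.hilbert(bandpass_filter(y, fs, band.low_hz, band.high_hz))
    env_x = np.abs(xa)
    # a flat envelope (e.g. a pure tone; 5% tolerance absorbs filter edge
    # transients) has no fluctuation to correlate
    if np.std(env_x) < 0.05 * max(float(np.mean(env_x)), 1e-300):
        raise UndefinedMetricError(
            "reference envelope is constant; correlation undefined"
        )
    # component of y orthogonal to x at zero lag (analytic-signal domain)
    env_y_orth = np.abs(np.imag(ya * np.conj(xa) / np.maximum(env_x, 1e-300)))
    log_x = _log_envelope(env_x)
    log_y = _log_envelope(env_y_orth)
    if np.std(log_y) < 1e-8:
        # the shared component was (numerically) everything: no residual
        # envelope to correlate, connectivity zero by convention
        return 0.0
    r = float(np.corrcoef(log_x, log_y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def mean_envelope_connectivity(block: np.ndarray, band, fs: float
                               ) -> np.ndarray:
    """Per-channel mean orthogonalized log-envelope correlation.

    ``block`` is (channels, samples).  For each channel i, the returned
    entry is the mean over all j != i of the connectivity between i (as
    reference) and j, computed with a vectorized analytic-signal pass.
    Degenerate pairs contribute 0.
    """
    band = _as_band(band)
    block = np.asarray(block, dtype=np.float64)
    n_ch = block.shape[0]
    analytic = sps.hilbert(
        bandpass_filter(block, fs, band.low_hz, band.high_hz), axis=-1)
    env = np.abs(analytic)
    out = np.zeros(n_ch)
    for i in range(n_ch):
        env_i = env[i]
        if np.std(env_i) < 0.05 * max(float(np.mean(env_i)), 1e-300):
            continue  # flat reference envelope: contributes 0
        orth = np.abs(np.imag(analytic * np.conj(analytic[i]))
                      / np.maximum(env_i, 1e-300))
        log_ref = _log_envelope(env_i)
        log_orth = _log_envelope(orth)
        ref_c = log_ref - log_ref.mean()
        orth_c = log_orth - log_orth.mean(axis=-1, keepdims=True)
        denom = np.sqrt((orth_c ** 2).sum(axis=-1)) * np.sqrt((ref_c ** 2).sum())
        num = orth_c @ ref_c
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 1e-10, num / np.maximum(denom, 1e-300), 0.0)
        r[i] = 0.0
        out[i] = np.clip(r, -1.0, 1.0).sum() / max(n_ch - 1, 1)
    return out


def per_hz_band_powers(x: np.ndarray, fs: float, low_hz: float = 1.0,
                       high_hz: float = 30.0) -> np.ndarray:
    """Power in consecutive 1 Hz bins [low, low+1), ... per channel.

    Returns (channels, n_bins) with n_bins = high_hz - low_hz.
    """
    if high_hz > fs / 2:
        raise FrequencyError(f"{high_hz} Hz exceeds Nyquist at fs={fs}")
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    freqs, psd = welch_psd(x, fs)
    df = freqs[1] - freqs[0]
    edges = np.arange(low_hz, high_hz + 1e-9)
    out = np.empty((x.shape[0], len(edges) - 1))
    for j in range(len(edges) - 1):
        mask = (freqs >= edges[j]) & (freqs < edges[j + 1])
        out[:, j] = psd[:, mask].sum(axis=-1) * df
    return out
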