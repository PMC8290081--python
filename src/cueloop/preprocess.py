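"""Offline and online signal cleaning: high-pass, RLS blink removal, rejection.

Offline high-pass is a zero-phase Hamming FIR; the online variant is a causal
4th-order Butterworth whose state persists across consecutive 1-s windows so
a streamed session equals the filter applied to the concatenated signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import EpochSet, RawRecording

__all__ = [
    "RlsConfig",
    "highpass",
    "OnlineHighpass",
    "RlsBlinkFilter",
    "remove_blinks_rls",
    "reject_epochs",
]


@dataclass
class RlsConfig:
    """Settings for the recursive-least-squares EOG regression filter."""

    forgetting_factor: float = 0.9999
    init_regularization: float = 0.01
    reference_channels: tuple[str, ...] = ("VEOG", "HEOG")

    def __post_init__(self) -> None:
        if not (0.0 < self.forgetting_factor <= 1.0):
            raise ValueError("forgetting_factor must lie in (0, 1]")
        if self.init_regularization <= 0:
            raise ValueError("init_regularization must be positive")


def _fir_highpass(cutoff_hz: float, fs: float, transition_hz: float = 0.5) -> np.ndarray:
    numtaps = int(np.ceil(3.3 * fs / transition_hz)) | 1  # odd length
    return signal.firwin(numtaps, cutoff_hz, fs=fs, pass_zero="highpass", window="hamming")


def _butter_sos(cutoff_hz: float, fs: float) -> np.ndarray:
    return signal.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")


def highpass(rec: RawRecording, cutoff_hz: float = 0.5, mode: str = "offline") -> RawRecording:
    """High-pass filter every channel of a recording.

    ``offline`` is zero-phase (filtfilt over the FIR kernel); ``online``
    applies the causal Butterworth in one pass, matching what a stream of
    :class:`OnlineHighpass` windows would produce.
    """
    if cutoff_hz >= rec.sampling_rate / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    out = rec.copy()
    if mode == "offline":
        taps = _fir_highpass(cutoff_hz, rec.sampling_rate)
        pad = min(3 * len(taps), rec.n_samples - 1)
        out.data = signal.filtfilt(taps, [1.0], rec.data, axis=1, padlen=pad)
    elif mode == "online":
        sos = _butter_sos(cutoff_hz, rec.sampling_rate)
        out.data = signal.sosfilt(sos, rec.data, axis=1)
    else:
        raise ValueError(f"unknown highpass mode {mode!r}")
    return out


class OnlineHighpass:
    """Causal high-pass with per-channel state carried across windows."""

    def __init__(self, n_channels: int, sampling_rate: float, cutoff_hz: float = 0.5):
        if cutoff_hz >= sampling_rate / 2.0:
            raise ValueError("cutoff must be below the Nyquist frequency")
        self._sos = _butter_sos(cutoff_hz, sampling_rate)
        self._zi = np.zeros((self._sos.shape[0], n_channels, 2))

    def process(self, window: np.ndarray) -> np.ndarray:
        """Filter one (channels x samples) window, updating internal state."""
        out, self._zi = signal.sosfilt(self._sos, window, axis=1, zi=self._zi)
        return out


class RlsBlinkFilter:
    """Streaming RLS filter regressing the EOG references out of scalp data.

    The inverse-correlation matrix update depends only on the shared
    reference signals, so a single matrix serves all target channels; the
    per-channel weights update jointly.  Reference channels pass through
    untouched.
    """

    def __init__(self, channel_labels: list[str], cfg: RlsConfig | None = None):
        self.cfg = cfg or RlsConfig()
        upper = [l.upper() for l in channel_labels]
        self.ref_idx = []
        for ref in self.cfg.reference_channels:
            if ref.upper() not in upper:
                raise KeyError(f"RLS reference channel {ref!r} not in recording")
            self.ref_idx.append(upper.index(ref.upper()))
        self.target_idx = [i for i in range(len(channel_labels)) if i not in self.ref_idx]
        m = len(self.ref_idx)
        self.P = np.eye(m) / self.cfg.init_regularization
        self.W = np.zeros((len(self.target_idx), m))

    def process(self, window: np.ndarray) -> np.ndarray:
        """Clean one (channels x samples) window sample-by-sample."""
        lam = self.cfg.forgetting_factor
        out = window.astype(np.float64).copy()
        refs = window[self.ref_idx]
        targets = out[self.target_idx]
        for n in range(window.shape[1]):
            x = refs[:, n]
            Px = self.P @ x
            k = Px / (lam + x @ Px)
            e = targets[:, n] - self.W @ x
            self.W += np.outer(e, k)
            P = (self.P - np.outer(k, Px)) / lam
            self.P = 0.5 * (P + P.T)  # symmetrize: keeps P PSD over long runs
            targets[:, n] = e
        out[self.target_idx] = targets
        return out


def remove_blinks_rls(rec: RawRecording, cfg: RlsConfig | None = None) -> RawRecording:
    """Subtract the adaptive EOG contribution from every non-reference channel."""
    filt = RlsBlinkFilter(rec.channel_labels, cfg)
    out = rec.copy()
    out.data = filt.process(rec.data)
    return out


def reject_epochs(epochs: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """Flag trials whose absolute amplitude exceeds ``threshold_uv`` anywhere.

    Rejection is flag-based (``kept`` set False); data are retained.  EOG
    channels are included in the scan.  Idempotent.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2)) if epochs.n_trials else np.empty(0)
    kept = epochs.kept & ~(peak > threshold_uv)
    return EpochSet(
        data=epochs.data,
        times_ms=epochs.times_ms,
        labels=epochs.labels,
        channel_labels=list(epochs.channel_labels),
        kept=kept,
        sampling_rate=epochs.sampling_rate,
        n_dropped=epochs.n_dropped,
    )
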