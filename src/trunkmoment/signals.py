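"""Signal conditioning: Butterworth filtering, the EMG linear-envelope chain,
MVC normalization, anti-aliased resampling to 50 Hz, and cross-correlation
delay estimation for exoskeleton synchronization.

All Butterworth filters default to zero-phase (forward-backward) application,
which doubles the effective order but introduces no group delay; a causal
mode is available for online-style processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal


class FilterParameterError(ValueError):
    pass


class SignalLengthError(ValueError):
    pass


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # lowpass | highpass | bandpass
    order: int
    cutoff_hz: float | tuple[float, float]
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise FilterParameterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise FilterParameterError("filter order must be positive")
        cutoffs = np.atleast_1d(np.asarray(self.cutoff_hz, dtype=float))
        if self.kind == "bandpass" and cutoffs.size != 2:
            raise FilterParameterError("bandpass needs two cutoff frequencies")
        if self.kind != "bandpass" and cutoffs.size != 1:
            raise FilterParameterError(f"{self.kind} needs one cutoff frequency")
        if np.any(cutoffs <= 0):
            raise FilterParameterError("cutoffs must be positive")


def butterworth(x, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply a Butterworth filter; zero-phase by default."""
    x = np.asarray(x, dtype=float)
    cutoffs = np.atleast_1d(np.asarray(spec.cutoff_hz, dtype=float))
    if np.any(cutoffs >= fs / 2):
        raise FilterParameterError(
            f"cutoff {cutoffs} Hz at or above Nyquist ({fs / 2} Hz)"
        )
    if x.shape[0] <= 3 * spec.order:
        raise SignalLengthError("signal too short for the requested order")
    wn = cutoffs / (fs / 2)
    btype = {"lowpass": "low", "highpass": "high", "bandpass": "bandpass"}[spec.kind]
    sos = sp_signal.butter(spec.order, wn if wn.size > 1 else wn[0],
                           btype=btype, output="sos")
    if spec.zero_phase:
        return sp_signal.sosfiltfilt(sos, x, axis=0)
    return sp_signal.sosfilt(sos, x, axis=0)


def emg_envelope(raw, fs: float = 2000.0, *, notch_mains_hz: float | None = None
                 ) -> np.ndarray:
    """Linear envelope of a raw surface-EMG signal.

    Chain: band-pass 10-400 Hz (2nd order) -> high-pass 30 Hz to suppress ECG
    artifacts -> full-wave rectification -> low-pass 2.5 Hz; the result is
    clipped at zero (zero-phase low-passing can undershoot by a small
    numerical amount).  An optional mains notch is available, default off.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] < fs:  # < 1 s
        raise SignalLengthError("EMG shorter than the 1 s filter warm-up")
    x = butterworth(raw, fs, FilterSpec("bandpass", 2, (10.0, 400.0)))
    x = butterworth(x, fs, FilterSpec("highpass", 2, 30.0))
    if notch_mains_hz is not None:
        b, a = sp_signal.iirnotch(notch_mains_hz, Q=30.0, fs=fs)
        x = sp_signal.filtfilt(b, a, x, axis=0)
    x = np.abs(x)
    x = butterworth(x, fs, FilterSpec("lowpass", 2, 2.5))
    return np.clip(x, 0.0, None)


def normalize_mvc(envelope, mvc_peak: float) -> np.ndarray:
    """Scale an envelope by the subject's MVC envelope peak for that channel."""
    if mvc_peak <= 0:
        raise FilterParameterError("MVC peak must be positive")
    return np.asarray(envelope, dtype=float) / mvc_peak


def resample_to_50hz(x, fs_in: float) -> np.ndarray:
    """Anti-aliased, delay-compensated decimation to 50 Hz.

    Only integer decimation factors are supported (e.g. 200 or 2000 Hz in).
    Uses polyphase FIR resampling, which compensates the filter group delay.
    """
    x = np.asarray(x, dtype=float)
    factor = fs_in / 50.0
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise FilterParameterError(
            f"input rate {fs_in} Hz is not an integer multiple of 50 Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return x.copy()
    return sp_signal.resample_poly(x, up=1, down=factor, axis=0,
                                   padtype="line")


def estimate_delay_xcorr(sig_a, sig_b, fs: float) -> int:
    """Integer lag (in samples) by which ``sig_b`` trails ``sig_a``.

    The lag maximizes the normalized cross-correlation of the mean-removed
    signals; positive lag means ``sig_b`` is a delayed copy of ``sig_a``.
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.shape[0] < 2 * fs or b.shape[0] < 2 * fs:
        raise SignalLengthError("need at least 2 s of signal for alignment")
    a = a - a.mean()
    b = b - b.mean()
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise DegenerateInputError("constant signal has no alignment information")
    corr = sp_signal.correlate(b, a, mode="full")
    norm = np.sqrt(np.dot(a, a) * np.dot(b, b))
    corr = corr / norm
    lags = sp_signal.correlation_lags(b.shape[0], a.shape[0], mode="full")
    return int(lags[np.argmax(corr)])
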