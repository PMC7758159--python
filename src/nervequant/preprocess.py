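"""Filtering and rectified leaky integration of nerve channels.

Two preprocessing chains are used downstream:

* spike chain: 300-1000 Hz band-pass plus a 50 Hz notch, spikes are then
  detected on the filtered magnitude;
* burst chain: stricter 300-550 Hz band-pass (no notch) followed by full-wave
  rectification and a leaky integrator with a 0.1 s decay time constant.

Filter family and order are not dictated by the acquisition chain, so the
defaults are a 4th-order Butterworth band-pass and a second-order IIR notch
(q = 30), applied forward-backward (zero phase) so event times are not
shifted.  Causal (single-pass) filtering is available via ``zero_phase=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DataError, ParameterError

__all__ = [
    "FilterSpec",
    "IntegratedTrace",
    "bandpass_filter",
    "notch_filter",
    "rectify_integrate",
    "bp_bin_summary",
    "SPIKE_BAND",
    "BURST_BAND",
    "NOTCH_HZ",
    "DEFAULT_TAU_S",
]

SPIKE_BAND = (300.0, 1000.0)
BURST_BAND = (300.0, 550.0)
NOTCH_HZ = 50.0
DEFAULT_TAU_S = 0.1


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one filtering stage."""

    kind: str  # "bandpass" | "notch"
    low_hz: float | None = None
    high_hz: float | None = None
    center_hz: float | None = None
    q_factor: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "notch"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ParameterError("order must be >= 1")
        if self.kind == "bandpass":
            if self.low_hz is None or self.high_hz is None:
                raise ParameterError("bandpass needs low_hz and high_hz")
            if not 0 < self.low_hz < self.high_hz:
                raise ParameterError(
                    f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
                )
        else:
            if self.center_hz is None or self.center_hz <= 0:
                raise ParameterError("notch needs center_hz > 0")
            if self.q_factor <= 0:
                raise ParameterError("q_factor must be > 0")


@dataclass(frozen=True)
class IntegratedTrace:
    """Nonnegative envelope produced by :func:`rectify_integrate`."""

    samples: np.ndarray
    fs: float
    tau: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ParameterError("tau must be > 0")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


def _validate_band(low: float, high: float, fs: float) -> None:
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ParameterError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq} Hz"
        )


def bandpass_sos(fs: float, spec: FilterSpec) -> np.ndarray:
    """Second-order-section coefficients for the band-pass described by ``spec``."""
    if spec.kind != "bandpass":
        raise ParameterError("spec is not a bandpass")
    _validate_band(spec.low_hz, spec.high_hz, fs)
    return signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=fs, output="sos"
    )


def bandpass_filter(trace: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Band-pass filter a trace; same length in, same length out.

    Zero-phase mode runs the filter forward and backward over a
    reflect-padded copy, doubling the stop-band attenuation and cancelling
    group delay.
    """
    x = np.asarray(trace, dtype=float)
    sos = bandpass_sos(fs, spec)
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, x, padtype="even")
    return signal.sosfilt(sos, x)


def notch_filter(
    trace: np.ndarray,
    fs: float,
    center_hz: float = NOTCH_HZ,
    q_factor: float = 30.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Remove a narrow band around ``center_hz`` (mains interference)."""
    if not 0 < center_hz < fs / 2:
        raise ParameterError(f"center_hz must be in (0, fs/2), got {center_hz}")
    if q_factor <= 0:
        raise ParameterError("q_factor must be > 0")
    b, a = signal.iirnotch(center_hz, q_factor, fs=fs)
    x = np.asarray(trace, dtype=float)
    if zero_phase:
        return signal.filtfilt(b, a, x, padtype="even")
    return signal.lfilter(b, a, x)


def rectify_integrate(trace: np.ndarray, fs: float, tau: float = DEFAULT_TAU_S) -> IntegratedTrace:
    """Full-wave rectify then leaky-integrate with decay time constant ``tau``.

    Implements ``y[n] = y[n-1] * a + |x[n]| * (1 - a)`` with
    ``a = exp(-1 / (fs * tau))`` and ``y[-1] = 0``.  The ``(1 - a)`` input
    weight normalises the integrator to unit DC gain, so a constant input
    converges to itself and the envelope stays on the amplitude scale of the
    input.
    """
    if tau <= 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    if fs <= 0:
        raise ParameterError(f"fs must be > 0, got {fs}")
    a = float(np.exp(-1.0 / (fs * tau)))
    rect = np.abs(np.asarray(trace, dtype=float))
    env = signal.lfilter([1.0 - a], [1.0, -a], rect)
    return IntegratedTrace(samples=env, fs=fs, tau=tau)


def bp_bin_summary(
    bp: np.ndarray, fs: float, bin_s: float = 600.0
) -> list[tuple[float, float]]:
    """Per-bin (mean, sd) of a blood-pressure channel, complete bins only.

    An incomplete trailing bin is flagged with a warning and not summarised.
    """
    if bin_s <= 0:
        raise ParameterError("bin_s must be > 0")
    x = np.asarray(bp, dtype=float)
    if x.size == 0:
        raise DataError("empty blood-pressure trace")
    n_per = int(round(bin_s * fs))
    n_bins = x.size // n_per
    if x.size % n_per:
        warnings.warn(
            f"trailing {x.size % n_per} samples do not fill a {bin_s} s bin; skipped",
            UserWarning,
            stacklevel=2,
        )
    out = []
    for i in range(n_bins):
        chunk = x[i * n_per : (i + 1) * n_per]
        out.append((float(chunk.mean()), float(chunk.std())))
    return out
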