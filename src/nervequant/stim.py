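"""Stimulation protocol representation, scheduling and artifact blanking.

The reference protocol stimulates on alternate minutes within a 10-minute
window (ON for 60 s out of every 120 s), at 5 Hz with monophasic 0.3 mA
pulses; sham runs keep the stimulator off.  Quantification then uses a common
analysis window from 10 to 20 minutes for both arms.  The first minute is
taken as ON (the phase within each 2-minute cycle is configurable), and the
pulse width defaults to 1 ms — typical for peripheral-nerve monophasic
stimulation and irrelevant to the downstream analysis windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "StimProtocol",
    "StimSchedule",
    "build_schedule",
    "render_pulse_train",
    "analysis_window",
    "blank_artifacts",
    "ANALYSIS_WINDOW_S",
]

#: common post-stimulation analysis window, seconds
ANALYSIS_WINDOW_S = (600.0, 1200.0)


@dataclass(frozen=True)
class StimProtocol:
    pulse_rate: float = 5.0  # Hz
    pulse_amplitude_ma: float = 0.3
    pulse_shape: str = "monophasic"
    pulse_width_s: float = 0.001
    on_s: float = 60.0
    period_s: float = 120.0
    window_s: float = 600.0
    mode: str = "vns"  # "vns" | "sham"
    start_on: bool = True  # whether each cycle begins with the ON phase

    def __post_init__(self) -> None:
        if self.mode not in ("vns", "sham"):
            raise ParameterError(f"mode must be 'vns' or 'sham', got {self.mode!r}")
        if self.pulse_shape != "monophasic":
            raise ParameterError("only monophasic pulses are supported")
        if self.pulse_rate <= 0 or self.pulse_amplitude_ma <= 0 or self.pulse_width_s <= 0:
            raise ParameterError("pulse_rate, pulse_amplitude_ma and pulse_width_s must be > 0")
        if not 0 < self.on_s <= self.period_s:
            raise ParameterError(f"need 0 < on_s <= period_s, got {self.on_s} / {self.period_s}")
        n_cycles = self.window_s / self.period_s
        if self.window_s <= 0 or abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ParameterError(
                f"window_s ({self.window_s}) must be a positive multiple of "
                f"period_s ({self.period_s})"
            )

    @property
    def n_cycles(self) -> int:
        return int(round(self.window_s / self.period_s))


@dataclass(frozen=True)
class StimSchedule:
    on_intervals: list[tuple[float, float]] = field(default_factory=list)
    pulse_times: list[float] = field(default_factory=list)

    @property
    def total_on_s(self) -> float:
        return sum(e - s for s, e in self.on_intervals)


def build_schedule(p: StimProtocol) -> StimSchedule:
    """Expand a protocol into explicit ON intervals and pulse times.

    In vns mode with defaults this yields ON intervals
    [0,60), [120,180), [240,300), [360,420), [480,540) with 5 Hz pulses
    inside each; sham yields an empty schedule.
    """
    if p.mode == "sham":
        return StimSchedule()
    intervals: list[tuple[float, float]] = []
    pulses: list[float] = []
    pulses_per_on = int(round(p.on_s * p.pulse_rate))
    for c in range(p.n_cycles):
        start = c * p.period_s + (0.0 if p.start_on else p.period_s - p.on_s)
        intervals.append((start, start + p.on_s))
        pulses.extend(start + j / p.pulse_rate for j in range(pulses_per_on))
    return StimSchedule(on_intervals=intervals, pulse_times=pulses)


def render_pulse_train(
    s: StimSchedule,
    p: StimProtocol,
    fs: float,
    duration_s: float | None = None,
) -> np.ndarray:
    """Render the schedule as a sampled current trace in mA.

    Nonnegative (monophasic); ``pulse_amplitude_ma`` during each pulse and 0
    elsewhere, including everything outside the ON intervals.
    """
    if fs <= 0:
        raise ParameterError("fs must be > 0")
    if p.pulse_width_s < 1.0 / fs:
        raise ParameterError(
            f"pulse_width_s ({p.pulse_width_s}) shorter than one sample at fs={fs}"
        )
    if p.pulse_width_s >= 1.0 / p.pulse_rate:
        raise ParameterError("pulses overlap: pulse_width_s >= 1/pulse_rate")
    if duration_s is None:
        duration_s = p.window_s
    n = int(round(duration_s * fs))
    out = np.zeros(n)
    width_n = int(round(p.pulse_width_s * fs))
    for t in s.pulse_times:
        i0 = int(round(t * fs))
        if i0 >= n:
            continue
        out[i0 : min(i0 + width_n, n)] = p.pulse_amplitude_ma
    return out


def analysis_window(mode: str) -> tuple[float, float]:
    """Common analysis window (seconds): 10-20 min for both sham and vns arms."""
    if mode not in ("vns", "sham"):
        raise ParameterError(f"mode must be 'vns' or 'sham', got {mode!r}")
    return ANALYSIS_WINDOW_S


def blank_artifacts(
    trace: np.ndarray,
    fs: float,
    s: StimSchedule,
    blank_ms: float = 2.0,
) -> np.ndarray:
    """Replace ``blank_ms`` after each pulse with linear interpolation.

    The anchors sit just outside each blanked window, so the operation is
    idempotent; recordings analysed only after the stimulation window do not
    need it, but it makes within-window analysis safe.
    """
    if blank_ms < 0:
        raise ParameterError("blank_ms must be >= 0")
    x = np.asarray(trace, dtype=float).copy()
    if blank_ms == 0 or not s.pulse_times:
        return x
    n = x.size
    half_open = int(round(blank_ms / 1000.0 * fs))
    for t in s.pulse_times:
        i0 = int(round(t * fs))
        i1 = i0 + half_open  # exclusive
        if i1 <= 0 or i0 >= n:
            continue
        i0 = max(i0, 0)
        i1 = min(i1, n)
        a = i0 - 1
        va = x[a] if a >= 0 else (x[i1] if i1 < n else 0.0)
        vb = x[i1] if i1 < n else va
        span = i1 - (a if a >= 0 else i0 - 1)
        idx = np.arange(i0, i1)
        # linear ramp between the sample before and the sample after the window
        frac = (idx - (i0 - 1)) / span
        x[i0:i1] = va + frac * (vb - va)
    return x
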