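"""Recording container plus delimited-text I/O, slicing and annotation handling.

Conventions
-----------
* Nerve channels are stored in microvolts *after* the amplifier gain has been
  divided out; blood pressure is stored in mmHg.
* Time is seconds from recording start; samples are 0-based; every interval is
  half-open ``[start, end)`` so events on a bin edge are never double-counted.
* A recording ``foo.csv`` may carry two plain-text sidecars:
  ``foo.annotations.csv`` (``label,t_start,t_end`` per line, seconds relative
  to the recording start) and ``foo.meta.json`` (sampling rate, start time,
  per-channel units, whether the gain was divided out).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, MalformedInputError, ParameterError, RangeError

__all__ = [
    "Annotation",
    "Recording",
    "read_recording",
    "write_recording",
    "slice_recording",
    "annotation_sidecar_path",
    "meta_sidecar_path",
]

#: relative tolerance on the sampling interval when validating time columns
_DT_RTOL = 1e-6


@dataclass(frozen=True)
class Annotation:
    """A labelled time segment, in seconds relative to the recording start."""

    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ParameterError(
                f"annotation {self.label!r}: t_start ({self.t_start}) must be "
                f"< t_end ({self.t_end})"
            )
        if self.t_start < 0:
            raise ParameterError(f"annotation {self.label!r}: t_start must be >= 0")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Recording:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    channels
        Mapping channel name -> 1-D sample vector.  All channels must have the
        same length.
    fs
        Sampling rate in Hz.
    t0
        Absolute start time in seconds (0 for a fresh recording).
    annotations
        Labelled segments, in seconds relative to ``t0``.
    units
        Optional per-channel unit strings (e.g. ``{"nerve": "uV"}``).
    """

    channels: dict[str, np.ndarray]
    fs: float
    t0: float = 0.0
    annotations: list[Annotation] = field(default_factory=list)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"fs must be > 0, got {self.fs}")
        if not self.channels:
            raise ParameterError("a Recording needs at least one channel")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {k: v.shape for k, v in self.channels.items()}
        ns = {v.shape[0] for v in self.channels.values()}
        if any(v.ndim != 1 for v in self.channels.values()) or len(ns) != 1:
            raise ParameterError(f"all channels must be 1-D and equal length, got {lengths}")
        if self.n_samples < 1:
            raise ParameterError("a Recording needs at least one sample")
        for a in self.annotations:
            if a.t_end > self.duration + 0.5 / self.fs:
                raise ParameterError(
                    f"annotation {a.label!r} ends at {a.t_end} s, beyond the "
                    f"recording duration of {self.duration} s"
                )

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise DataError(f"no channel named {name!r}; have {sorted(self.channels)}") from None

    def annotation(self, label: str) -> Annotation:
        """Return the first annotation with the given label."""
        for a in self.annotations:
            if a.label == label:
                return a
        raise DataError(f"recording has no annotation labelled {label!r}")


def annotation_sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".annotations.csv")


def meta_sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".meta.json")


def read_recording(
    path: str | Path,
    fs: float | None = None,
    gain: float = 1.0,
) -> Recording:
    """Read a recording from a delimited text export.

    The file must have a header row, a ``time`` column (seconds) and at least
    one signal column.  The sampling interval must be constant and consistent
    with ``fs`` to within 1 ppm.  Signal values are divided by ``gain`` (use
    the amplifier's internal gain to recover physical units from raw counts).

    If ``fs`` is omitted it is taken from the ``.meta.json`` sidecar, or
    inferred from the time column as a fallback.
    """
    path = Path(path)
    if gain <= 0:
        raise ParameterError(f"gain must be > 0, got {gain}")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise MalformedInputError(f"{path}: empty file") from exc
    if df.shape[0] == 0:
        raise MalformedInputError(f"{path}: no data rows")
    if "time" not in df.columns:
        raise MalformedInputError(f"{path}: missing required 'time' column")
    signal_cols = [c for c in df.columns if c != "time"]
    if not signal_cols:
        raise MalformedInputError(f"{path}: no signal columns")

    meta: dict = {}
    mpath = meta_sidecar_path(path)
    if mpath.exists():
        meta = json.loads(mpath.read_text())
    if fs is None:
        fs = meta.get("fs")
    t = df["time"].to_numpy(dtype=float)
    if fs is None:
        if len(t) < 2:
            raise MalformedInputError(f"{path}: cannot infer fs from a single sample")
        fs = 1.0 / float(np.median(np.diff(t)))
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(np.abs(dt * fs - 1.0) > _DT_RTOL):
            worst = int(np.argmax(np.abs(dt * fs - 1.0)))
            raise MalformedInputError(
                f"{path}: irregular time step at row {worst + 1} "
                f"(dt={dt[worst]:.9g} s, expected {1.0 / fs:.9g} s)"
            )

    channels = {c: df[c].to_numpy(dtype=float) / gain for c in signal_cols}
    annotations = _read_annotations(annotation_sidecar_path(path))
    units = meta.get("units", {})
    t0 = float(meta.get("t0", t[0]))
    return Recording(channels=channels, fs=float(fs), t0=t0, annotations=annotations, units=units)


def _read_annotations(path: Path) -> list[Annotation]:
    if not path.exists():
        return []
    out: list[Annotation] = []
    df = pd.read_csv(path)
    for row in df.itertuples(index=False):
        out.append(Annotation(str(row.label), float(row.t_start), float(row.t_end)))
    return out


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as delimited text plus annotation/metadata sidecars.

    Values are written with 17 significant digits, so read -> write -> read is
    lossless to double precision.
    """
    path = Path(path)
    cols = {"time": rec.time}
    cols.update(rec.channels)
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.17g")

    apath = annotation_sidecar_path(path)
    if rec.annotations:
        adf = pd.DataFrame(
            [(a.label, a.t_start, a.t_end) for a in rec.annotations],
            columns=["label", "t_start", "t_end"],
        )
        adf.to_csv(apath, index=False, float_format="%.17g")
    elif apath.exists():
        apath.unlink()

    meta = {
        "fs": rec.fs,
        "t0": rec.t0,
        "units": rec.units,
        "gain_corrected": True,
        "note": "signal columns are stored in physical units (amplifier gain divided out)",
    }
    meta_sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    return path


def slice_recording(rec: Recording, t_start: float, t_end: float) -> Recording:
    """Extract the half-open window ``[t_start, t_end)`` (absolute seconds).

    The result contains exactly ``round((t_end - t_start) * fs)`` samples, its
    ``t0`` is ``t_start``, and annotations are clipped and re-referenced to the
    new start.
    """
    if not t_start < t_end:
        raise ParameterError(f"need t_start < t_end, got [{t_start}, {t_end})")
    eps = 0.5 / rec.fs
    if t_start < rec.t0 - eps or t_end > rec.t0 + rec.duration + eps:
        raise RangeError(
            f"window [{t_start}, {t_end}) outside recording "
            f"[{rec.t0}, {rec.t0 + rec.duration})"
        )
    i0 = int(round((t_start - rec.t0) * rec.fs))
    n = int(round((t_end - t_start) * rec.fs))
    if n < 1:
        raise ParameterError("window shorter than one sample")
    if i0 + n > rec.n_samples:
        raise RangeError("window extends past the last sample")

    offset = t_start - rec.t0
    new_dur = n / rec.fs
    annotations = []
    for a in rec.annotations:
        s = max(a.t_start - offset, 0.0)
        e = min(a.t_end - offset, new_dur)
        if s < e:
            annotations.append(Annotation(a.label, s, e))
    return Recording(
        channels={k: v[i0 : i0 + n].copy() for k, v in rec.channels.items()},
        fs=rec.fs,
        t0=t_start,
        annotations=annotations,
        units=dict(rec.units),
    )
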