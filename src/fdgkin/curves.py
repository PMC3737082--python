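"""Time-activity containers shared across the package.

Two containers cover everything the modeling needs:

* :class:`SampledCurve` — an instantaneous activity curve sampled at
  (possibly irregular) time points, used for whole-blood curves and plasma
  input functions.  The study's blood counter records at 1-s resolution,
  so 1 s is the native spacing throughout.
* :class:`FrameTAC` — a frame-structured tissue time-activity curve, i.e.
  frame-averaged activity over contiguous reconstruction intervals.

All times are seconds, all activities kBq/cm^3.  Radioactive-decay
correction is assumed to have been applied upstream; nothing in this
package models physical decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SampledCurve", "FrameTAC"]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class SampledCurve:
    """Instantaneous activity curve: strictly increasing times (s), kBq/cm^3.

    ``kind`` records the curve's role: ``"blood"`` for whole-blood activity,
    ``"plasma"`` for a plasma input function.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "plasma"

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        values = _as_float_array(self.values, "values")
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if times.size < 2:
            raise ValueError("a curve needs at least 2 samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.kind not in ("blood", "plasma"):
            raise ValueError(f"kind must be 'blood' or 'plasma', got {self.kind!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def start(self) -> float:
        return float(self.times[0])

    @property
    def end(self) -> float:
        return float(self.times[-1])

    def __len__(self) -> int:
        return int(self.times.size)

    def interp(self, t) -> np.ndarray:
        """Linear interpolation onto ``t``, holding end values constant
        outside the sampled support (relevant for time-shift studies)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.values)

    def with_values(self, values) -> "SampledCurve":
        return replace(self, values=np.asarray(values, dtype=float))

    def shifted(self, delta_s: float) -> "SampledCurve":
        """Curve with all sample times moved by ``delta_s`` seconds
        (positive = later)."""
        return replace(self, times=self.times + float(delta_s))


@dataclass(frozen=True)
class FrameTAC:
    """Frame-averaged tissue curve over contiguous, non-overlapping frames."""

    start: np.ndarray
    end: np.ndarray
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        start = _as_float_array(self.start, "start")
        end = _as_float_array(self.end, "end")
        values = self.values
        if values is None:
            values = np.zeros_like(start)
        values = _as_float_array(values, "values")
        if not (start.size == end.size == values.size):
            raise ValueError("start, end and values must have equal length")
        if np.any(end <= start):
            bad = int(np.argmax(end <= start))
            raise ValueError(f"frame {bad}: end ({end[bad]}) must exceed start ({start[bad]})")
        if start.size > 1 and not np.allclose(end[:-1], start[1:]):
            bad = int(np.argmax(~np.isclose(end[:-1], start[1:])))
            raise ValueError(
                f"frames must be contiguous: end[{bad}]={end[bad]} != start[{bad + 1}]={start[bad + 1]}"
            )
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        object.__setattr__(self, "values", values)

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    @property
    def durations(self) -> np.ndarray:
        return self.end - self.start

    @property
    def span(self) -> float:
        return float(self.end[-1])

    def __len__(self) -> int:
        return int(self.start.size)

    def with_values(self, values) -> "FrameTAC":
        return replace(self, values=np.asarray(values, dtype=float))

    def schedule(self) -> "FrameTAC":
        """The bare frame schedule (values zeroed)."""
        return FrameTAC(self.start, self.end, np.zeros_like(self.start))
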