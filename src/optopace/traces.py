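"""Uniformly sampled physiological time series and their CSV round trips.

All traces share one layout: a uniform time grid ``t`` in seconds and a
value array in the unit the subclass declares (mV for membrane potential,
pA for whole-cell current, Fura-2 ratio units for calcium).  On-disk form
is a two-column CSV whose header names the unit, e.g. ``time_s,V_mV``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trace", "VoltageTrace", "CurrentTrace", "CaTrace", "EventTimes"]

#: relative tolerance on grid uniformity checks
_DT_RTOL = 1e-6


@dataclass
class Trace:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, uniformly spaced, increasing.
    values : ndarray
        Sample values, same length as ``t``.
    """

    t: np.ndarray
    values: np.ndarray

    #: CSV column name for the value column; subclasses override.
    value_column: str = field(default="value", init=False, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.values.shape:
            raise ValueError("t and values must be 1-D arrays of equal length")
        if self.t.size < 2:
            raise ValueError("a trace needs at least two samples")
        if not (np.isfinite(self.t).all() and np.isfinite(self.values).all()):
            raise ValueError("trace contains non-finite samples")
        dts = np.diff(self.t)
        dt = dts[0]
        if dt <= 0 or not np.allclose(dts, dt, rtol=_DT_RTOL, atol=_DT_RTOL * max(dt, 1e-12)):
            raise ValueError("time grid must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Span covered by the samples, ``n * dt`` (half-open convention)."""
        return self.t.size * self.dt

    def window(self, t_start: float, t_end: float) -> "Trace":
        """Samples with ``t_start <= t < t_end`` as a new trace."""
        mask = (self.t >= t_start) & (self.t < t_end)
        if mask.sum() < 2:
            raise ValueError(f"window [{t_start}, {t_end}) contains fewer than 2 samples")
        return type(self)(self.t[mask], self.values[mask])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.t, self.value_column: self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (time_s, value)")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass
class VoltageTrace(Trace):
    """Membrane potential in mV on a uniform grid."""

    value_column: str = field(default="V_mV", init=False, repr=False)

    @property
    def V(self) -> np.ndarray:
        return self.values


@dataclass
class CurrentTrace(Trace):
    """Whole-cell current in pA on a uniform grid."""

    value_column: str = field(default="I_pA", init=False, repr=False)

    @property
    def I(self) -> np.ndarray:  # noqa: E743 - conventional electrophysiology symbol
        return self.values


@dataclass
class CaTrace(Trace):
    """Fura-2 ratio (F340/F380) on a uniform grid, dimensionless."""

    value_column: str = field(default="ratio", init=False, repr=False)

    @property
    def ratio(self) -> np.ndarray:
        return self.values


@dataclass
class EventTimes:
    """Strictly increasing event onset times of one kind.

    ``kind`` is a free label (``"AP"``, ``"CaT"``, ``"contraction"``) shared
    by the detectors and the windowed-frequency helpers.
    """

    times: np.ndarray
    kind: str = "event"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.times.size and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.times, "kind": self.kind}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTimes":
        df = pd.read_csv(path)
        kind = str(df["kind"].iloc[0]) if "kind" in df and len(df) else "event"
        return cls(df["time_s"].to_numpy(), kind=kind)
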