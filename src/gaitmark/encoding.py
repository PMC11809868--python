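"""Gait events, Gaussian confidence curves, and peak decoding.

Event times are encoded as *confidence curves*: a unit-height Gaussian of
standard deviation sigma (default 53.3 ms) centred on each event, zero
between events.  These curves serve both as the regression target for the
sequence models and as the representation that is decoded back to discrete
events by peak detection with a minimum height and minimum inter-peak
interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "GaitEvent",
    "GaitEventSet",
    "ConfidenceCurve",
    "DEFAULT_SIGMA_MS",
    "GAUSSIAN_SUPPORT_SIGMAS",
    "encode_events",
    "decode_peaks",
    "curve_correlation",
]

Side = Literal["L", "R"]
EventType = Literal["HS", "TO"]
Source = Literal["manual", "threshold", "model", "truth"]

#: Width of the Gaussian placed on each event (ms).
DEFAULT_SIGMA_MS = 53.3
#: Gaussian support half-width in sigmas; the curve is exactly zero beyond
#: this (value at the cut is exp(-8) < 4e-4, below decoding relevance).
GAUSSIAN_SUPPORT_SIGMAS = 4.0


@dataclass(frozen=True, order=True)
class GaitEvent:
    """A single heel strike (HS) or toe off (TO) on one side, in ms."""

    time_ms: float
    side: Side
    type: EventType

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.type not in ("HS", "TO"):
            raise ValueError(f"type must be 'HS' or 'TO', got {self.type!r}")
        if self.time_ms < 0:
            raise ValueError("event time must be non-negative")


@dataclass(frozen=True)
class GaitEventSet:
    """An ordered collection of gait events with a provenance tag."""

    events: tuple[GaitEvent, ...]
    source: Source = "manual"

    def __post_init__(self) -> None:
        events = tuple(sorted(self.events))
        object.__setattr__(self, "events", events)
        for side in ("L", "R"):
            for etype in ("HS", "TO"):
                t = self.times(side, etype)  # type: ignore[arg-type]
                if t.size >= 2 and np.any(np.diff(t) <= 0):
                    raise ValueError(f"duplicate event times in stream ({side}, {etype})")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def times(self, side: Side | None = None, type: EventType | None = None) -> np.ndarray:
        """Event times (ms) filtered by side and/or type, ascending."""
        sel = [
            e.time_ms
            for e in self.events
            if (side is None or e.side == side) and (type is None or e.type == type)
        ]
        return np.asarray(sel, dtype=float)

    def stream(self, side: Side, type: EventType) -> "GaitEventSet":
        """The sub-set restricted to one (side, type) stream."""
        return GaitEventSet(
            tuple(e for e in self.events if e.side == side and e.type == type),
            source=self.source,
        )

    @staticmethod
    def from_times(times_ms: Iterable[float], side: Side, type: EventType,
                   source: Source = "manual") -> "GaitEventSet":
        return GaitEventSet(
            tuple(GaitEvent(float(t), side, type) for t in times_ms), source=source
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [(e.side, e.type, e.time_ms) for e in self.events]
        pd.DataFrame(rows, columns=["side", "type", "time_ms"]).to_csv(path, index=False)

    @staticmethod
    def read_csv(path: str | Path, source: Source = "manual") -> "GaitEventSet":
        df = pd.read_csv(path)
        events = tuple(
            GaitEvent(float(r.time_ms), str(r.side), str(r.type))  # type: ignore[arg-type]
            for r in df.itertuples()
        )
        return GaitEventSet(events, source=source)


@dataclass(frozen=True)
class ConfidenceCurve:
    """A per-sample event-likelihood series for one (side, type) stream.

    Encoder output lies in [0, 1]; model or fused output may slightly
    leave that range but must stay finite.
    """

    values: np.ndarray
    rate_hz: float
    side: Side
    type: EventType
    sigma_ms: float = DEFAULT_SIGMA_MS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("confidence curve contains non-finite values")

    def __len__(self) -> int:
        return int(self.values.size)

    def times_ms(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate_hz * 1000.0

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_ms": self.times_ms(), "value": self.values}).to_csv(
            path, index=False
        )


def encode_events(events: GaitEventSet, n_samples: int, rate_hz: float,
                  sigma_ms: float = DEFAULT_SIGMA_MS,
                  side: Side | None = None, type: EventType | None = None) -> ConfidenceCurve:
    """Encode a single event stream as a Gaussian confidence curve.

    The value at sample time t is exp(-(t - t_e)^2 / (2 sigma^2)) for the
    nearest event within the truncated support (4 sigma), zero elsewhere;
    overlapping Gaussians combine by elementwise maximum so the peak height
    stays 1.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma_ms must be positive")
    sides = {e.side for e in events}
    types = {e.type for e in events}
    if side is None:
        if len(sides) > 1:
            raise ValueError("event set spans multiple sides; pass side= explicitly")
        side = next(iter(sides), "L")
    if type is None:
        if len(types) > 1:
            raise ValueError("event set spans multiple types; pass type= explicitly")
        type = next(iter(types), "HS")

    t_grid = np.arange(n_samples) / rate_hz * 1000.0
    duration_ms = n_samples / rate_hz * 1000.0
    values = np.zeros(n_samples)
    support = GAUSSIAN_SUPPORT_SIGMAS * sigma_ms
    dt_ms = 1000.0 / rate_hz
    for t_e in events.times(side, type):
        if not (0.0 <= t_e <= duration_ms):
            raise ValueError(f"event at {t_e} ms outside the trial window [0, {duration_ms}] ms")
        lo = max(0, int(np.ceil((t_e - support) / dt_ms)))
        hi = min(n_samples, int(np.floor((t_e + support) / dt_ms)) + 1)
        if lo >= hi:
            continue
        seg = t_grid[lo:hi]
        np.maximum(values[lo:hi], np.exp(-((seg - t_e) ** 2) / (2 * sigma_ms**2)),
                   out=values[lo:hi])
    return ConfidenceCurve(values, rate_hz, side, type, sigma_ms)


def _local_maxima(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices and heights of local maxima, with plateau maxima reported
    at the plateau centre.  Endpoints are not peaks."""
    n = values.size
    peaks: list[int] = []
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j < n - 1 and values[j + 1] == values[j]:
                j += 1
            if j < n - 1 and values[j + 1] < values[j]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    idx = np.asarray(peaks, dtype=int)
    return idx, values[idx] if idx.size else np.empty(0)


def decode_peaks(curve: ConfidenceCurve, min_height: float = 0.3,
                 min_interval_ms: float = 1000.0) -> GaitEventSet:
    """Decode a confidence curve to events by constrained peak detection.

    Local maxima of height >= ``min_height`` are accepted greedily in
    descending height order; any remaining peak strictly within
    ``min_interval_ms`` of an accepted peak is rejected.  Equal heights
    break ties toward the earlier peak.
    """
    values = curve.values
    idx, heights = _local_maxima(values)
    keep = heights >= min_height
    idx, heights = idx[keep], heights[keep]
    min_gap = min_interval_ms * curve.rate_hz / 1000.0

    # descending height, earlier index first among ties
    order = np.lexsort((idx, -heights))
    accepted: list[int] = []
    for k in order:
        if all(abs(idx[k] - a) >= min_gap for a in accepted):
            accepted.append(int(idx[k]))
    accepted.sort()
    times = np.asarray(accepted, dtype=float) * (1000.0 / curve.rate_hz)
    return GaitEventSet.from_times(times, curve.side, curve.type, source="model")


def curve_correlation(a: ConfidenceCurve, b: ConfidenceCurve) -> float:
    """Pearson correlation between two equal-length confidence curves."""
    x, y = a.values, b.values
    if x.size != y.size:
        raise ValueError("curves must have equal length")
    if x.size < 2:
        raise ValueError("curves must have length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant curve")
    return float(np.corrcoef(x, y)[0, 1])
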