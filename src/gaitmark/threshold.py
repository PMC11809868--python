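"""Conventional GRF-threshold gait event detection.

The baseline every instrumented-treadmill lab uses: a heel strike is
declared when the vertical GRF rises through a small fraction of body
weight (default 1%), a toe off when it falls back below.  The detector is
deliberately naive — no debouncing by default — so it reproduces the
classic failure modes on artifact-laden signals: foot drag during swing
and cross-plate contamination both produce threshold crossings and hence
spurious events.
"""

from __future__ import annotations

import numpy as np

from .encoding import GaitEvent, GaitEventSet, Side
from .io import SignalChannel

__all__ = ["detect_threshold_events"]


def detect_threshold_events(grf: SignalChannel, body_weight_N: float,
                            threshold_fraction: float = 0.01,
                            side: Side = "L",
                            min_contact_ms: float = 0.0) -> GaitEventSet:
    """Detect HS/TO events by thresholding a vertical GRF channel.

    Entry (HS) is the first sample at or above the threshold after a
    below-threshold sample; exit (TO) is the first sample strictly below
    it.  ``min_contact_ms`` > 0 enables an optional debounce that drops
    contact/flight intervals shorter than the given duration (off by
    default, so artifact-induced extra events are preserved).
    """
    if grf.kind != "grf_vertical":
        raise TypeError(f"expected a grf_vertical channel, got kind {grf.kind!r}")
    if body_weight_N <= 0:
        raise ValueError("body_weight_N must be positive")

    thr = threshold_fraction * body_weight_N
    above = grf.values >= thr
    flips = np.flatnonzero(np.diff(above.astype(np.int8)))
    # crossing index = first sample in the new state
    hs_idx = [int(i) + 1 for i in flips if not above[i]]
    to_idx = [int(i) + 1 for i in flips if above[i]]

    if min_contact_ms > 0:
        min_gap = min_contact_ms * grf.rate_hz / 1000.0
        hs_idx, to_idx = _debounce(hs_idx, to_idx, min_gap)

    dt_ms = 1000.0 / grf.rate_hz  # exact per-sample step avoids FP drift
    events = [GaitEvent(i * dt_ms, side, "HS") for i in hs_idx]
    events += [GaitEvent(i * dt_ms, side, "TO") for i in to_idx]
    return GaitEventSet(tuple(events), source="threshold")


def _debounce(hs_idx: list[int], to_idx: list[int], min_gap: float) -> tuple[list[int], list[int]]:
    """Merge contact/flight intervals shorter than ``min_gap`` samples."""
    crossings = sorted([(i, "HS") for i in hs_idx] + [(i, "TO") for i in to_idx])
    kept: list[tuple[int, str]] = []
    for i, kind in crossings:
        if kept and i - kept[-1][0] < min_gap and kept[-1][1] != kind:
            kept.pop()  # short interval: cancel the pair of crossings
        else:
            kept.append((i, kind))
    return [i for i, k in kept if k == "HS"], [i for i, k in kept if k == "TO"]
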