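"""Event-detection error metrics.

Detected events are compared against a reference set by pairing each
reference ("manual") event with the closest detected event in the same
(side, type) stream.  The error sign convention is model minus manual, so
a positive error means the manual event was earlier.  From the matches
the standard bundle is computed: mean error (ME), median absolute error
(MAE), interquartile range of the signed error (IQR), standard deviation
over successful detections only (SD), maximum absolute error (MAX),
successful detection rate within 16 ms (SR), overall detection rate
within 1000 ms (DR), and the signed count of extra events.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import EventType, GaitEventSet, Side

__all__ = [
    "EventMatch",
    "ErrorReport",
    "match_events",
    "error_report",
    "count_extra_events",
    "SR_WINDOW_MS",
    "DR_WINDOW_MS",
]

#: Success window: a detection within 16 ms of a manual event counts as
#: successful (the 84% coverage window of inter-rater variability).
SR_WINDOW_MS = 16.0
#: Overall-detection window, matched to the minimum decode interval.
DR_WINDOW_MS = 1000.0


@dataclass(frozen=True)
class EventMatch:
    """One manual event and its closest detected event (if any)."""

    manual_time_ms: float
    model_time_ms: float | None
    side: Side
    type: EventType

    @property
    def error_ms(self) -> float | None:
        """Signed timing error, model minus manual; None when unmatched."""
        if self.model_time_ms is None:
            return None
        return self.model_time_ms - self.manual_time_ms


@dataclass(frozen=True)
class ErrorReport:
    me_ms: float
    mae_ms: float
    iqr_ms: float
    sd_ms: float
    max_ms: float
    sr_pct: float
    dr_pct: float
    n_events: int

    COLUMNS = ("ME_ms", "MAE_ms", "IQR_ms", "SD_ms", "MAX_ms", "SR_pct", "DR_pct", "n_events")

    def as_row(self) -> tuple[float, ...]:
        return (self.me_ms, self.mae_ms, self.iqr_ms, self.sd_ms, self.max_ms,
                self.sr_pct, self.dr_pct, self.n_events)

    @staticmethod
    def to_csv(reports: dict[str, "ErrorReport"], path: str | Path) -> None:
        df = pd.DataFrame(
            [r.as_row() for r in reports.values()],
            index=list(reports.keys()),
            columns=list(ErrorReport.COLUMNS),
        )
        df.to_csv(path, index_label="stream")


def _closest(manual_t: float, model_times: np.ndarray) -> float:
    """Closest model time to a manual time; equidistant ties -> earlier."""
    d = np.abs(model_times - manual_t)
    best = np.flatnonzero(d == d.min())[0]  # times ascending => first is earlier
    return float(model_times[best])


def match_events(model: GaitEventSet, manual: GaitEventSet) -> list[EventMatch]:
    """Pair every manual event with the closest model event of its stream.

    Model events may be re-used across manual events (per-manual-event
    closest match).  Manual events in a stream with no model events yield
    matches with ``model_time_ms`` None.
    """
    matches: list[EventMatch] = []
    for side in ("L", "R"):
        for etype in ("HS", "TO"):
            man_t = manual.times(side, etype)  # type: ignore[arg-type]
            mod_t = model.times(side, etype)  # type: ignore[arg-type]
            for t in man_t:
                m = _closest(t, mod_t) if mod_t.size else None
                matches.append(EventMatch(float(t), m, side, etype))  # type: ignore[arg-type]
    return matches


def error_report(matches: list[EventMatch], sr_window_ms: float = SR_WINDOW_MS,
                 dr_window_ms: float = DR_WINDOW_MS) -> ErrorReport:
    """Summarise a list of event matches.

    Unmatched manual events count as failures for SR and DR and are
    excluded from the error statistics.  SD is the sample (n-1) standard
    deviation over successful matches only (|error| <= ``sr_window_ms``),
    so a few large outliers do not inflate it.
    """
    if not matches:
        raise ValueError("error_report needs at least one match")
    errors = np.asarray([m.error_ms for m in matches if m.error_ms is not None])
    n = len(matches)
    if errors.size == 0:
        return ErrorReport(np.nan, np.nan, np.nan, np.nan, np.nan, 0.0, 0.0, n)
    abs_err = np.abs(errors)
    successes = errors[abs_err <= sr_window_ms]
    sd = float(np.std(successes, ddof=1)) if successes.size >= 2 else 0.0
    q75, q25 = np.percentile(errors, [75, 25])
    return ErrorReport(
        me_ms=float(np.mean(errors)),
        mae_ms=float(np.median(abs_err)),
        iqr_ms=float(q75 - q25),
        sd_ms=sd,
        max_ms=float(abs_err.max()),
        sr_pct=float(100.0 * successes.size / n),
        dr_pct=float(100.0 * np.count_nonzero(abs_err <= dr_window_ms) / n),
        n_events=n,
    )


def count_extra_events(model: GaitEventSet, manual: GaitEventSet,
                       side: Side | None = None, type: EventType | None = None) -> int:
    """Signed surplus of model events over manual events.

    The model stream is trimmed to the span from the model event closest
    to the first manual event through the model event closest to the last
    manual event; the result is trimmed-model count minus manual count
    (positive = extra detections, negative = missed events).  When side or
    type is None the count is summed over the corresponding streams.
    """
    sides = ("L", "R") if side is None else (side,)
    types = ("HS", "TO") if type is None else (type,)
    total = 0
    seen_any = False
    for s in sides:
        for t in types:
            man_t = manual.times(s, t)  # type: ignore[arg-type]
            mod_t = model.times(s, t)  # type: ignore[arg-type]
            if man_t.size == 0:
                continue
            seen_any = True
            if mod_t.size == 0:
                total -= man_t.size
                continue
            lo = _closest(man_t[0], mod_t)
            hi = _closest(man_t[-1], mod_t)
            trimmed = mod_t[(mod_t >= lo) & (mod_t <= hi)]
            total += int(trimmed.size - man_t.size)
    if not seen_any:
        raise ValueError("count_extra_events needs a non-empty manual set")
    return total
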