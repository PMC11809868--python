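"""Signed-power fusion of per-signal confidence curves.

Three single-signal models (ipsilateral GRF, contralateral GRF,
ipsilateral heel height) each emit a confidence curve; the final curve is
their elementwise signed-power product

    C = sign(C_iGRF)|C_iGRF|^a * sign(C_cGRF)|C_cGRF|^b * sign(C_iHeel)|C_iHeel|^c

with exponents a, b, c in [0, 3].  A zero exponent replaces its term by
the constant 1, so with the shipped weights (a=0.3, b=0, c=0.01) the
contralateral-GRF model drops out entirely.  Exponents are tuned by
minimising the RMS timing error of the decoded events against reference
events.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import ConfidenceCurve, GaitEventSet, decode_peaks
from .metrics import match_events

__all__ = [
    "FusionWeights",
    "DEFAULT_WEIGHTS",
    "DEFAULT_WEIGHT_GRID",
    "signed_power",
    "combine_curves",
    "tune_weights",
]


@dataclass(frozen=True)
class FusionWeights:
    """Exponents (a, b, c) for the iGRF, cGRF and iHeel curves."""

    a: float = 0.3
    b: float = 0.0
    c: float = 0.01

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 3.0:
                raise ValueError(f"weight {name}={v} outside [0, 3]")


DEFAULT_WEIGHTS = FusionWeights()

#: Log-spaced candidate values per coefficient covering [0, 3] and hitting
#: the shipped optimum exactly.
DEFAULT_WEIGHT_GRID: tuple[float, ...] = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0)

#: RMSE penalty (ms) for a reference event with no detection within the
#: matching horizon — bounds the otherwise-undefined contribution.
UNMATCHED_PENALTY_MS = 1000.0


def signed_power(x, p: float):
    """sign(x) * |x|^p, elementwise; p = 0 yields the constant 1.

    Real-valued for fractional p and negative x, matching the sign-prefix
    convention of the fusion formula.
    """
    if p < 0:
        raise ValueError("exponent must be non-negative")
    x = np.asarray(x, dtype=float)
    if p == 0:
        out = np.ones_like(x)
    else:
        out = np.sign(x) * np.abs(x) ** p
    return out if out.ndim else float(out)


def combine_curves(c_igrf: ConfidenceCurve, c_iheel: ConfidenceCurve,
                   weights: FusionWeights = DEFAULT_WEIGHTS,
                   c_cgrf: ConfidenceCurve | None = None) -> ConfidenceCurve:
    """Fuse per-signal curves by the signed-power product.

    The contralateral-GRF curve is only required when its exponent b is
    positive; with b = 0 its term is the constant 1.
    """
    if len(c_igrf) != len(c_iheel):
        raise ValueError("curves must have equal length")
    if weights.b > 0 and c_cgrf is None:
        raise ValueError("weights.b > 0 requires the contralateral GRF curve")
    v = signed_power(c_igrf.values, weights.a) * signed_power(c_iheel.values, weights.c)
    if weights.b > 0:
        assert c_cgrf is not None
        if len(c_cgrf) != len(c_igrf):
            raise ValueError("curves must have equal length")
        v = v * signed_power(c_cgrf.values, weights.b)
    return ConfidenceCurve(v, c_igrf.rate_hz, c_igrf.side, c_igrf.type, c_igrf.sigma_ms)


def _event_rmse(model: GaitEventSet, reference: GaitEventSet,
                penalty_ms: float = UNMATCHED_PENALTY_MS) -> float:
    errs = []
    for m in match_events(model, reference):
        e = m.error_ms
        if e is None or abs(e) > penalty_ms:
            errs.append(penalty_ms)
        else:
            errs.append(e)
    return float(np.sqrt(np.mean(np.square(errs)))) if errs else penalty_ms


def tune_weights(
    candidates: Sequence[FusionWeights],
    curves_by_trial: Sequence[dict[str, ConfidenceCurve]],
    reference: Sequence[GaitEventSet],
    min_height: float = 0.3,
    min_interval_ms: float = 1000.0,
) -> tuple[FusionWeights, pd.DataFrame]:
    """Select fusion exponents by event RMSE against reference events.

    ``curves_by_trial`` holds, per trial, the per-signal curves keyed as
    ``"igrf"``, ``"iheel"`` and optionally ``"cgrf"`` (each value may also
    be a list of curves, e.g. one per side/event-type).  For every
    candidate the curves are fused, decoded, matched to the reference,
    and scored by RMS timing error with unmatched reference events
    penalised at 1000 ms.  Returns the argmin candidate (ties -> first in
    candidate order) and the full score table.
    """
    if not candidates:
        raise ValueError("tune_weights needs at least one candidate")
    if len(curves_by_trial) != len(reference):
        raise ValueError("curves_by_trial and reference must align")

    rows = []
    best: tuple[float, int] | None = None
    for k, w in enumerate(candidates):
        sq_sum, n_tot = 0.0, 0
        for trial_curves, ref in zip(curves_by_trial, reference):
            igrf = _as_list(trial_curves["igrf"])
            iheel = _as_list(trial_curves["iheel"])
            cgrf = _as_list(trial_curves.get("cgrf", [None] * len(igrf)))
            events = []
            for ci, ch, cc in zip(igrf, iheel, cgrf):
                fused = combine_curves(ci, ch, w, cc)
                events.extend(decode_peaks(fused, min_height, min_interval_ms).events)
            rmse = _event_rmse(GaitEventSet(tuple(events), source="model"), ref)
            n_ref = len(ref)
            sq_sum += rmse**2 * n_ref
            n_tot += n_ref
        score = float(np.sqrt(sq_sum / max(n_tot, 1)))
        rows.append((w.a, w.b, w.c, score))
        if best is None or score < best[0]:
            best = (score, k)
    table = pd.DataFrame(rows, columns=["a", "b", "c", "rmse_ms"])
    assert best is not None
    return candidates[best[1]], table


def _as_list(x):
    return list(x) if isinstance(x, (list, tuple)) else [x]


def grid_candidates(values: Sequence[float] = DEFAULT_WEIGHT_GRID,
                    fix_b_zero: bool = True) -> list[FusionWeights]:
    """Cartesian candidate grid over the coefficient values."""
    b_values = (0.0,) if fix_b_zero else tuple(values)
    return [FusionWeights(a, b, c) for a, b, c in product(values, b_values, values)]
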