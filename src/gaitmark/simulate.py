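"""Synthetic slow-treadmill-walking trials with known ground-truth events.

Generates the signals a split-belt instrumented treadmill produces during
slow (~0.49 m/s) exoskeleton-assisted walking: an M-shaped vertical GRF
profile per stance, a heel-height arc per swing, and — crucially — the
two artifact classes that break naive GRF thresholding:

* *foot drag*: premature ground contact mid-swing injects a brief,
  low-amplitude GRF blip on the swinging foot's plate;
* *cross-plate (unclean) strikes*: a foot landing partly on the opposite
  belt adds a fraction of its stance force to the other plate's channel.

Timing, not force-curve fidelity, is the contract: the generator's job is
to give every detector a signal whose true heel-strike and toe-off times
are known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .encoding import GaitEvent, GaitEventSet
from .io import SignalChannel, TrialRecord

__all__ = ["SimParams", "make_gait_schedule", "grf_stance_profile", "simulate_trial"]

# Shape constant of the double-hump stance profile
# F(p) = A sin(pi p)(1 + 0.5 cos(2 pi p)): maxima sit exactly at p = 0.25
# and 0.75 with height A/sqrt(2), the midstance dip is A/2.
_SHAPE_MAX = np.sin(np.pi * 0.25) * (1 + 0.5 * np.cos(np.pi * 0.5))  # = 1/sqrt(2)
#: Fraction of the swing at which the heel arc peaks (shortly after toe off).
_HEEL_PEAK_FRACTION = 0.35


@dataclass(frozen=True)
class SimParams:
    """Simulator settings; defaults emulate slow treadmill walking."""

    duration_s: float = 180.0
    rate_hz: float = 1000.0
    belt_speed_mps: float = 0.491
    stride_period_ms: float = 2000.0
    stride_jitter_sd_ms: float = 20.0
    stance_fraction: float = 0.65
    body_weight_N: float = 700.0
    grf_peak_factor: float = 1.1
    heel_lift_mm: float = 150.0
    noise_sd_N: float = 1.0
    heel_noise_sd_mm: float = 0.5
    drag_rate: float = 0.0
    cross_plate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must lie strictly in (0, 1)")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate_hz and duration_s must be positive")
        if self.stride_period_ms <= 0:
            raise ValueError("stride_period_ms must be positive")
        for name in ("drag_rate", "cross_plate_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.body_weight_N <= 0:
            raise ValueError("body_weight_N must be positive")

    @property
    def duration_ms(self) -> float:
        return self.duration_s * 1000.0


class _Stride(NamedTuple):
    hs_ms: float
    to_ms: float
    next_hs_ms: float  # end of the swing that follows this stance


def _stride_plan(params: SimParams, rng: np.random.Generator) -> dict[str, list[_Stride]]:
    """Jittered stride timing per side, extending one stride past the end
    so trailing stances/swings are assembled (then truncated) correctly."""
    start = params.stride_period_ms / 4.0
    horizon = params.duration_ms + 2 * params.stride_period_ms
    periods: list[float] = []
    hs: list[float] = [start]
    while hs[-1] < horizon:
        p = params.stride_period_ms + rng.normal(0.0, params.stride_jitter_sd_ms)
        p = max(p, 0.5 * params.stride_period_ms)  # guard absurd jitter draws
        periods.append(p)
        hs.append(hs[-1] + p)

    def strides(offset_frac: float) -> list[_Stride]:
        out = []
        for k in range(len(periods)):
            h = hs[k] + offset_frac * periods[k]
            h_next = hs[k + 1] + (offset_frac * periods[k + 1] if k + 1 < len(periods)
                                  else offset_frac * periods[k])
            t = h + params.stance_fraction * periods[k]
            out.append(_Stride(h, t, h_next))
        return out

    return {"L": strides(0.0), "R": strides(0.5)}


def make_gait_schedule(params: SimParams,
                       rng: np.random.Generator | None = None) -> GaitEventSet:
    """Ground-truth event schedule for both sides.

    Left heel strikes fall at cumulative jittered stride periods; each toe
    off follows its heel strike by ``stance_fraction`` of that stride's
    period; the right side is offset by half a period.  Only events inside
    the trial duration are returned.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    plan = _stride_plan(params, rng)
    events = []
    for side, strides in plan.items():
        for st in strides:
            if st.hs_ms <= params.duration_ms:
                events.append(GaitEvent(st.hs_ms, side, "HS"))  # type: ignore[arg-type]
            if st.to_ms <= params.duration_ms:
                events.append(GaitEvent(st.to_ms, side, "TO"))  # type: ignore[arg-type]
    return GaitEventSet(tuple(events), source="truth")


def grf_stance_profile(phase, params: SimParams):
    """Vertical GRF (N) at a given fraction of stance elapsed.

    Smooth M-shape: zero at contact and lift-off, maxima of
    ``grf_peak_factor * body_weight_N`` at phases 0.25 and 0.75, and a
    midstance dip of ~0.78 body weight.  Zero outside [0, 1].
    """
    phase = np.asarray(phase, dtype=float)
    amp = params.grf_peak_factor * params.body_weight_N / _SHAPE_MAX
    inside = (phase >= 0.0) & (phase <= 1.0)
    p = np.where(inside, phase, 0.0)
    f = amp * np.sin(np.pi * p) * (1 + 0.5 * np.cos(2 * np.pi * p))
    out = np.where(inside, f, 0.0)
    return out if out.ndim else float(out)


def _heel_arc(u):
    """Unit swing arc: 0 at both ends, peak 1 at ``_HEEL_PEAK_FRACTION``."""
    u = np.asarray(u, dtype=float)
    pk = _HEEL_PEAK_FRACTION
    rise = 0.5 * (1 - np.cos(np.pi * u / pk))
    fall = 0.5 * (1 + np.cos(np.pi * (u - pk) / (1 - pk)))
    out = np.where(u <= pk, rise, fall)
    return np.where((u >= 0) & (u <= 1), out, 0.0)


def simulate_trial(params: SimParams) -> tuple[TrialRecord, GaitEventSet]:
    """Simulate one trial; returns the record and its ground-truth events.

    Reproducible from ``params.seed``: the stride schedule is drawn first,
    then drag blips, then cross-plate contamination, then sensor noise.
    """
    rng = np.random.default_rng(params.seed)
    plan = _stride_plan(params, rng)

    n = int(round(params.duration_s * params.rate_hz)) + 1
    t_ms = np.arange(n) / params.rate_hz * 1000.0
    grf = {"L": np.zeros(n), "R": np.zeros(n)}
    heel = {"L": np.zeros(n), "R": np.zeros(n)}

    def _slice(t0: float, t1: float) -> slice:
        i0 = max(0, int(np.ceil(t0 * params.rate_hz / 1000.0)))
        i1 = min(n, int(np.floor(t1 * params.rate_hz / 1000.0)) + 1)
        return slice(i0, max(i0, i1))

    # stance force and swing heel arcs
    for side, strides in plan.items():
        for st in strides:
            s = _slice(st.hs_ms, st.to_ms)
            phase = (t_ms[s] - st.hs_ms) / (st.to_ms - st.hs_ms)
            grf[side][s] += grf_stance_profile(phase, params)
            s = _slice(st.to_ms, st.next_hs_ms)
            u = (t_ms[s] - st.to_ms) / (st.next_hs_ms - st.to_ms)
            heel[side][s] += params.heel_lift_mm * _heel_arc(u)
        # leading partial swing before the first heel strike
        first = strides[0]
        swing_ms = (1 - params.stance_fraction) * params.stride_period_ms
        s = _slice(first.hs_ms - swing_ms, first.hs_ms)
        u = (t_ms[s] - (first.hs_ms - swing_ms)) / swing_ms
        heel[side][s] += params.heel_lift_mm * _heel_arc(u)

    # foot drag: premature-contact blip on the swinging foot's own plate
    for side in ("L", "R"):
        for st in plan[side]:
            if rng.random() >= params.drag_rate:
                continue
            swing = st.next_hs_ms - st.to_ms
            start = st.to_ms + rng.uniform(0.3, 0.6) * swing
            dur = rng.uniform(50.0, 150.0)
            mag = rng.uniform(0.02, 0.08) * params.body_weight_N
            s = _slice(start, min(start + dur, st.next_hs_ms))
            u = (t_ms[s] - start) / dur
            grf[side][s] += mag * np.sin(np.pi * np.clip(u, 0, 1)) ** 2

    # cross-plate strikes: part of a stance lands on the opposite plate
    for side, other in (("L", "R"), ("R", "L")):
        for st in plan[side]:
            if rng.random() >= params.cross_plate_rate:
                continue
            frac = rng.uniform(0.1, 0.4)
            s = _slice(st.hs_ms, st.to_ms)
            phase = (t_ms[s] - st.hs_ms) / (st.to_ms - st.hs_ms)
            grf[other][s] += frac * grf_stance_profile(phase, params)

    # sensor noise; both force and height stay physically non-negative
    for side in ("L", "R"):
        if params.noise_sd_N > 0:
            grf[side] += rng.normal(0.0, params.noise_sd_N, n)
        if params.heel_noise_sd_mm > 0:
            heel[side] += rng.normal(0.0, params.heel_noise_sd_mm, n)
        np.clip(grf[side], 0.0, None, out=grf[side])
        np.clip(heel[side], 0.0, None, out=heel[side])

    truth_events = []
    for side, strides in plan.items():
        for st in strides:
            if st.hs_ms <= params.duration_ms:
                truth_events.append(GaitEvent(st.hs_ms, side, "HS"))  # type: ignore[arg-type]
            if st.to_ms <= params.duration_ms:
                truth_events.append(GaitEvent(st.to_ms, side, "TO"))  # type: ignore[arg-type]
    truth = GaitEventSet(tuple(truth_events), source="truth")

    artifacts = params.drag_rate > 0 or params.cross_plate_rate > 0
    trial = TrialRecord(
        trial_id=f"sim-{params.seed:04d}",
        body_weight_N=params.body_weight_N,
        grf_left=SignalChannel(grf["L"], params.rate_hz, "grf_vertical"),
        grf_right=SignalChannel(grf["R"], params.rate_hz, "grf_vertical"),
        heel_left=SignalChannel(heel["L"], params.rate_hz, "heel_height"),
        heel_right=SignalChannel(heel["R"], params.rate_hz, "heel_height"),
        condition="exo" if artifacts else "no_exo",
        rate_hz=params.rate_hz,
    )
    return trial, truth
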