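"""Single-signal LSTM gait-event detectors.

Each detector maps one normalized input channel — the ipsilateral
vertical GRF ("igrf"), the contralateral vertical GRF ("cgrf"), or the
ipsilateral heel height ("iheel") — to two confidence curves, one for
heel strikes and one for toe offs.  Models are trained *incrementally*:
one (trial, side) sequence at a time in left/right-alternating order,
continuing from the current weights, with the learning rate halved every
50 epochs within each increment.

Long sequences are split into fixed-length chunks for minibatching; at
prediction time per-chunk outputs are stitched back together with the
first ``chunk_overlap_samples`` of every chunk (the hidden-state warm-up)
discarded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .encoding import ConfidenceCurve, GaitEventSet, Side, encode_events
from .io import SignalChannel, TrialRecord
from .nn import AdamState, DivergenceError, LSTMCore

__all__ = [
    "ModelConfig",
    "TrainingSequence",
    "GaitLSTM",
    "PAPER_CONFIG",
    "DESK_CONFIG",
    "normalize_input",
    "build_training_sequences",
    "train_incremental",
    "predict_curves",
    "learning_rate_at",
]

InputKind = Literal["igrf", "cgrf", "iheel"]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one single-signal detector."""

    input_kind: InputKind = "igrf"
    hidden_units: int = 540
    minibatch: int = 110
    epochs_per_increment: int = 500
    initial_learning_rate: float = 1e-3
    decay_factor: float = 0.5
    decay_every_epochs: int = 50
    chunk_length_samples: int = 2000
    chunk_overlap_samples: int = 200
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.chunk_length_samples < 2:
            raise ValueError("chunk_length_samples must be >= 2")
        if self.minibatch < 1 or self.epochs_per_increment < 1:
            raise ValueError("minibatch and epochs_per_increment must be >= 1")
        if not 0 < self.decay_factor <= 1:
            raise ValueError("decay_factor must lie in (0, 1]")
        if self.input_kind not in ("igrf", "cgrf", "iheel"):
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if not 0 <= self.chunk_overlap_samples < self.chunk_length_samples:
            raise ValueError("chunk overlap must be shorter than the chunk")


#: Full-size configuration (1000 Hz signals).
PAPER_CONFIG = ModelConfig(hidden_units=540, minibatch=110, epochs_per_increment=500,
                           chunk_length_samples=2000, chunk_overlap_samples=200)
#: Scaled preset for desk testing (100 Hz signals).  The half-chunk overlap
#: gives every emitted sample at least one full stride of recurrent context;
#: the higher learning rate compensates for the shorter epoch budget.
DESK_CONFIG = ModelConfig(hidden_units=64, minibatch=16, epochs_per_increment=100,
                          chunk_length_samples=400, chunk_overlap_samples=200,
                          initial_learning_rate=5e-3)


def learning_rate_at(config: ModelConfig, epoch: int) -> float:
    """Learning rate at a 0-based epoch within one increment."""
    return config.initial_learning_rate * config.decay_factor ** (
        epoch // config.decay_every_epochs
    )


@dataclass(frozen=True)
class TrainingSequence:
    """One (trial, side) input sequence with its target curves."""

    input: SignalChannel
    target_hs: ConfidenceCurve
    target_to: ConfidenceCurve
    label: str = ""

    def __post_init__(self) -> None:
        if not len(self.input) == len(self.target_hs) == len(self.target_to):
            raise ValueError("input and target curves must have equal length")


def normalize_input(channel: SignalChannel, body_weight_N: float) -> SignalChannel:
    """Scale a channel to model units.

    GRF is divided by body weight; heel height is min-max scaled to [0, 1]
    per trial (a constant heel channel maps to all zeros).
    """
    if body_weight_N <= 0:
        raise ValueError("body_weight_N must be positive")
    v = channel.values
    if channel.kind == "grf_vertical":
        out = v / body_weight_N
    else:
        span = np.ptp(v)
        out = (v - v.min()) / span if span > 0 else np.zeros_like(v)
    return SignalChannel(out, channel.rate_hz, channel.kind)


def _input_channel(trial: TrialRecord, side: Side, kind: InputKind) -> SignalChannel:
    other: Side = "R" if side == "L" else "L"
    if kind == "igrf":
        ch = trial.channel(side, "grf_vertical")
    elif kind == "cgrf":
        ch = trial.channel(other, "grf_vertical")
    else:
        ch = trial.channel(side, "heel_height")
    return normalize_input(ch, trial.body_weight_N)


def build_training_sequences(trials: Sequence[TrialRecord],
                             truths: Sequence[GaitEventSet],
                             input_kind: InputKind,
                             sigma_ms: float | None = None) -> list[TrainingSequence]:
    """Assemble sequences in incremental order: per trial, left then right.

    Targets are the Gaussian confidence curves of the ipsilateral events;
    trials should be ordered cleanest first.
    """
    seqs: list[TrainingSequence] = []
    for trial, truth in zip(trials, truths):
        assert trial.rate_hz is not None, "trials must be preprocessed to a common rate"
        for side in ("L", "R"):
            inp = _input_channel(trial, side, input_kind)  # type: ignore[arg-type]
            n = len(inp)
            kwargs = {} if sigma_ms is None else {"sigma_ms": sigma_ms}
            hs = encode_events(truth.stream(side, "HS"), n, trial.rate_hz,  # type: ignore[arg-type]
                               side=side, type="HS", **kwargs)
            to = encode_events(truth.stream(side, "TO"), n, trial.rate_hz,  # type: ignore[arg-type]
                               side=side, type="TO", **kwargs)
            seqs.append(TrainingSequence(inp, hs, to, label=f"{trial.trial_id}-{side}"))
    return seqs


def _chunk_starts(n: int, length: int, overlap: int) -> list[int]:
    if n <= length:
        return [0]
    stride = length - overlap
    starts = list(range(0, n - length, stride))
    starts.append(n - length)  # final chunk flush with the end
    return starts


@dataclass
class GaitLSTM:
    """A trained (or freshly initialised) single-signal detector."""

    config: ModelConfig
    core: LSTMCore

    @classmethod
    def initialise(cls, config: ModelConfig) -> "GaitLSTM":
        rng = np.random.default_rng(config.seed)
        return cls(config, LSTMCore(1, config.hidden_units, 2, rng))

    def save(self, path: str | Path) -> None:
        """Checkpoint: weights (.npz) with the config embedded as JSON."""
        path = Path(path)
        np.savez(path, __config__=np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
            **self.core.params)

    @classmethod
    def load(cls, path: str | Path) -> "GaitLSTM":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls.initialise(cfg)
            for k in model.core.params:
                model.core.params[k] = data[k].copy()
        return model


def train_incremental(config: ModelConfig,
                      sequences: Sequence[TrainingSequence]) -> tuple[GaitLSTM, list[list[float]]]:
    """Train one detector incrementally over the given sequences.

    For each sequence in order, runs ``epochs_per_increment`` epochs
    continuing from the current weights; within each increment the
    learning rate follows the decay schedule and the Adam moments restart.
    Returns the model and the per-increment, per-epoch mean loss history.
    Fully reproducible from ``config.seed``.
    """
    if not sequences:
        raise ValueError("train_incremental needs at least one sequence")
    model = GaitLSTM.initialise(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    history: list[list[float]] = []
    L, V = config.chunk_length_samples, config.chunk_overlap_samples

    for seq in sequences:
        x = seq.input.values
        y = np.stack([seq.target_hs.values, seq.target_to.values], axis=-1)
        starts = _chunk_starts(x.size, L, V)
        length = min(L, x.size)
        xb = np.stack([x[s:s + length, None] for s in starts])  # (n_chunks, L, 1)
        yb = np.stack([y[s:s + length] for s in starts])

        adam = AdamState(model.core.params)
        losses: list[float] = []
        for epoch in range(config.epochs_per_increment):
            lr = learning_rate_at(config, epoch)
            order = rng.permutation(len(starts))
            epoch_loss = 0.0
            for lo in range(0, len(order), config.minibatch):
                sel = order[lo:lo + config.minibatch]
                xs, ys = xb[sel], yb[sel]
                pred, cache = model.core.forward(xs, want_cache=True)
                resid = pred - ys
                loss = float(np.mean(resid**2))
                if not np.isfinite(loss):
                    raise DivergenceError(epoch)
                dy = 2.0 * resid / resid.size
                grads = model.core.backward(cache, dy)
                adam.step(model.core.params, grads, lr, clip_norm=config.grad_clip)
                epoch_loss += loss * len(sel)
            losses.append(epoch_loss / len(starts))
        history.append(losses)
    return model, history


def predict_curves(model: GaitLSTM, input: SignalChannel,
                   side: Side = "L", chunk_length: int | None = None,
                   chunk_overlap: int | None = None) -> tuple[ConfidenceCurve, ConfidenceCurve]:
    """Predict the HS and TO confidence curves for one normalized channel.

    The sequence is processed in overlapping chunks (batched, so long
    trials stay fast); each chunk's warm-up samples are discarded except
    at the very start of the sequence.  ``chunk_length``/``chunk_overlap``
    default to the training configuration; longer prediction chunks give
    the recurrent state more context and cost less stitching overhead.
    """
    x = input.values
    if x.size == 0:
        raise ValueError("cannot predict on a length-0 input")
    L = model.config.chunk_length_samples if chunk_length is None else chunk_length
    V = model.config.chunk_overlap_samples if chunk_overlap is None else chunk_overlap
    if not 0 <= V < L:
        raise ValueError("chunk overlap must be shorter than the chunk")
    starts = _chunk_starts(x.size, L, V)
    length = min(L, x.size)
    xb = np.stack([x[s:s + length, None] for s in starts])
    yb, _ = model.core.forward(xb)
    out = np.empty((x.size, 2))
    written = 0
    for k, s in enumerate(starts):
        out[written:s + length] = yb[k, written - s:, :]
        written = s + length
    if not np.all(np.isfinite(out)):
        raise ValueError("model produced non-finite confidence values")
    hs = ConfidenceCurve(out[:, 0], input.rate_hz, side, "HS")
    to = ConfidenceCurve(out[:, 1], input.rate_hz, side, "TO")
    return hs, to
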