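"""Minimal LSTM sequence regressor: NumPy forward pass, backpropagation
through time, and Adam.

One LSTM layer over a single-feature input, followed by a linear map to
two outputs (the HS and TO confidence values at each time step), trained
with mean-squared-error loss.  Written for small models (tens to a few
hundred hidden units) on CPU; all state is plain float64 arrays so runs
are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMCore", "AdamState", "DivergenceError"]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random orthogonal matrix (QR of a Gaussian, sign-corrected)."""
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


class LSTMCore:
    """Parameters and forward/backward passes of the regressor.

    Gate layout in the fused weight matrices is (input, forget, cell,
    output).  Input/output weights are initialised uniformly in
    [-1/sqrt(H), 1/sqrt(H)]; the recurrent block of each gate is
    orthogonal, which markedly speeds up convergence of the timing
    dynamics; the forget-gate bias is raised by +1 so early training does
    not forget the stride-period context it needs.
    """

    def __init__(self, input_size: int, hidden_size: int, output_size: int,
                 rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.output_size = output_size
        H = hidden_size
        k = 1.0 / np.sqrt(H)
        u = lambda *shape: rng.uniform(-k, k, shape)
        self.params: dict[str, np.ndarray] = {
            "Wx": u(input_size, 4 * H),
            "Wh": np.concatenate([_orthogonal(H, rng) for _ in range(4)], axis=1),
            "b": u(4 * H),
            "Wy": u(H, output_size),
            "by": u(output_size),
        }
        self.params["b"][H:2 * H] += 1.0  # forget-gate bias

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Run the network over a batch of sequences.

        x has shape (B, T, input_size); returns y of shape
        (B, T, output_size) and, when requested, the cache needed by
        :meth:`backward`.
        """
        B, T, D = x.shape
        H = self.hidden_size
        Wx, Wh, b, Wy, by = (self.params[k] for k in ("Wx", "Wh", "b", "Wy", "by"))
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates = np.empty((T, B, 4 * H)) if want_cache else None
        cs = np.empty((T, B, H)) if want_cache else None
        tanh_cs = np.empty((T, B, H)) if want_cache else None
        hs = np.empty((T, B, H))
        for t in range(T):
            z = x[:, t, :] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[t] = h
            if want_cache:
                gates[t, :, :H] = i
                gates[t, :, H:2 * H] = f
                gates[t, :, 2 * H:3 * H] = g
                gates[t, :, 3 * H:] = o
                cs[t] = c
                tanh_cs[t] = tc
        y = hs.transpose(1, 0, 2) @ Wy + by
        cache = (x, gates, cs, tanh_cs, hs) if want_cache else None
        return y, cache

    def backward(self, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. all parameters.

        ``dy`` is dLoss/dy with shape (B, T, output_size).
        """
        x, gates, cs, tanh_cs, hs = cache
        B, T, D = x.shape
        H = self.hidden_size
        Wh, Wy = self.params["Wh"], self.params["Wy"]

        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        hs_flat = hs.transpose(1, 0, 2).reshape(B * T, H)
        dy_flat = dy.reshape(B * T, self.output_size)
        grads["Wy"] = hs_flat.T @ dy_flat
        grads["by"] = dy_flat.sum(axis=0)

        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        dy_t = dy.transpose(1, 0, 2)  # (T, B, out)
        for t in range(T - 1, -1, -1):
            i = gates[t, :, :H]
            f = gates[t, :, H:2 * H]
            g = gates[t, :, 2 * H:3 * H]
            o = gates[t, :, 3 * H:]
            tc = tanh_cs[t]
            c_prev = cs[t - 1] if t > 0 else np.zeros((B, H))
            h_prev = hs[t - 1] if t > 0 else np.zeros((B, H))

            dh = dy_t[t] @ Wy.T + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dz = np.empty((B, 4 * H))
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
            dz[:, 3 * H:] = dh * tc * o * (1.0 - o)

            grads["Wx"] += x[:, t, :].T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh_next = dz @ Wh.T
            dc_next = dc * f
        return grads


class AdamState:
    """Adam optimiser state for one parameter set."""

    def __init__(self, params: dict[str, np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float, clip_norm: float | None = None) -> None:
        if clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > clip_norm:
                scale = clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k in params:
            self.m[k] = b1 * self.m[k] + (1 - b1) * grads[k]
            self.v[k] = b2 * self.v[k] + (1 - b2) * grads[k] ** 2
            m_hat = self.m[k] / bias1
            v_hat = self.v[k] / bias2
            params[k] -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
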