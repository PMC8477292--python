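"""The hierarchical visit-sequence network (HVec).

Architecture (record level -> person level -> heads):

* **record encoder** — one fully-connected layer with tanh nonlinearity
  mapping the 707-dim record vector to a ``visit_embed_size`` (default 200)
  record embedding, with dropout on its output during training;
* **person state** — an LSTM consumes record embeddings in date order and
  maintains a ``rnn_output_size`` (default 128) hidden state, the *person
  vector*, reset to zeros at the start of each person's sequence;
* **heads** — eight independent affine maps from the person vector: the two
  main classification targets (30-day mortality, 30-day readmission,
  logits), three autoencoder reconstructions partitioning the 707-dim input
  (code spans 640 / demographic+care-site context 48 / statistics+history
  19), two cost regressions (memorize the current record's total cost,
  predict the next record's), and a cardiac-arrest-record classifier.

The implementation is plain NumPy with hand-written backpropagation.  The
backward pass accepts a *stack* of per-task head gradients and propagates
them through the shared encoder/LSTM in one vectorized pass, returning one
flat gradient vector per task — exactly what the cosine-gated multitask
update needs.

Everything is deterministic given the init seed and (in training mode) an
explicit dropout RNG; evaluation mode is a pure function of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .featurization import GROUP_SLICES, TOTAL_DIM

__all__ = ["HVecParams", "PersonState", "HeadOutputs", "HVecModel", "HEAD_SPECS"]

#: Head name -> output dimension, in canonical parameter order.
HEAD_SPECS: tuple[tuple[str, int], ...] = (
    ("mortality", 1),
    ("readmission", 1),
    ("recon_codes", GROUP_SLICES["codes"].stop - GROUP_SLICES["codes"].start),      # 640
    ("recon_context", GROUP_SLICES["context"].stop - GROUP_SLICES["context"].start),  # 48
    ("recon_history", GROUP_SLICES["stats"].stop - GROUP_SLICES["stats"].start),    # 19
    ("cur_cost", 1),
    ("fut_cost", 1),
    ("ihca", 1),
)


@dataclass(frozen=True)
class HVecParams:
    """Model hyperparameters (defaults per the reference configuration)."""

    visit_embed_size: int = 200
    rnn_output_size: int = 128
    learning_rate: float = 1e-3
    dropout_rate: float = 0.5
    l2_weight: float = 0.01
    code_embed_size: int = 128
    input_dim: int = TOTAL_DIM
    init_seed: int = 0

    def validate(self) -> None:
        if min(self.visit_embed_size, self.rnn_output_size,
               self.code_embed_size, self.input_dim) < 1:
            raise ValueError("all sizes must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class PersonState:
    """LSTM carry for one person; zeros at the start of each sequence."""

    hidden: np.ndarray
    cell: np.ndarray

    @classmethod
    def initial(cls, rnn_output_size: int, batch: Optional[int] = None) -> "PersonState":
        shape = (rnn_output_size,) if batch is None else (batch, rnn_output_size)
        return cls(np.zeros(shape), np.zeros(shape))


@dataclass
class HeadOutputs:
    """Raw head outputs for one person vector (logits / linear values)."""

    mortality_logit: float
    readmission_logit: float
    reconstruction_codes: np.ndarray
    reconstruction_context: np.ndarray
    reconstruction_history: np.ndarray
    current_cost_pred: float
    future_cost_pred: float
    ihca_logit: float


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class HVecModel:
    """Encoder + LSTM + multitask heads with per-task backprop."""

    def __init__(self, params: HVecParams = HVecParams()):
        params.validate()
        self.params = params
        rng = np.random.default_rng(params.init_seed)
        D, E, H = params.input_dim, params.visit_embed_size, params.rnn_output_size
        w: dict[str, np.ndarray] = {}
        w["enc_W"] = rng.normal(0.0, 1.0 / np.sqrt(D), size=(D, E))
        w["enc_b"] = np.zeros(E)
        w["lstm_Wx"] = rng.normal(0.0, 1.0 / np.sqrt(E), size=(E, 4 * H))
        w["lstm_Wh"] = rng.normal(0.0, 1.0 / np.sqrt(H), size=(H, 4 * H))
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        w["lstm_b"] = b
        for name, out in HEAD_SPECS:
            w[f"head_{name}_W"] = rng.normal(0.0, 1.0 / np.sqrt(H), size=(H, out))
            w[f"head_{name}_b"] = np.zeros(out)
        self.weights = w
        self._param_names = list(w.keys())

    # -- parameter vector utilities -----------------------------------------

    @property
    def param_names(self) -> list[str]:
        return list(self._param_names)

    def n_params(self) -> int:
        return sum(self.weights[n].size for n in self._param_names)

    def param_vector(self) -> np.ndarray:
        return np.concatenate([self.weights[n].ravel() for n in self._param_names])

    def set_param_vector(self, v: np.ndarray) -> None:
        off = 0
        for n in self._param_names:
            w = self.weights[n]
            self.weights[n] = v[off:off + w.size].reshape(w.shape).copy()
            off += w.size
        if off != v.size:
            raise ValueError("parameter vector length mismatch")

    def grads_to_vector(self, grads: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([
            np.ravel(grads.get(n, np.zeros_like(self.weights[n])))
            for n in self._param_names
        ])

    def weight_mask_vector(self) -> np.ndarray:
        """1 for weight-matrix entries, 0 for biases (L2 applies to weights only)."""
        return np.concatenate([
            np.full(self.weights[n].size, 0.0 if n.endswith("_b") else 1.0)
            for n in self._param_names
        ])

    # -- forward -------------------------------------------------------------

    def encode_record(self, x: np.ndarray, training: bool = False,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Record embedding: tanh affine map (+ dropout in training mode)."""
        e = np.tanh(x @ self.weights["enc_W"] + self.weights["enc_b"])
        if training and self.params.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode encoding requires an RNG")
            keep = 1.0 - self.params.dropout_rate
            e = e * (rng.random(e.shape) < keep) / keep
        return e

    def step_person(self, state: PersonState, record_embedding: np.ndarray
                    ) -> tuple[PersonState, np.ndarray]:
        """One LSTM step; the person vector is the new hidden state."""
        H = self.params.rnn_output_size
        if state.hidden.shape[-1] != H or state.cell.shape[-1] != H:
            raise ValueError("PersonState dimensions do not match rnn_output_size")
        z = (record_embedding @ self.weights["lstm_Wx"]
             + state.hidden @ self.weights["lstm_Wh"] + self.weights["lstm_b"])
        i = _sigmoid(z[..., :H])
        f = _sigmoid(z[..., H:2 * H])
        g = np.tanh(z[..., 2 * H:3 * H])
        o = _sigmoid(z[..., 3 * H:])
        c = f * state.cell + i * g
        h = o * np.tanh(c)
        return PersonState(h, c), h

    def predict_heads(self, person_vector: np.ndarray) -> HeadOutputs:
        """All eight head outputs for a single person vector."""
        w = self.weights
        y = {name: person_vector @ w[f"head_{name}_W"] + w[f"head_{name}_b"]
             for name, _ in HEAD_SPECS}
        return HeadOutputs(
            mortality_logit=float(y["mortality"][0]),
            readmission_logit=float(y["readmission"][0]),
            reconstruction_codes=y["recon_codes"],
            reconstruction_context=y["recon_context"],
            reconstruction_history=y["recon_history"],
            current_cost_pred=float(y["cur_cost"][0]),
            future_cost_pred=float(y["fut_cost"][0]),
            ihca_logit=float(y["ihca"][0]),
        )

    def head_outputs_batch(self, h: np.ndarray, names: Optional[list[str]] = None
                           ) -> dict[str, np.ndarray]:
        """Head outputs for an (..., H) stack of person vectors."""
        w = self.weights
        if names is None:
            names = [n for n, _ in HEAD_SPECS]
        return {n: h @ w[f"head_{n}_W"] + w[f"head_{n}_b"] for n in names}

    def forward_batch(self, X: np.ndarray, lengths: np.ndarray,
                      training: bool = False,
                      rng: Optional[np.random.Generator] = None) -> dict:
        """Forward pass over a padded batch.

        X is (B, T, input_dim) with zero padding past each person's length;
        returns a cache holding every intermediate needed for backprop,
        including the (B, T, H) stack of person vectors ``h``.
        """
        B, T, D = X.shape
        H = self.params.rnn_output_size
        e = np.tanh(X @ self.weights["enc_W"] + self.weights["enc_b"])
        if training and self.params.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode forward requires an RNG")
            keep = 1.0 - self.params.dropout_rate
            dmask = (rng.random(e.shape) < keep) / keep
        else:
            dmask = np.ones_like(e)
        e_d = e * dmask

        i_s = np.empty((B, T, H)); f_s = np.empty((B, T, H))
        g_s = np.empty((B, T, H)); o_s = np.empty((B, T, H))
        c_s = np.empty((B, T, H)); tc_s = np.empty((B, T, H))
        h_s = np.empty((B, T, H))
        h = np.zeros((B, H)); c = np.zeros((B, H))
        Wx, Wh, b = self.weights["lstm_Wx"], self.weights["lstm_Wh"], self.weights["lstm_b"]
        for t in range(T):
            z = e_d[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H]); f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H]); o = _sigmoid(z[:, 3 * H:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            i_s[:, t], f_s[:, t], g_s[:, t], o_s[:, t] = i, f, g, o
            c_s[:, t], tc_s[:, t], h_s[:, t] = c, tc, h
        mask = (np.arange(T)[None, :] < np.asarray(lengths)[:, None])
        return {"X": X, "e": e, "dmask": dmask, "e_d": e_d,
                "i": i_s, "f": f_s, "g": g_s, "o": o_s,
                "c": c_s, "tanh_c": tc_s, "h": h_s, "mask": mask}

    # -- backward ------------------------------------------------------------

    def backward_tasks(self, cache: dict, dh_tasks: np.ndarray,
                       head_grads: list[dict[str, np.ndarray]]) -> np.ndarray:
        """Per-task gradients through the shared encoder and LSTM.

        ``dh_tasks`` is (K, B, T, H): for each of K tasks, the gradient of
        that task's scalar loss w.r.t. every person vector (already masked to
        zero at padded positions).  ``head_grads`` gives, per task, the
        gradients of its own head parameters (dict name -> array).  Returns a
        (K, n_params) array of flat per-task gradient vectors.
        """
        # Gradient arithmetic runs in single precision: the loss surfaces are
        # smooth, first-order optimizers tolerate 1e-7 relative gradient
        # noise, and the contractions below dominate training cost.  The
        # forward pass (and hence every prediction contract) stays float64.
        f32 = np.float32
        X = cache["X"].astype(f32, copy=False)
        e = cache["e"].astype(f32, copy=False)
        dmask = cache["dmask"].astype(f32, copy=False)
        e_d = cache["e_d"].astype(f32, copy=False)
        i_s = cache["i"].astype(f32, copy=False)
        f_s = cache["f"].astype(f32, copy=False)
        g_s = cache["g"].astype(f32, copy=False)
        o_s = cache["o"].astype(f32, copy=False)
        c_s = cache["c"].astype(f32, copy=False)
        tc_s = cache["tanh_c"].astype(f32, copy=False)
        h_all = cache["h"].astype(f32, copy=False)
        dh_tasks = dh_tasks.astype(f32, copy=False)
        K = dh_tasks.shape[0]
        B, T, D = X.shape
        E = e.shape[-1]
        H = self.params.rnn_output_size
        Wx = self.weights["lstm_Wx"].astype(f32)
        Wh = self.weights["lstm_Wh"].astype(f32)

        # Sequential pass: gate gradients dz per step.  dz is stored in
        # (B, T, K, Z) layout so the heavy weight contractions below are
        # single BLAS calls on contiguous memory.
        Z = 4 * H
        dz_all = np.empty((B, T, K, Z), dtype=f32)
        dh_next = np.zeros((K, B, H), dtype=f32)
        dc_next = np.zeros((K, B, H), dtype=f32)
        for t in range(T - 1, -1, -1):
            dh = dh_tasks[:, :, t] + dh_next
            i, f, g, o = i_s[:, t], f_s[:, t], g_s[:, t], o_s[:, t]
            tc = tc_s[:, t]
            c_prev = c_s[:, t - 1] if t > 0 else np.zeros((B, H), dtype=f32)
            dc = dh * o * (1.0 - tc * tc) + dc_next
            dz = np.empty((K, B, Z), dtype=f32)
            dz[..., :H] = (dc * g) * i * (1.0 - i)
            dz[..., H:2 * H] = (dc * c_prev) * f * (1.0 - f)
            dz[..., 2 * H:3 * H] = (dc * i) * (1.0 - g * g)
            dz[..., 3 * H:] = (dh * tc) * o * (1.0 - o)
            dz_all[:, t] = dz.transpose(1, 0, 2)
            dh_next = (dz.reshape(K * B, Z) @ Wh.T).reshape(K, B, H)
            dc_next = dc * f

        dz_flat = dz_all.reshape(B * T, K * Z)
        dWx = np.moveaxis(
            (e_d.reshape(B * T, E).T @ dz_flat).reshape(E, K, Z), 1, 0)
        h_prev_all = np.concatenate(
            [np.zeros((B, 1, H), dtype=f32), h_all[:, :-1]], axis=1)
        dWh = np.moveaxis(
            (h_prev_all.reshape(B * T, H).T @ dz_flat).reshape(H, K, Z), 1, 0)
        db = dz_all.sum(axis=(0, 1))
        # dpre kept in (B, T, K, E) layout for the encoder contraction.
        dpre = (dz_flat.reshape(B * T * K, Z) @ Wx.T).reshape(B, T, K, E)
        dpre *= dmask[:, :, None, :]
        dpre *= (1.0 - e * e)[:, :, None, :]
        denc_W = np.moveaxis(
            (X.reshape(B * T, D).T @ dpre.reshape(B * T, K * E)).reshape(D, K, E), 1, 0)
        denc_b = dpre.sum(axis=(0, 1))

        out = np.zeros((K, self.n_params()))
        offsets = {}
        off = 0
        for n in self._param_names:
            offsets[n] = off
            off += self.weights[n].size
        for k in range(K):
            grads = {"enc_W": denc_W[k], "enc_b": denc_b[k],
                     "lstm_Wx": dWx[k], "lstm_Wh": dWh[k], "lstm_b": db[k]}
            grads.update(head_grads[k])
            for n, g in grads.items():
                o0 = offsets[n]
                out[k, o0:o0 + g.size] = np.ravel(g)
        return out
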