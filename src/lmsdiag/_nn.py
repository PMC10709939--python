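"""A small, deterministic feedforward binary classifier in pure numpy.

Architecture: ``n_hidden_layers`` equal-width hidden blocks, each
Linear -> BatchNorm -> ReLU -> Dropout, followed by a single sigmoid output
unit.  Trained with Adam (fixed learning rate) on binary cross-entropy.
All randomness (init, shuffling, dropout masks) comes from one seeded
generator, so training is reproducible on a given platform.

Sized for tabular inputs with tens of features and ~100 samples; everything
is dense float64, no attempt at large-scale efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-8


@dataclass
class _Param:
    value: np.ndarray
    m: np.ndarray = field(init=False)
    v: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class FeedForwardNet:
    """Binary MLP with batch-norm and dropout; see module docstring."""

    def __init__(
        self,
        n_features: int,
        n_hidden_layers: int,
        n_hidden_nodes: int,
        dropout_rate: float,
        seed: int = 0,
    ) -> None:
        self.n_features = n_features
        self.n_hidden_layers = n_hidden_layers
        self.n_hidden_nodes = n_hidden_nodes
        self.dropout_rate = float(dropout_rate)
        self.rng = np.random.default_rng(seed)
        self._t = 0  # Adam step counter

        dims = [n_features] + [n_hidden_nodes] * n_hidden_layers
        self.W: list[_Param] = []
        self.b: list[_Param] = []
        self.gamma: list[_Param] = []
        self.beta: list[_Param] = []
        self.run_mean: list[np.ndarray] = []
        self.run_var: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            # He initialization for ReLU blocks
            self.W.append(_Param(self.rng.normal(0, np.sqrt(2.0 / d_in), (d_in, d_out))))
            self.b.append(_Param(np.zeros(d_out)))
            self.gamma.append(_Param(np.ones(d_out)))
            self.beta.append(_Param(np.zeros(d_out)))
            self.run_mean.append(np.zeros(d_out))
            self.run_var.append(np.ones(d_out))
        self.W_out = _Param(self.rng.normal(0, np.sqrt(1.0 / dims[-1]), (dims[-1], 1)))
        self.b_out = _Param(np.zeros(1))

    # ---- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        cache = []
        A = X
        for l in range(self.n_hidden_layers):
            Z = A @ self.W[l].value + self.b[l].value
            if training:
                mu = Z.mean(axis=0)
                var = Z.var(axis=0)
                self.run_mean[l] = _BN_MOMENTUM * self.run_mean[l] + (1 - _BN_MOMENTUM) * mu
                self.run_var[l] = _BN_MOMENTUM * self.run_var[l] + (1 - _BN_MOMENTUM) * var
            else:
                mu, var = self.run_mean[l], self.run_var[l]
            inv_std = 1.0 / np.sqrt(var + _BN_EPS)
            Zhat = (Z - mu) * inv_std
            H = self.gamma[l].value * Zhat + self.beta[l].value
            relu_mask = H > 0
            A_next = H * relu_mask
            if training and self.dropout_rate > 0:
                keep = 1.0 - self.dropout_rate
                drop_mask = (self.rng.random(A_next.shape) < keep) / keep
                A_next = A_next * drop_mask
            else:
                drop_mask = None
            cache.append((A, Z, Zhat, inv_std, relu_mask, drop_mask))
            A = A_next
        logits = A @ self.W_out.value + self.b_out.value
        p = 1.0 / (1.0 + np.exp(-logits))
        return p.ravel(), A, cache

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p, _, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return p

    def hidden_representation(self, X: np.ndarray) -> np.ndarray:
        """Activations of the last hidden layer in inference mode."""
        _, A, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return A

    # ---- backward / training ----------------------------------------------

    def _adam_step(self, param: _Param, grad: np.ndarray, lr: float) -> None:
        param.m = _ADAM_B1 * param.m + (1 - _ADAM_B1) * grad
        param.v = _ADAM_B2 * param.v + (1 - _ADAM_B2) * grad**2
        m_hat = param.m / (1 - _ADAM_B1**self._t)
        v_hat = param.v / (1 - _ADAM_B2**self._t)
        param.value -= lr * m_hat / (np.sqrt(v_hat) + _ADAM_EPS)

    def _train_batch(self, X: np.ndarray, y: np.ndarray, lr: float) -> float:
        n = X.shape[0]
        p, A_last, cache = self._forward(X, training=True)
        eps = 1e-12
        loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))

        self._t += 1
        dlogits = ((p - y) / n)[:, None]
        dW_out = A_last.T @ dlogits
        db_out = dlogits.sum(axis=0)
        dA = dlogits @ self.W_out.value.T
        self._adam_step(self.W_out, dW_out, lr)
        self._adam_step(self.b_out, db_out, lr)

        for l in range(self.n_hidden_layers - 1, -1, -1):
            A_in, Z, Zhat, inv_std, relu_mask, drop_mask = cache[l]
            if drop_mask is not None:
                dA = dA * drop_mask
            dH = dA * relu_mask
            dgamma = (dH * Zhat).sum(axis=0)
            dbeta = dH.sum(axis=0)
            dZhat = dH * self.gamma[l].value
            # batch-norm backward (batch statistics)
            m = Z.shape[0]
            dZ = (inv_std / m) * (
                m * dZhat - dZhat.sum(axis=0) - Zhat * (dZhat * Zhat).sum(axis=0)
            )
            dW = A_in.T @ dZ
            db = dZ.sum(axis=0)
            dA = dZ @ self.W[l].value.T
            self._adam_step(self.gamma[l], dgamma, lr)
            self._adam_step(self.beta[l], dbeta, lr)
            self._adam_step(self.W[l], dW, lr)
            self._adam_step(self.b[l], db, lr)
        return float(loss)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        learning_rate: float = 0.001,
    ) -> list[float]:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        batch_size = max(2, min(batch_size, n))
        history = []
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                if idx.size < 2:
                    continue  # batch-norm needs >= 2 samples
                losses.append(self._train_batch(X[idx], y[idx], learning_rate))
            history.append(float(np.mean(losses)))
        return history

    # ---- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_hidden_layers": self.n_hidden_layers,
            "n_hidden_nodes": self.n_hidden_nodes,
            "dropout_rate": self.dropout_rate,
            "W": [p.value.tolist() for p in self.W],
            "b": [p.value.tolist() for p in self.b],
            "gamma": [p.value.tolist() for p in self.gamma],
            "beta": [p.value.tolist() for p in self.beta],
            "run_mean": [a.tolist() for a in self.run_mean],
            "run_var": [a.tolist() for a in self.run_var],
            "W_out": self.W_out.value.tolist(),
            "b_out": self.b_out.value.tolist(),
        }

    @classmethod
    def from_state_dict(cls, state: dict) -> "FeedForwardNet":
        net = cls(
            state["n_features"], state["n_hidden_layers"], state["n_hidden_nodes"],
            state["dropout_rate"], seed=0,
        )
        for l in range(net.n_hidden_layers):
            net.W[l].value = np.array(state["W"][l])
            net.b[l].value = np.array(state["b"][l])
            net.gamma[l].value = np.array(state["gamma"][l])
            net.beta[l].value = np.array(state["beta"][l])
            net.run_mean[l] = np.array(state["run_mean"][l])
            net.run_var[l] = np.array(state["run_var"][l])
        net.W_out.value = np.array(state["W_out"])
        net.b_out.value = np.array(state["b_out"])
        return net
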