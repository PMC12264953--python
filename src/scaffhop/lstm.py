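"""A NumPy LSTM language model over SMILES tokens.

Implements exactly what the generator and the RL engine need, with no
autodiff framework: stacked LSTM layers with an embedding and a softmax
output head, per-sequence negative log-likelihoods (NLL, in nats), full
backpropagation through time for arbitrary per-sequence loss weights, Adam
updates, and seeded autoregressive sampling with temperature.

Two loss shapes share one backward pass:

* maximum-likelihood training minimizes ``mean_i NLL_i`` — weights ``1/B``;
* the RL squared loss ``mean_i (NLL_aug_i - NLL_agent_i)^2`` has gradient
  ``2/B * (NLL_agent_i - NLL_aug_i) * dNLL_i/dtheta`` — the caller passes
  those per-sequence factors as ``weights``.

All arithmetic is float32; sequence batches are padded with token 0.
"""

from __future__ import annotations

import copy

import numpy as np

from .vocab import Vocabulary

__all__ = ["SmilesLSTM", "Adam"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class SmilesLSTM:
    """Stacked LSTM over a SMILES vocabulary.

    Parameters follow the common recurrent language-model recipe: token
    embedding, ``num_layers`` LSTM layers of ``hidden_dim`` units, and a
    linear projection back to the vocabulary. Weights are uniform
    ``+-1/sqrt(fan_in)`` initialized from a seeded generator; the forget-gate
    bias starts at 1 so fresh models keep context by default.
    """

    def __init__(
        self,
        vocab: Vocabulary,
        embedding_dim: int = 128,
        hidden_dim: int = 256,
        num_layers: int = 2,
        seed: int = 42,
    ) -> None:
        self.vocab = vocab
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        self.num_layers = num_layers
        rng = np.random.default_rng(seed)
        V, D, H = len(vocab), embedding_dim, hidden_dim

        def init(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape).astype(np.float32)

        self.params: dict[str, np.ndarray] = {"E": init((V, D), D)}
        for layer in range(num_layers):
            d_in = D if layer == 0 else H
            self.params[f"Wx{layer}"] = init((d_in, 4 * H), d_in)
            self.params[f"Wh{layer}"] = init((H, 4 * H), H)
            b = np.zeros(4 * H, dtype=np.float32)
            b[H : 2 * H] = 1.0
            self.params[f"b{layer}"] = b
        self.params["Wo"] = init((H, V), H)
        self.params["bo"] = np.zeros(V, dtype=np.float32)

    # -- batching -----------------------------------------------------------

    @property
    def dtype(self):
        return self.params["E"].dtype

    def _pad(self, seqs: list[list[int]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Inputs ``^ + seq``, targets ``seq + $``, and the target mask."""
        B = len(seqs)
        T = max((len(s) for s in seqs), default=0) + 1
        X = np.zeros((B, T), dtype=np.int64)
        Y = np.zeros((B, T), dtype=np.int64)
        M = np.zeros((B, T), dtype=self.dtype)
        for i, s in enumerate(seqs):
            X[i, 0] = self.vocab.begin
            X[i, 1 : len(s) + 1] = s
            Y[i, : len(s)] = s
            Y[i, len(s)] = self.vocab.end
            M[i, : len(s) + 1] = 1.0
        return X, Y, M

    # -- forward / backward -------------------------------------------------

    def _step(self, x, h, c, layer):
        """One LSTM cell update; returns (h_new, c_new, gate cache)."""
        H = self.hidden_dim
        p = self.params
        z = x @ p[f"Wx{layer}"] + h @ p[f"Wh{layer}"] + p[f"b{layer}"]
        ai = _sigmoid(z[:, :H])
        af = _sigmoid(z[:, H : 2 * H])
        ag = np.tanh(z[:, 2 * H : 3 * H])
        ao = _sigmoid(z[:, 3 * H :])
        c_new = af * c + ai * ag
        tc = np.tanh(c_new)
        return ao * tc, c_new, (x, h, c, ai, af, ag, ao, tc)

    def _forward(self, seqs, keep_cache):
        X, Y, M = self._pad(seqs)
        B, T = X.shape
        H, L = self.hidden_dim, self.num_layers
        p = self.params
        h = [np.zeros((B, H), dtype=self.dtype) for _ in range(L)]
        c = [np.zeros((B, H), dtype=self.dtype) for _ in range(L)]
        nll = np.zeros(B, dtype=self.dtype)
        steps = []
        for t in range(T):
            x = p["E"][X[:, t]]
            layer_caches = []
            for layer in range(L):
                h[layer], c[layer], cache = self._step(x, h[layer], c[layer], layer)
                x = h[layer]
                if keep_cache:
                    layer_caches.append(cache)
            logits = x @ p["Wo"] + p["bo"]
            logits[:, self.vocab.pad] = -1e30  # same support as sampling
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            logp = np.log(probs[np.arange(B), Y[:, t]] + 1e-30)
            nll -= logp * M[:, t]
            if keep_cache:
                steps.append((X[:, t], Y[:, t], M[:, t], probs, x, layer_caches))
        return nll, (steps, B, T)

    def nll(self, seqs: list[list[int]]) -> np.ndarray:
        """Per-sequence NLL in nats (forward only)."""
        return self._forward(seqs, keep_cache=False)[0]

    def nll_and_grads(
        self, seqs: list[list[int]], weights: np.ndarray
    ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        """NLLs plus gradients of ``sum_i weights_i * NLL_i`` (BPTT)."""
        nll, (steps, B, T) = self._forward(seqs, keep_cache=True)
        H, L = self.hidden_dim, self.num_layers
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh = [np.zeros((B, H), dtype=self.dtype) for _ in range(L)]
        dc = [np.zeros((B, H), dtype=self.dtype) for _ in range(L)]
        w = np.asarray(weights, dtype=self.dtype)[:, None]
        for t in range(T - 1, -1, -1):
            x_ids, y_ids, mask, probs, h_top, layer_caches = steps[t]
            dlogits = probs.copy()
            dlogits[np.arange(B), y_ids] -= 1.0
            dlogits *= mask[:, None] * w
            grads["Wo"] += h_top.T @ dlogits
            grads["bo"] += dlogits.sum(axis=0)
            dx = dlogits @ p["Wo"].T
            for layer in range(L - 1, -1, -1):
                x_in, h_prev, c_prev, ai, af, ag, ao, tc = layer_caches[layer]
                dht = dx + dh[layer]
                dct = dc[layer] + dht * ao * (1.0 - tc * tc)
                dzi = dct * ag * ai * (1.0 - ai)
                dzf = dct * c_prev * af * (1.0 - af)
                dzg = dct * ai * (1.0 - ag * ag)
                dzo = dht * tc * ao * (1.0 - ao)
                dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
                grads[f"Wx{layer}"] += x_in.T @ dz
                grads[f"Wh{layer}"] += h_prev.T @ dz
                grads[f"b{layer}"] += dz.sum(axis=0)
                dx = dz @ p[f"Wx{layer}"].T
                dh[layer] = dz @ p[f"Wh{layer}"].T
                dc[layer] = dct * af
            np.add.at(grads["E"], x_ids, dx)
        return nll, grads

    # -- sampling -----------------------------------------------------------

    def sample(
        self,
        n: int,
        max_len: int = 100,
        temperature: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> tuple[list[list[int]], np.ndarray]:
        """Draw ``n`` token sequences autoregressively.

        Temperature rescales the sampling distribution only; the returned
        NLLs are always the model's own (temperature-1) likelihoods, which is
        what both the RL loss and the frequency/likelihood consistency check
        need. ``temperature=0`` is greedy argmax decoding.
        """
        if rng is None:
            rng = np.random.default_rng(0)
        p = self.params
        H, L = self.hidden_dim, self.num_layers
        h = [np.zeros((n, H), dtype=self.dtype) for _ in range(L)]
        c = [np.zeros((n, H), dtype=self.dtype) for _ in range(L)]
        tok = np.full(n, self.vocab.begin, dtype=np.int64)
        alive = np.ones(n, dtype=bool)
        nll = np.zeros(n, dtype=self.dtype)
        seqs: list[list[int]] = [[] for _ in range(n)]
        for _ in range(max_len + 1):
            x = p["E"][tok]
            for layer in range(L):
                h[layer], c[layer], _ = self._step(x, h[layer], c[layer], layer)
                x = h[layer]
            logits = x @ p["Wo"] + p["bo"]
            logits[:, self.vocab.pad] = -1e30  # never emit padding
            shifted = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(shifted)
            probs /= probs.sum(axis=1, keepdims=True)
            if temperature == 0.0:
                nxt = probs.argmax(axis=1)
            else:
                if temperature != 1.0:
                    tempered = np.exp(shifted / temperature)
                    tempered /= tempered.sum(axis=1, keepdims=True)
                else:
                    tempered = probs
                u = rng.random(n)
                nxt = (tempered.cumsum(axis=1) < u[:, None]).sum(axis=1)
                nxt = np.minimum(nxt, len(self.vocab) - 1)
            nll -= np.where(alive, np.log(probs[np.arange(n), nxt] + 1e-30), 0.0)
            for i in np.flatnonzero(alive):
                if nxt[i] == self.vocab.end:
                    alive[i] = False
                else:
                    seqs[i].append(int(nxt[i]))
            tok = np.where(alive, nxt, self.vocab.pad)
            if not alive.any():
                break
        # sequences cut off at max_len never emitted the end token; score
        # them with a clean forward pass so their NLL includes it
        if alive.any():
            idx = np.flatnonzero(alive)
            nll_end = self.nll([seqs[i] for i in idx])
            nll[idx] = nll_end
        return seqs, nll

    def clone(self) -> "SmilesLSTM":
        twin = copy.copy(self)
        twin.params = {k: v.copy() for k, v in self.params.items()}
        return twin


class Adam:
    """Adam over a parameter dict, with global-norm gradient clipping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3, clip: float = 5.0):
        self.lr = lr
        self.clip = clip
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = self.clip / norm if norm > self.clip else 1.0
        for k, p in params.items():
            g = grads[k] * scale
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
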