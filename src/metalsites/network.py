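"""Convolutional-recurrent network core, implemented directly on numpy.

Architecture: 1-D convolution over the residue axis (window w, zero-padded so
sequence length is preserved) with ReLU, a unidirectional GRU whose final
hidden state h_L summarises the whole chain, and a linear layer with two
output neurons followed by softmax.  Training uses class-weighted
cross-entropy, Adam, and full backpropagation through time.

Variable-length sequences are processed in batches padded with zero feature
rows; since the convolution zero-pads its ends anyway and the readout (and
thus every gradient) comes from each sequence's own step L, the batched
computation is exactly equivalent to per-sequence processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetParams", "ConvGRUNet"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class NetParams:
    """All trainable tensors.  GRU gate layout along the last axis: r, z, n."""

    Wc: np.ndarray  # (w, n_in, C) conv filter
    bc: np.ndarray  # (C,)
    Wx: np.ndarray  # (C, 3H) input-to-hidden
    Wh: np.ndarray  # (H, 3H) hidden-to-hidden
    bx: np.ndarray  # (3H,)
    bh: np.ndarray  # (3H,)
    Wo: np.ndarray  # (H, n_out)
    bo: np.ndarray  # (n_out,)

    def copy(self) -> "NetParams":
        return NetParams(**{k: v.copy() for k, v in self.__dict__.items()})

    def as_dict(self) -> dict[str, np.ndarray]:
        return dict(self.__dict__)


class ConvGRUNet:
    """Stateless forward/backward machinery for the conv→GRU→linear net."""

    def __init__(self, n_in: int, conv_width: int, conv_channels: int,
                 hidden: int, n_out: int = 2):
        if conv_width < 1 or conv_width % 2 == 0:
            raise ValueError("conv_width must be a positive odd integer")
        self.n_in = n_in
        self.w = conv_width
        self.C = conv_channels
        self.H = hidden
        self.n_out = n_out

    # ---------------------------------------------------------------- init
    def init_params(self, rng: np.random.Generator) -> NetParams:
        def glorot(*shape):
            fan_in, fan_out = shape[-2] * (shape[0] if len(shape) == 3 else 1), shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        H, C = self.H, self.C
        bx = np.zeros(3 * H)
        # bias the update gate toward carrying state (z ≈ sigmoid(1)), so
        # accumulated evidence survives long sequences from the start
        bx[H:2 * H] = 1.0
        return NetParams(
            Wc=glorot(self.w, self.n_in, C),
            bc=np.zeros(C),
            Wx=glorot(C, 3 * H),
            Wh=glorot(H, 3 * H),
            bx=bx,
            bh=np.zeros(3 * H),
            Wo=glorot(H, self.n_out),
            bo=np.zeros(self.n_out),
        )

    # ------------------------------------------------------------- helpers
    def _conv_windows(self, X: np.ndarray) -> np.ndarray:
        """(B, L, F) → (B, L, w*F) stacked zero-padded windows."""
        B, L, F = X.shape
        pad = (self.w - 1) // 2
        Xp = np.zeros((B, L + 2 * pad, F))
        Xp[:, pad:pad + L] = X
        return np.concatenate(
            [Xp[:, k:k + L] for k in range(self.w)], axis=2
        )

    def conv_forward(self, X: np.ndarray, p: NetParams) -> tuple[np.ndarray, dict]:
        """Width-w 1-D convolution + ReLU; length preserved by zero padding."""
        B, L, F = X.shape
        if L < 1:
            raise ValueError("sequence length must be >= 1")
        win = self._conv_windows(X)  # (B, L, w*F)
        pre = win @ p.Wc.reshape(self.w * F, self.C) + p.bc
        act = np.maximum(pre, 0.0)
        return act, {"win": win, "pre": pre}

    def conv_backward(self, d_act: np.ndarray, cache: dict, p: NetParams,
                      grads: dict) -> None:
        d_pre = d_act * (cache["pre"] > 0)
        B, L, _ = d_pre.shape
        flat_win = cache["win"].reshape(B * L, -1)
        flat_d = d_pre.reshape(B * L, -1)
        grads["Wc"] += (flat_win.T @ flat_d).reshape(p.Wc.shape)
        grads["bc"] += flat_d.sum(axis=0)

    def gru_forward(self, A: np.ndarray, lengths: np.ndarray,
                    p: NetParams) -> tuple[np.ndarray, dict]:
        """Run the GRU over t=1..L; return h at each sequence's own L."""
        B, L, C = A.shape
        H = self.H
        Gx = A @ p.Wx + p.bx  # (B, L, 3H)
        h = np.zeros((B, H))
        hs = np.zeros((B, L, H))
        rs = np.zeros((B, L, H))
        zs = np.zeros((B, L, H))
        ns = np.zeros((B, L, H))
        ghn = np.zeros((B, L, H))
        for t in range(L):
            gh = h @ p.Wh + p.bh
            r = _sigmoid(Gx[:, t, :H] + gh[:, :H])
            z = _sigmoid(Gx[:, t, H:2 * H] + gh[:, H:2 * H])
            n = np.tanh(Gx[:, t, 2 * H:] + r * gh[:, 2 * H:])
            h = (1.0 - z) * n + z * h
            hs[:, t], rs[:, t], zs[:, t], ns[:, t] = h, r, z, n
            ghn[:, t] = gh[:, 2 * H:]
        hL = hs[np.arange(B), lengths - 1]
        return hL, {"A": A, "hs": hs, "rs": rs, "zs": zs, "ns": ns,
                    "ghn": ghn, "lengths": lengths}

    def gru_backward(self, d_hL: np.ndarray, cache: dict, p: NetParams,
                     grads: dict) -> np.ndarray:
        A, hs = cache["A"], cache["hs"]
        rs, zs, ns, ghn = cache["rs"], cache["zs"], cache["ns"], cache["ghn"]
        lengths = cache["lengths"]
        B, L, H = hs.shape
        dGx = np.zeros((B, L, 3 * H))
        dh = np.zeros((B, H))
        inject = np.zeros((B, L, H))
        inject[np.arange(B), lengths - 1] = d_hL
        for t in range(L - 1, -1, -1):
            dh = dh + inject[:, t]
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H))
            r, z, n = rs[:, t], zs[:, t], ns[:, t]
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dn_pre = dn * (1.0 - n * n)
            dghn = dn_pre * r
            dr = dn_pre * ghn[:, t]
            dr_pre = dr * r * (1.0 - r)
            dz_pre = dz * z * (1.0 - z)
            dGx[:, t, :H] = dr_pre
            dGx[:, t, H:2 * H] = dz_pre
            dGx[:, t, 2 * H:] = dn_pre
            dGh = np.concatenate([dr_pre, dz_pre, dghn], axis=1)
            grads["Wh"] += h_prev.T @ dGh
            grads["bh"] += dGh.sum(axis=0)
            dh = dh_prev + dGh @ p.Wh.T
        flat_A = A.reshape(B * L, -1)
        flat_dGx = dGx.reshape(B * L, -1)
        grads["Wx"] += flat_A.T @ flat_dGx
        grads["bx"] += flat_dGx.sum(axis=0)
        return (dGx @ p.Wx.T)  # d wrt A, (B, L, C)

    # ------------------------------------------------------------ full net
    def forward(self, X: np.ndarray, lengths: np.ndarray,
                p: NetParams, want_cache: bool = False, masks=None):
        """*masks*, if given, are inverted-dropout masks (per-sequence,
        shared across timesteps): (B, 1, C) on the conv activations and
        (B, H) on h_L.  Used during training only."""
        act, conv_cache = self.conv_forward(X, p)
        if masks is not None:
            act = act * masks[0]
        hL, gru_cache = self.gru_forward(act, lengths, p)
        if masks is not None:
            hL = hL * masks[1]
        logits = hL @ p.Wo + p.bo
        probs = softmax(logits)
        if not want_cache:
            return probs
        return probs, {"conv": conv_cache, "gru": gru_cache, "hL": hL,
                       "masks": masks}

    def backward(self, d_logits: np.ndarray, cache: dict,
                 p: NetParams) -> dict[str, np.ndarray]:
        grads = {k: np.zeros_like(v) for k, v in p.as_dict().items()}
        masks = cache["masks"]
        grads["Wo"] += cache["hL"].T @ d_logits
        grads["bo"] += d_logits.sum(axis=0)
        d_hL = d_logits @ p.Wo.T
        if masks is not None:
            d_hL = d_hL * masks[1]
        d_act = self.gru_backward(d_hL, cache["gru"], p, grads)
        if masks is not None:
            d_act = d_act * masks[0]
        self.conv_backward(d_act, cache["conv"], p, grads)
        return grads

    def dropout_masks(self, B: int, rate: float,
                      rng: np.random.Generator):
        if rate <= 0.0:
            return None
        keep = 1.0 - rate
        mA = (rng.random((B, 1, self.C)) < keep) / keep
        mh = (rng.random((B, self.H)) < keep) / keep
        return mA, mh

    def loss_and_grads(self, X: np.ndarray, lengths: np.ndarray,
                       y: np.ndarray, weights: np.ndarray,
                       p: NetParams, masks=None) -> tuple[float, dict]:
        """Class-weighted cross-entropy (weighted mean) and its gradients."""
        probs, cache = self.forward(X, lengths, p, want_cache=True,
                                    masks=masks)
        B = len(y)
        wsum = weights.sum()
        eps = 1e-12
        loss = float(-(weights * np.log(probs[np.arange(B), y] + eps)).sum() / wsum)
        d_logits = probs.copy()
        d_logits[np.arange(B), y] -= 1.0
        d_logits *= (weights / wsum)[:, None]
        return loss, self.backward(d_logits, cache, p)


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> None:
    """Scale gradients in place so their global L2 norm is ≤ max_norm."""
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


class Adam:
    """Adam optimiser with decoupled weight decay over a NetParams instance."""

    def __init__(self, params: NetParams, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.as_dict().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.as_dict().items()}

    def step(self, params: NetParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            arr = getattr(params, k)
            arr[...] -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                   + self.wd * arr)
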