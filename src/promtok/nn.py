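"""A small bidirectional self-attention encoder in plain numpy.

Forward and backward passes are written out explicitly (no autograd), which
keeps the package dependency-light and makes training exactly reproducible:
given a seed, loss traces are bit-identical across runs on the same
platform.  The architecture is the standard pre-norm transformer encoder —
token + learned positional embeddings, multi-head self-attention with a key
padding mask, a 4x feed-forward block, and a final layer norm — with two
heads on top: a masked-token softmax over the vocabulary (pretraining) and
a single-logit classifier read from the first ([CLS]) position
(fine-tuning).

Sizes are desk-scale by default (2 layers, 64 hidden, 4 heads) but fully
configurable, so the same code scales up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EncoderConfig", "init_params", "TransformerEncoder", "Adam"]

_NEG = np.float32(-1e9)


@dataclass
class EncoderConfig:
    """Architecture knobs; ``hidden`` must divide evenly into ``heads``."""

    layers: int = 2
    hidden: int = 64
    heads: int = 4
    max_tokens: int = 640
    dropout: float = 0.0
    ffn_mult: int = 4

    def __post_init__(self) -> None:
        if self.hidden % self.heads:
            raise ValueError("hidden size must be divisible by heads")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def init_params(
    cfg: EncoderConfig, vocab_size: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    H, F = cfg.hidden, cfg.hidden * cfg.ffn_mult
    std = 0.02

    def w(*shape):
        return (rng.normal(0.0, std, shape)).astype(np.float32)

    p: dict[str, np.ndarray] = {
        "E": w(vocab_size, H),
        "P": w(cfg.max_tokens, H),
        "lnf.g": np.ones(H, np.float32),
        "lnf.b": np.zeros(H, np.float32),
        "mlm.W": w(H, vocab_size),
        "mlm.b": np.zeros(vocab_size, np.float32),
        "cls.W": w(H, 1),
        "cls.b": np.zeros(1, np.float32),
    }
    for i in range(cfg.layers):
        p[f"l{i}.ln1.g"] = np.ones(H, np.float32)
        p[f"l{i}.ln1.b"] = np.zeros(H, np.float32)
        p[f"l{i}.ln2.g"] = np.ones(H, np.float32)
        p[f"l{i}.ln2.b"] = np.zeros(H, np.float32)
        for nm in ("Wq", "Wk", "Wv", "Wo"):
            p[f"l{i}.{nm}"] = w(H, H)
        for nm in ("bq", "bk", "bv", "bo"):
            p[f"l{i}.{nm}"] = np.zeros(H, np.float32)
        p[f"l{i}.W1"] = w(H, F)
        p[f"l{i}.b1"] = np.zeros(F, np.float32)
        p[f"l{i}.W2"] = w(F, H)
        p[f"l{i}.b2"] = np.zeros(H, np.float32)
    return p


def _ln_forward(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _ln_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx.astype(dy.dtype), dg.astype(dy.dtype), db.astype(dy.dtype)


class TransformerEncoder:
    """Stateless compute graph over a parameter dict."""

    def __init__(self, cfg: EncoderConfig, vocab_size: int):
        self.cfg = cfg
        self.vocab_size = vocab_size

    # ---------------- forward ----------------

    def forward(
        self,
        params: dict[str, np.ndarray],
        ids: np.ndarray,
        pad_mask: np.ndarray,
        train: bool = False,
        drop_rng: np.random.Generator | None = None,
    ):
        """Encode ``ids`` [B, L] (``pad_mask`` True at real positions).

        Returns the final hidden states [B, L, H] and a cache for
        :meth:`backward`.
        """
        cfg = self.cfg
        B, L = ids.shape
        if L > cfg.max_tokens:
            raise ValueError(f"sequence of {L} tokens exceeds max_tokens")
        x = params["E"][ids] + params["P"][:L][None, :, :]
        keymask = (~pad_mask)[:, None, None, :]  # [B,1,1,L]
        cache: dict = {"ids": ids, "pad_mask": pad_mask, "layers": []}
        p_drop = cfg.dropout if train else 0.0
        for i in range(cfg.layers):
            x, lc = self._layer_forward(params, i, x, keymask, p_drop, drop_rng)
            cache["layers"].append(lc)
        out, lnf_c = _ln_forward(x, params["lnf.g"], params["lnf.b"])
        cache["lnf"] = lnf_c
        return out, cache

    def _layer_forward(self, params, i, x, keymask, p_drop, drop_rng):
        cfg = self.cfg
        B, L, H = x.shape
        nh, dh = cfg.heads, H // cfg.heads
        pre = f"l{i}."
        h, ln1_c = _ln_forward(x, params[pre + "ln1.g"], params[pre + "ln1.b"])
        q = h @ params[pre + "Wq"] + params[pre + "bq"]
        k = h @ params[pre + "Wk"] + params[pre + "bk"]
        v = h @ params[pre + "Wv"] + params[pre + "bv"]

        def split(t):  # [B,L,H] -> [B,nh,L,dh]
            return t.reshape(B, L, nh, dh).transpose(0, 2, 1, 3)

        qh, kh, vh = split(q), split(k), split(v)
        scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
        scores = np.where(keymask, _NEG, scores)
        scores -= scores.max(-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(-1, keepdims=True)
        ctx = attn @ vh  # [B,nh,L,dh]
        ctx_m = ctx.transpose(0, 2, 1, 3).reshape(B, L, H)
        a = ctx_m @ params[pre + "Wo"] + params[pre + "bo"]
        drop1 = None
        if p_drop > 0.0:
            drop1 = (drop_rng.random(a.shape) >= p_drop).astype(a.dtype) / (
                1.0 - p_drop
            )
            a = a * drop1
        x1 = x + a
        h2, ln2_c = _ln_forward(x1, params[pre + "ln2.g"], params[pre + "ln2.b"])
        z = h2 @ params[pre + "W1"] + params[pre + "b1"]
        r = np.maximum(z, 0.0)
        f = r @ params[pre + "W2"] + params[pre + "b2"]
        drop2 = None
        if p_drop > 0.0:
            drop2 = (drop_rng.random(f.shape) >= p_drop).astype(f.dtype) / (
                1.0 - p_drop
            )
            f = f * drop2
        x2 = x1 + f
        lc = (ln1_c, h, qh, kh, vh, attn, ctx_m, drop1, ln2_c, h2, z, r, drop2)
        return x2, lc

    # ---------------- backward ----------------

    def backward(self, params, cache, dout):
        """Gradient of a scalar loss wrt all parameters given d(final states)."""
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dx, dg, db = _ln_backward(dout, cache["lnf"])
        grads["lnf.g"] += dg
        grads["lnf.b"] += db
        for i in reversed(range(self.cfg.layers)):
            dx = self._layer_backward(params, grads, i, cache["layers"][i], dx)
        ids = cache["ids"]
        np.add.at(grads["E"], ids, dx)
        grads["P"][: ids.shape[1]] += dx.sum(0)
        return grads

    def _layer_backward(self, params, grads, i, lc, dx2):
        cfg = self.cfg
        (ln1_c, h, qh, kh, vh, attn, ctx_m, drop1, ln2_c, h2, z, r, drop2) = lc
        B, L, H = h.shape
        nh, dh = cfg.heads, H // cfg.heads
        pre = f"l{i}."
        # FFN branch
        df = dx2 if drop2 is None else dx2 * drop2
        grads[pre + "W2"] += r.reshape(-1, r.shape[-1]).T @ df.reshape(-1, H)
        grads[pre + "b2"] += df.sum((0, 1))
        dr = df @ params[pre + "W2"].T
        dz = dr * (z > 0)
        grads[pre + "W1"] += h2.reshape(-1, H).T @ dz.reshape(-1, dz.shape[-1])
        grads[pre + "b1"] += dz.sum((0, 1))
        dh2 = dz @ params[pre + "W1"].T
        dx1_ln, dg2, db2 = _ln_backward(dh2, ln2_c)
        grads[pre + "ln2.g"] += dg2
        grads[pre + "ln2.b"] += db2
        dx1 = dx2 + dx1_ln
        # attention branch
        da = dx1 if drop1 is None else dx1 * drop1
        grads[pre + "Wo"] += ctx_m.reshape(-1, H).T @ da.reshape(-1, H)
        grads[pre + "bo"] += da.sum((0, 1))
        dctx_m = da @ params[pre + "Wo"].T
        dctx = dctx_m.reshape(B, L, nh, dh).transpose(0, 2, 1, 3)
        dattn = dctx @ vh.transpose(0, 1, 3, 2)
        dvh = attn.transpose(0, 1, 3, 2) @ dctx
        dscores = (dattn - (dattn * attn).sum(-1, keepdims=True)) * attn
        dscores /= np.sqrt(dh)
        dqh = dscores @ kh
        dkh = dscores.transpose(0, 1, 3, 2) @ qh

        def merge(t):  # [B,nh,L,dh] -> [B,L,H]
            return t.transpose(0, 2, 1, 3).reshape(B, L, H)

        dq, dk, dv = merge(dqh), merge(dkh), merge(dvh)
        h_flat = h.reshape(-1, H)
        grads[pre + "Wq"] += h_flat.T @ dq.reshape(-1, H)
        grads[pre + "bq"] += dq.sum((0, 1))
        grads[pre + "Wk"] += h_flat.T @ dk.reshape(-1, H)
        grads[pre + "bk"] += dk.sum((0, 1))
        grads[pre + "Wv"] += h_flat.T @ dv.reshape(-1, H)
        grads[pre + "bv"] += dv.sum((0, 1))
        dh_ = (
            dq @ params[pre + "Wq"].T
            + dk @ params[pre + "Wk"].T
            + dv @ params[pre + "Wv"].T
        )
        dx_ln, dg1, db1 = _ln_backward(dh_, ln1_c)
        grads[pre + "ln1.g"] += dg1
        grads[pre + "ln1.b"] += db1
        return dx1 + dx_ln

    # ---------------- heads ----------------

    def mlm_loss(self, params, hidden, cache, target_pos, target_ids):
        """Masked-token cross-entropy, computed only at masked positions.

        ``target_pos`` is an array of (batch, position) index pairs;
        ``target_ids`` the true token ids there.  Returns (mean loss,
        d hidden) for the backward pass.
        """
        b_idx, p_idx = target_pos[:, 0], target_pos[:, 1]
        hsel = hidden[b_idx, p_idx]  # [M,H]
        logits = hsel @ params["mlm.W"] + params["mlm.b"]  # [M,V]
        logits -= logits.max(-1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(-1, keepdims=True)
        M = len(target_ids)
        loss = -np.log(probs[np.arange(M), target_ids] + 1e-12).mean()
        dlogits = probs
        dlogits[np.arange(M), target_ids] -= 1.0
        dlogits /= M
        grads_head = {
            "mlm.W": hsel.T @ dlogits,
            "mlm.b": dlogits.sum(0),
        }
        dhsel = dlogits @ params["mlm.W"].T
        dhidden = np.zeros_like(hidden)
        np.add.at(dhidden, (b_idx, p_idx), dhsel)
        return float(loss), dhidden.astype(hidden.dtype), grads_head

    def cls_forward(self, params, hidden):
        """Promoter probability from the [CLS] (first) position."""
        logit = hidden[:, 0] @ params["cls.W"] + params["cls.b"]  # [B,1]
        return 1.0 / (1.0 + np.exp(-logit[:, 0]))

    def cls_loss(self, params, hidden, labels):
        """Binary cross-entropy; returns (mean loss, d hidden, head grads)."""
        probs = self.cls_forward(params, hidden)
        y = labels.astype(np.float64)
        loss = -(y * np.log(probs + 1e-12) + (1 - y) * np.log(1 - probs + 1e-12)).mean()
        dlogit = ((probs - y) / len(y)).astype(hidden.dtype)  # [B]
        grads_head = {
            "cls.W": hidden[:, 0].T @ dlogit[:, None],
            "cls.b": dlogit.sum(keepdims=True),
        }
        dhidden = np.zeros_like(hidden)
        dhidden[:, 0] = dlogit[:, None] * params["cls.W"][None, :, 0]
        return float(loss), dhidden, grads_head


class Adam:
    """Adaptive-moment gradient descent over a parameter dict."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )
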