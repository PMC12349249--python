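"""Few-shot similarity networks over [240, 8] sensor-array samples.

Three metric-learning heads share one convolutional embedding:

* **SE-RelationNet** — the main model.  The embedding is a stem convolution
  followed by residual blocks (pathway F1: three convolutions plus a
  squeeze-and-excitation block; pathway F2: a single convolution; output
  ``y = F1(x) + F2(x)``) and a temporal-reduction stage, mapping a
  ``[240, 8]`` sample to a ``[63, 30]`` feature map.  The relation head
  concatenates a class feature map with a query feature map along the
  channel axis, passes the pair through a convolution, an SE block, a
  bidirectional GRU, dropout, and a fully connected layer, and squashes the
  result through a sigmoid into a relation score in (0, 1).
* **SiameseFewShot** — flattened embeddings; the elementwise absolute
  difference between a class-mean vector and a query vector feeds two fully
  connected layers and a sigmoid.
* **ProtoFewShot** — flattened embeddings; class prototypes are support
  means, and query class probabilities are a softmax over negative squared
  Euclidean distances.

All parameters live in the package's own autodiff engine; forward passes in
eval mode are deterministic.
"""

from __future__ import annotations

import io
import json
import math
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import (Module, Parameter, Tensor, avg_pool1d, concat, conv1d,
                       leaky_relu, log_softmax, matmul, mean_, relu, reshape,
                       sigmoid, stack, sub, tanh)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbeddingConfig:
    """Architecture of the embedding module."""

    in_channels: int = 8
    in_timesteps: int = 240
    n_residual_blocks: int = 3
    f1_convs_per_block: int = 3
    se_ratio: int = 16
    leaky_slope: float = 0.01
    feature_channels: int = 30
    out_timesteps: int = 63
    temporal_pool: int = 3
    batch_norm: bool = True
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.se_ratio < 1:
            raise ValueError("se_ratio must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if not (0 < self.leaky_slope < 1):
            raise ValueError("leaky_slope must lie in (0, 1)")


@dataclass(frozen=True)
class HeadConfig:
    """Architecture of the relation (metrics) head."""

    conv_channels: int = 30
    se_ratio: int = 16
    hidden_size: int = 32
    recurrent: str = "bigru"   # bigru | gru | bilstm | lstm | birnn | rnn
    num_layers: int = 1
    dropout: float = 0.3
    leaky_slope: float = 0.01
    batch_norm: bool = True


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0):
        scale = math.sqrt(2.0 / (cin * kernel))
        self.weight = Parameter(rng.normal(0.0, scale, size=(cout, cin, kernel)))
        self.bias = Parameter(np.zeros(cout))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        out = conv1d(x, self.weight, stride=self.stride, padding=self.padding)
        return out + reshape(self.bias, (1, -1, 1))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = math.sqrt(6.0 / (n_in + n_out))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class BatchNorm1d(Module):
    """Per-channel normalization for [B, C, L] maps; batch statistics in
    training mode, running averages in eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = mean_(x, axis=(0, 2), keepdims=True)
            centered = sub(x, mu)
            var = mean_(centered * centered, axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = centered / ad.sqrt(var + self.eps)
        else:
            mu = self.running_mean.reshape(1, -1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1)
            xhat = (x - mu) / sd
        return xhat * reshape(self.gamma, (1, -1, 1)) + reshape(self.beta, (1, -1, 1))


class SEBlock(Module):
    """Squeeze-and-excitation channel attention for [B, C, L] maps.

    Squeeze: per-channel mean over time.  Excite: a bottleneck of two fully
    connected layers (width C/ratio with ReLU, back to C with sigmoid).
    Scale: channel-wise multiplication by the resulting (0, 1) weights.
    """

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator):
        hidden = max(1, math.ceil(channels / ratio))
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def weights(self, x: Tensor) -> Tensor:
        z = mean_(x, axis=2)                       # squeeze: [B, C]
        return sigmoid(self.fc2(relu(self.fc1(z))))

    def __call__(self, x: Tensor) -> Tensor:
        s = self.weights(x)
        return x * reshape(s, (*s.shape, 1))       # scale


def dropout(x: Tensor, p: float, train: bool,
            rng: np.random.Generator | None) -> Tensor:
    if not train or p <= 0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class ResidualBlock(Module):
    """y = F1(x) + F2(x) with a long feature pathway and a short skip.

    F1: ``f1_convs`` convolutions (kernel 3, same padding, optional batch
    norm, leaky-ReLU) followed by an SE block.  F2: one kernel-1 convolution.
    Shape-preserving.
    """

    def __init__(self, channels: int, f1_convs: int, se_ratio: int,
                 leaky_slope: float, batch_norm: bool, rng: np.random.Generator):
        self.convs = [Conv1d(channels, channels, 3, rng, padding=1)
                      for _ in range(f1_convs)]
        self.norms = [BatchNorm1d(channels) for _ in range(f1_convs)] if batch_norm else []
        self.se = SEBlock(channels, se_ratio, rng)
        self.skip = Conv1d(channels, channels, 1, rng)
        self.slope = leaky_slope

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        h = x
        for i, conv in enumerate(self.convs):
            h = conv(h)
            if self.norms:
                h = self.norms[i](h, train)
            h = leaky_relu(h, self.slope)
        return self.se(h) + self.skip(x)


# ---------------------------------------------------------------------------
# recurrent cells
# ---------------------------------------------------------------------------


class GRUCell(Module):
    """Gated recurrent unit: reset gate r_t and update gate z_t (sigmoid),
    candidate state h'_t (tanh of input plus reset-filtered history), and
    blend h_t = z_t * h_{t-1} + (1 - z_t) * h'_t."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        b = 1.0 / math.sqrt(hidden)
        u = lambda *s: Parameter(rng.uniform(-b, b, size=s))
        self.Wr, self.Ur, self.br = u(n_in, hidden), u(hidden, hidden), u(hidden)
        self.Wz, self.Uz, self.bz = u(n_in, hidden), u(hidden, hidden), u(hidden)
        self.Wh, self.Uh, self.bh = u(n_in, hidden), u(hidden, hidden), u(hidden)
        self.hidden = hidden

    def initial(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.hidden)))

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        r = sigmoid(matmul(x_t, self.Wr) + matmul(h, self.Ur) + self.br)
        z = sigmoid(matmul(x_t, self.Wz) + matmul(h, self.Uz) + self.bz)
        h_cand = tanh(matmul(x_t, self.Wh) + matmul(r * h, self.Uh) + self.bh)
        return z * h + (1.0 - z) * h_cand

    output = staticmethod(lambda state: state)


class RNNCell(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        b = 1.0 / math.sqrt(hidden)
        self.W = Parameter(rng.uniform(-b, b, size=(n_in, hidden)))
        self.U = Parameter(rng.uniform(-b, b, size=(hidden, hidden)))
        self.b = Parameter(rng.uniform(-b, b, size=hidden))
        self.hidden = hidden

    def initial(self, batch: int) -> Tensor:
        return Tensor(np.zeros((batch, self.hidden)))

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        return tanh(matmul(x_t, self.W) + matmul(h, self.U) + self.b)

    output = staticmethod(lambda state: state)


class LSTMCell(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        b = 1.0 / math.sqrt(hidden)
        u = lambda *s: Parameter(rng.uniform(-b, b, size=s))
        self.Wi, self.Ui, self.bi = u(n_in, hidden), u(hidden, hidden), u(hidden)
        self.Wf, self.Uf, self.bf = u(n_in, hidden), u(hidden, hidden), u(hidden)
        self.Wo, self.Uo, self.bo = u(n_in, hidden), u(hidden, hidden), u(hidden)
        self.Wg, self.Ug, self.bg = u(n_in, hidden), u(hidden, hidden), u(hidden)
        self.hidden = hidden

    def initial(self, batch: int):
        z = Tensor(np.zeros((batch, self.hidden)))
        return (z, Tensor(np.zeros((batch, self.hidden))))

    def step(self, x_t: Tensor, state):
        h, c = state
        i = sigmoid(matmul(x_t, self.Wi) + matmul(h, self.Ui) + self.bi)
        f = sigmoid(matmul(x_t, self.Wf) + matmul(h, self.Uf) + self.bf)
        o = sigmoid(matmul(x_t, self.Wo) + matmul(h, self.Uo) + self.bo)
        g = tanh(matmul(x_t, self.Wg) + matmul(h, self.Ug) + self.bg)
        c = f * c + i * g
        return (o * tanh(c), c)

    output = staticmethod(lambda state: state[0])


_CELLS = {"gru": GRUCell, "rnn": RNNCell, "lstm": LSTMCell}


def gru_direction(x: Tensor, cell: GRUCell, h0: np.ndarray | None = None,
                  reverse: bool = False) -> Tensor:
    """One GRU scan over a [B, T, C] sequence; returns outputs [B, T, H].

    This is a fused tape primitive: the forward recursion and its
    backpropagation-through-time are written out explicitly against the
    gate equations, which keeps long sequences cheap.  Numerically it is
    the same recursion as looping :meth:`GRUCell.step` (a property the
    test-suite checks directly).
    """
    xd = x.data
    B, T, C = xd.shape
    H = cell.hidden
    params = (cell.Wr, cell.Ur, cell.br, cell.Wz, cell.Uz, cell.bz,
              cell.Wh, cell.Uh, cell.bh)
    Wr, Ur, br, Wz, Uz, bz, Wh, Uh, bh = (p.data for p in params)
    order = list(range(T - 1, -1, -1) if reverse else range(T))
    from scipy.special import expit

    if isinstance(h0, Tensor):
        h0 = h0.data
    h = np.zeros((B, H), dtype=xd.dtype) if h0 is None \
        else np.broadcast_to(np.asarray(h0, dtype=xd.dtype), (B, H)).copy()
    xflat = xd.reshape(B * T, C)
    pr = (xflat @ Wr + br).reshape(B, T, H)
    pz = (xflat @ Wz + bz).reshape(B, T, H)
    ph = (xflat @ Wh + bh).reshape(B, T, H)
    outputs = np.empty((B, T, H), dtype=xd.dtype)
    h_prev = np.empty((T, B, H), dtype=xd.dtype)
    rs = np.empty_like(h_prev)
    zs = np.empty_like(h_prev)
    hcs = np.empty_like(h_prev)
    for t in order:
        h_prev[t] = h
        r = expit(pr[:, t] + h @ Ur)
        z = expit(pz[:, t] + h @ Uz)
        hc = np.tanh(ph[:, t] + (r * h) @ Uh)
        h = z * h + (1.0 - z) * hc
        rs[t], zs[t], hcs[t] = r, z, hc
        outputs[:, t] = h

    cache: dict = {}

    def grads_for(g: np.ndarray) -> dict:
        if cache.get("key") != id(g):
            dW = {name: np.zeros_like(arr) for name, arr in
                  zip("Wr Ur br Wz Uz bz Wh Uh bh".split(),
                      (Wr, Ur, br, Wz, Uz, bz, Wh, Uh, bh))}
            dx = np.empty_like(xd)
            dh = np.zeros((B, H), dtype=np.result_type(g.dtype, xd.dtype))
            for t in reversed(order):
                dh = dh + g[:, t]
                hp, r, z, hc = h_prev[t], rs[t], zs[t], hcs[t]
                dz = dh * (hp - hc)
                daz = dz * z * (1.0 - z)
                dhc = dh * (1.0 - z)
                dah = dhc * (1.0 - hc ** 2)
                dah_Uh = dah @ Uh.T
                dar = dah_Uh * hp * r * (1.0 - r)
                dh = dh * z + dah_Uh * r + daz @ Uz.T + dar @ Ur.T
                x_t = xd[:, t]
                dx[:, t] = dar @ Wr.T + daz @ Wz.T + dah @ Wh.T
                dW["Wr"] += x_t.T @ dar
                dW["Ur"] += hp.T @ dar
                dW["br"] += dar.sum(axis=0)
                dW["Wz"] += x_t.T @ daz
                dW["Uz"] += hp.T @ daz
                dW["bz"] += daz.sum(axis=0)
                dW["Wh"] += x_t.T @ dah
                dW["Uh"] += (r * hp).T @ dah
                dW["bh"] += dah.sum(axis=0)
            cache["key"] = id(g)
            cache["vals"] = {"x": dx, **dW}
        return cache["vals"]

    names = ["x", "Wr", "Ur", "br", "Wz", "Uz", "bz", "Wh", "Uh", "bh"]

    def make_vjp(name):
        return lambda g: grads_for(g)[name]

    return Tensor(outputs, _parents=(x, *params),
                  _vjps=tuple(make_vjp(n) for n in names))


class Recurrent(Module):
    """(Bi)directional recurrent layer stack over [B, T, C] sequences."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator,
                 kind: str = "bigru", num_layers: int = 1):
        self.bidirectional = kind.startswith("bi")
        cell_kind = kind[2:] if self.bidirectional else kind
        if cell_kind not in _CELLS:
            raise ValueError(f"unknown recurrent kind {kind!r}")
        dirs = 2 if self.bidirectional else 1
        self.layers = []
        for layer in range(num_layers):
            size = n_in if layer == 0 else hidden * dirs
            cells = [_CELLS[cell_kind](size, hidden, rng) for _ in range(dirs)]
            self.layers.append(cells)
        self.hidden = hidden

    def _run(self, cell, xs: list[Tensor], state=None) -> list[Tensor]:
        state = cell.initial(xs[0].shape[0]) if state is None else state
        outs = []
        for x_t in xs:
            state = cell.step(x_t, state)
            outs.append(cell.output(state))
        return outs

    def __call__(self, x: Tensor, initial=None) -> tuple[Tensor, Tensor]:
        """Returns (outputs [B, T, H*dirs], final [B, H*dirs]).

        The final state concatenates the forward pass's last hidden state
        with the backward pass's (which summarizes the sequence from its
        end back to its start).  GRU cells take the fused scan; other cell
        kinds run the generic per-step loop.
        """
        T = x.shape[1]
        seq: Tensor = x
        for cells in self.layers:
            if isinstance(cells[0], GRUCell):
                fwd_seq = gru_direction(seq, cells[0], h0=initial)
                if self.bidirectional:
                    bwd_seq = gru_direction(seq, cells[1], h0=initial, reverse=True)
                    final = concat([fwd_seq[:, -1, :], bwd_seq[:, 0, :]], axis=1)
                    seq = concat([fwd_seq, bwd_seq], axis=2)
                else:
                    final = fwd_seq[:, -1, :]
                    seq = fwd_seq
                continue
            xs = [seq[:, t, :] for t in range(T)]
            fwd = self._run(cells[0], xs, initial)
            if self.bidirectional:
                bwd = list(reversed(self._run(cells[1], list(reversed(xs)), initial)))
                steps = [concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
                final = concat([fwd[-1], bwd[0]], axis=1)
            else:
                steps = fwd
                final = fwd[-1]
            seq = stack(steps, axis=1)
        return seq, final


def bigru_layer(x, cell_fwd: GRUCell, cell_bwd: GRUCell | None = None,
                h0: np.ndarray | None = None) -> np.ndarray:
    """Run one bidirectional GRU layer and return its output sequence
    [B, T, H] (forward only) or [B, T, 2H] as a plain array.

    Exposed for direct inspection of the gate recursions; ``h0`` seeds the
    initial hidden state of both directions.
    """
    x = ad.astensor(x)
    T = x.shape[1]
    xs = [x[:, t, :] for t in range(T)]
    init = None if h0 is None else Tensor(h0)

    def run(cell, seq):
        state = cell.initial(seq[0].shape[0]) if init is None else init
        outs = []
        for x_t in seq:
            state = cell.step(x_t, state)
            outs.append(state)
        return outs

    fwd = run(cell_fwd, xs)
    if cell_bwd is None:
        return stack(fwd, axis=1).data
    bwd = list(reversed(run(cell_bwd, list(reversed(xs)))))
    return stack([concat([f, b], axis=1) for f, b in zip(fwd, bwd)], axis=1).data


# ---------------------------------------------------------------------------
# embedding module
# ---------------------------------------------------------------------------


class EmbeddingNet(Module):
    """Stem convolution -> temporal pooling -> residual blocks ->
    un-padded reduction convolution.

    The residual blocks preserve shape, so any block count yields the same
    output contract: [feature_channels, out_timesteps] per sample
    (default [30, 63] from a [8, 240] input; pooling by 3 gives 80 steps,
    and the kernel-18 reduction convolution lands exactly on 63).
    """

    def __init__(self, cfg: EmbeddingConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.stem = Conv1d(cfg.in_channels, cfg.feature_channels, 3, rng, padding=1)
        self.blocks = [
            ResidualBlock(cfg.feature_channels, cfg.f1_convs_per_block,
                          cfg.se_ratio, cfg.leaky_slope, cfg.batch_norm, rng)
            for _ in range(cfg.n_residual_blocks)
        ]
        pooled = (cfg.in_timesteps - cfg.temporal_pool) // cfg.temporal_pool + 1
        kernel = pooled - cfg.out_timesteps + 1
        if kernel < 1:
            raise ValueError(
                f"out_timesteps {cfg.out_timesteps} unreachable from "
                f"{cfg.in_timesteps} input steps with pool {cfg.temporal_pool}")
        self.reduce = Conv1d(cfg.feature_channels, cfg.feature_channels, kernel, rng)
        out = self(Tensor(np.zeros((1, cfg.in_channels, cfg.in_timesteps))), train=False)
        if out.shape != (1, cfg.feature_channels, cfg.out_timesteps):
            raise AssertionError(f"embedding shape contract violated: {out.shape}")

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        """[B, in_channels, in_timesteps] -> [B, feature_channels, out_timesteps]"""
        h = avg_pool1d(leaky_relu(self.stem(x), self.cfg.leaky_slope),
                       self.cfg.temporal_pool)
        for block in self.blocks:
            h = block(h, train)
        return leaky_relu(self.reduce(h), self.cfg.leaky_slope)


def class_feature(support_embeddings: Tensor, axis: int = 0) -> Tensor:
    """Elementwise mean of K support feature maps; identity for K = 1."""
    return mean_(support_embeddings, axis=axis)


def merge_features(f_class: Tensor, f_query: Tensor, axis: int = 1) -> Tensor:
    """Concatenate class features with query features along the channel
    axis, class features first."""
    if f_class.shape != f_query.shape:
        raise ValueError(f"shape mismatch: {f_class.shape} vs {f_query.shape}")
    return concat([f_class, f_query], axis=axis)


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------


class RelationHead(Module):
    """Convolution -> SE block -> BiGRU -> dropout -> FC -> sigmoid."""

    def __init__(self, in_channels: int, cfg: HeadConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.conv = Conv1d(in_channels, cfg.conv_channels, 3, rng, padding=1)
        self.norm = BatchNorm1d(cfg.conv_channels) if cfg.batch_norm else None
        self.se = SEBlock(cfg.conv_channels, cfg.se_ratio, rng)
        self.rnn = Recurrent(cfg.conv_channels, cfg.hidden_size, rng,
                             kind=cfg.recurrent, num_layers=cfg.num_layers)
        dirs = 2 if self.rnn.bidirectional else 1
        self.fc = Linear(cfg.hidden_size * dirs, 1, rng)

    def __call__(self, merged: Tensor, train: bool,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = self.conv(merged)
        if self.norm is not None:
            h = self.norm(h, train)
        h = leaky_relu(h, self.cfg.leaky_slope)
        h = self.se(h)
        _, final = self.rnn(h.transpose(0, 2, 1))
        final = dropout(final, self.cfg.dropout, train, rng)
        return sigmoid(self.fc(final))


class SERelationNet(Module):
    """Embedding + relation-scoring head."""

    kind = "relation"

    def __init__(self, emb_cfg: EmbeddingConfig | None = None,
                 head_cfg: HeadConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.emb_cfg = emb_cfg or EmbeddingConfig()
        self.head_cfg = head_cfg or HeadConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.embedding = EmbeddingNet(self.emb_cfg, rng)
        self.head = RelationHead(2 * self.emb_cfg.feature_channels, self.head_cfg, rng)

    def _embed_episode(self, support_x: np.ndarray, query_x: np.ndarray,
                       train: bool) -> tuple[Tensor, Tensor, int, int]:
        N, K = support_x.shape[:2]
        Q = query_x.shape[0]
        xs = support_x.reshape(N * K, *support_x.shape[2:]).transpose(0, 2, 1)
        xq = query_x.transpose(0, 2, 1)
        emb = self.embedding(Tensor(np.concatenate([xs, xq])), train)
        emb_support = emb[:N * K]
        emb_query = emb[N * K:]
        class_feats = class_feature(
            reshape(emb_support, (N, K, *emb_support.shape[1:])), axis=1)
        return class_feats, emb_query, N, Q

    def episode_scores(self, support_x: np.ndarray, query_x: np.ndarray,
                       train: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        """Relation scores [n_way, n_query] in (0, 1).

        ``support_x``: [N, K, T, C]; ``query_x``: [Q, T, C].  For K > 1 the
        class feature map is the elementwise mean of the K support
        embeddings, so identical supports collapse to the K = 1 scores.
        """
        class_feats, emb_query, N, Q = self._embed_episode(support_x, query_x, train)
        F, T = class_feats.shape[1], class_feats.shape[2]
        cf = ad.broadcast_to(reshape(class_feats, (N, 1, F, T)), (N, Q, F, T))
        qf = ad.broadcast_to(reshape(emb_query, (1, Q, F, T)), (N, Q, F, T))
        merged = reshape(concat([cf, qf], axis=2), (N * Q, 2 * F, T))
        scores = self.head(merged, train, rng)
        return reshape(scores, (N, Q))

    def predict(self, support_x: np.ndarray, query_x: np.ndarray) -> np.ndarray:
        """Class index per query (argmax score; ties -> lowest index)."""
        return np.argmax(self.episode_scores(support_x, query_x).data, axis=0)


class SiameseFewShot(Module):
    """Absolute difference of flattened embeddings -> two FC layers -> sigmoid."""

    kind = "siamese"

    def __init__(self, emb_cfg: EmbeddingConfig | None = None,
                 head_cfg: HeadConfig | None = None,
                 rng: np.random.Generator | None = None,
                 fc_hidden: int = 64):
        self.emb_cfg = emb_cfg or EmbeddingConfig()
        self.head_cfg = head_cfg or HeadConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.embedding = EmbeddingNet(self.emb_cfg, rng)
        dim = self.emb_cfg.feature_channels * self.emb_cfg.out_timesteps
        self.fc1 = Linear(dim, fc_hidden, rng)
        self.fc2 = Linear(fc_hidden, 1, rng)

    def _flat_embed(self, support_x, query_x, train):
        N, K = support_x.shape[:2]
        Q = query_x.shape[0]
        xs = support_x.reshape(N * K, *support_x.shape[2:]).transpose(0, 2, 1)
        xq = query_x.transpose(0, 2, 1)
        emb = self.embedding(Tensor(np.concatenate([xs, xq])), train)
        flat = reshape(emb, (emb.shape[0], -1))
        sup = mean_(reshape(flat[:N * K], (N, K, -1)), axis=1)   # class means [N, D]
        return sup, flat[N * K:], N, Q

    def episode_scores(self, support_x: np.ndarray, query_x: np.ndarray,
                       train: bool = False,
                       rng: np.random.Generator | None = None) -> Tensor:
        sup, qry, N, Q = self._flat_embed(support_x, query_x, train)
        D = sup.shape[1]
        diff = ad.absolute(sub(ad.broadcast_to(reshape(sup, (N, 1, D)), (N, Q, D)),
                               ad.broadcast_to(reshape(qry, (1, Q, D)), (N, Q, D))))
        h = relu(self.fc1(reshape(diff, (N * Q, D))))
        h = dropout(h, self.head_cfg.dropout, train, rng)
        return reshape(sigmoid(self.fc2(h)), (N, Q))

    def predict(self, support_x: np.ndarray, query_x: np.ndarray) -> np.ndarray:
        return np.argmax(self.episode_scores(support_x, query_x).data, axis=0)


class ProtoFewShot(Module):
    """Prototype = class-mean flattened embedding; P(class | query) is a
    softmax over negative squared Euclidean distances."""

    kind = "proto"

    def __init__(self, emb_cfg: EmbeddingConfig | None = None,
                 head_cfg: HeadConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.emb_cfg = emb_cfg or EmbeddingConfig()
        self.head_cfg = head_cfg or HeadConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.embedding = EmbeddingNet(self.emb_cfg, rng)

    def episode_log_probs(self, support_x: np.ndarray, query_x: np.ndarray,
                          train: bool = False,
                          rng: np.random.Generator | None = None) -> Tensor:
        """Log class probabilities [n_query, n_way]."""
        N, K = support_x.shape[:2]
        xs = support_x.reshape(N * K, *support_x.shape[2:]).transpose(0, 2, 1)
        xq = query_x.transpose(0, 2, 1)
        emb = self.embedding(Tensor(np.concatenate([xs, xq])), train)
        flat = reshape(emb, (emb.shape[0], -1))
        protos = mean_(reshape(flat[:N * K], (N, K, -1)), axis=1)     # [N, D]
        qry = flat[N * K:]                                            # [Q, D]
        q2 = ad.sum_(qry * qry, axis=1, keepdims=True)                # [Q, 1]
        p2 = reshape(ad.sum_(protos * protos, axis=1), (1, N))        # [1, N]
        d2 = q2 + p2 - 2.0 * matmul(qry, protos.transpose(1, 0))
        return log_softmax(-d2, axis=1)

    def episode_scores(self, support_x, query_x, train: bool = False,
                       rng=None) -> Tensor:
        """Probabilities transposed to [n_way, n_query] for a uniform API."""
        return ad.exp(self.episode_log_probs(support_x, query_x, train, rng)).transpose(1, 0)

    def predict(self, support_x: np.ndarray, query_x: np.ndarray) -> np.ndarray:
        return np.argmax(self.episode_log_probs(support_x, query_x).data, axis=1)


def proto_probabilities(prototypes: np.ndarray, query_embedding: np.ndarray) -> np.ndarray:
    """softmax(-d^2) over squared Euclidean distances of one query vector to
    each prototype; sums to 1."""
    prototypes = np.asarray(prototypes, float)
    d2 = ((prototypes - np.asarray(query_embedding, float)[None, :]) ** 2).sum(axis=1)
    z = -d2 - (-d2).max()
    e = np.exp(z)
    return e / e.sum()


MODEL_KINDS = {"relation": SERelationNet, "siamese": SiameseFewShot,
               "proto": ProtoFewShot}


def build_model(kind: str, emb_cfg: EmbeddingConfig | None = None,
                head_cfg: HeadConfig | None = None,
                rng: np.random.Generator | None = None):
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {sorted(MODEL_KINDS)}")
    return MODEL_KINDS[kind](emb_cfg, head_cfg, rng)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model, path: str | Path) -> None:
    """Single archive: JSON config + named parameter arrays + batch-norm
    running statistics."""
    meta = {"kind": model.kind,
            "embedding": asdict(model.emb_cfg),
            "head": asdict(model.head_cfg)}
    arrays = {f"param/{name}": p.data for name, p in model.named_parameters()}
    for name, bn in _named_batchnorms(model):
        arrays[f"bn_mean/{name}"] = bn.running_mean
        arrays[f"bn_var/{name}"] = bn.running_var
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(meta, indent=2))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name + ".npy", buf.getvalue())


def _named_batchnorms(module: Module, prefix: str = ""):
    def walk(value, path):
        if isinstance(value, BatchNorm1d):
            yield path, value
        elif isinstance(value, Module):
            yield from _named_batchnorms(value, path + ".")
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from walk(item, f"{path}.{i}")

    for name, value in vars(module).items():
        yield from walk(value, f"{prefix}{name}")


def load_checkpoint(path: str | Path):
    """Rebuild a model from an archive and validate its shape contract."""
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("config.json"))
        arrays = {}
        for info in zf.namelist():
            if info.endswith(".npy"):
                arrays[info[:-4]] = np.load(io.BytesIO(zf.read(info)))
    model = build_model(meta["kind"], EmbeddingConfig(**meta["embedding"]),
                        HeadConfig(**meta["head"]), np.random.default_rng(0))
    for name, p in model.named_parameters():
        stored = arrays[f"param/{name}"]
        if stored.shape != p.data.shape:
            raise ValueError(f"checkpoint shape mismatch at {name}: "
                             f"{stored.shape} vs {p.data.shape}")
        p.data = stored
    for name, bn in _named_batchnorms(model):
        bn.running_mean = arrays[f"bn_mean/{name}"]
        bn.running_var = arrays[f"bn_var/{name}"]
    cfg = model.emb_cfg
    out = model.embedding(Tensor(np.zeros((1, cfg.in_channels, cfg.in_timesteps))),
                          train=False)
    if out.shape != (1, cfg.feature_channels, cfg.out_timesteps):
        raise ValueError("loaded embedding violates its shape contract")
    return model
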