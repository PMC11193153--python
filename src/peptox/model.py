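"""The fused sequence/structure toxicity network.

Architecture, in the order a sample flows through it:

1. a bidirectional GRU maps the padded embedding matrix X (L_max x d_input)
   to per-residue sequence features h_seq (L_max x d_h);
2. a GVP-based message-passing network over the residue graph produces
   per-residue structural features; node state i is updated as
   m_i = LayerNorm(h_i + mean_j f(h_j || h_ij)) followed by
   h_i <- LayerNorm(h_i + g(m_i)), with f a stack of two and g a stack of
   three geometric vector perceptrons; a final scalar-only GVP reads the
   state out to h_strct (L x d_h), which is rotation/translation invariant;
3. channel dropout (p = 0.5) is applied to each modality independently
   during training, the two are concatenated to h_pep (L x 2 d_h), and an
   8-head self-attention layer refines them to h'_pep, with padded
   positions masked out of the softmax;
4. h'_pep is mean-pooled over the true length, the binary C-terminal
   amidation flag is appended, and a fully connected layer with softmax
   yields the toxicity probability (label "toxic" iff p > 0.5 strictly);
   a parallel linear head maps h'_pep to per-residue 8-class secondary
   structure scores;
5. the loss is (1 - lambda) * BCE(p, y) + lambda * CE(ss), the secondary
   structure term acting as a structural auxiliary task.

Everything runs on the NumPy autodiff engine in :mod:`peptox.autodiff`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import AA_ALPHABET
from .errors import ShapeMismatch
from .graphs import ResidueGraph

__all__ = [
    "ModelConfig",
    "ToxicityModel",
    "FusedFeatures",
    "compute_loss",
]

EPS_PROB = 1e-7


@dataclass
class ModelConfig:
    """Dimensions and switches of the network.

    ``d_h`` is the shared hidden width of both branches; the fused width is
    2 d_h, split over ``n_heads`` attention heads.  ``lambda_ss`` mixes the
    secondary-structure auxiliary loss into the objective.  ``d_max`` is
    the contact threshold the graphs were built with (stored here so
    checkpoints are self-describing).  ``attn_scale`` toggles 1/sqrt(d)
    scaling of attention logits; ``paper_pooling`` divides the pooled sum
    by L_max instead of the true length.
    """

    d_input: int = 64
    d_h: int = 64
    n_gnn_layers: int = 1
    n_gru_layers: int = 1
    n_heads: int = 8
    n_vector_channels: int = 16
    lambda_ss: float = 0.2
    d_max: float = 12.0
    L_max: int = 50
    dropout_p: float = 0.5
    attn_scale: bool = True
    paper_pooling: bool = False
    n_edge_scalars: int = 32
    n_ss_classes: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lambda_ss <= 1.0:
            raise ValueError("lambda_ss must lie in [0, 1]")
        if self.d_fused % self.n_heads:
            raise ShapeMismatch("fused width must be divisible by n_heads")

    @property
    def d_fused(self):
        return 2 * self.d_h

    @property
    def d_head(self):
        return self.d_fused // self.n_heads

    @classmethod
    def peptide(cls, **kw):
        """Preset for short peptides: d_h=64, one GNN and one GRU layer."""
        return cls(d_h=64, n_gnn_layers=1, n_gru_layers=1, **kw)

    @classmethod
    def protein(cls, L_max, **kw):
        """Preset for longer proteins: d_h=128, three GNN layers."""
        return cls(d_h=128, n_gnn_layers=3, n_gru_layers=1, L_max=L_max, **kw)


@dataclass
class FusedFeatures:
    """Intermediate activations of one forward pass (padded batch form)."""

    h_seq: Tensor        # (B, L_max, d_h)
    h_strct: Tensor      # (B, L_max, d_h)
    h_pep: Tensor        # (B, L_max, 2 d_h)
    h_prime: Tensor      # (B, L_max, 2 d_h)
    attention: np.ndarray  # (B, n_heads, L_max, L_max)
    lengths: np.ndarray
    mask: np.ndarray     # (B, L_max) 1.0 on real residues


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[-1]))
    return rng.uniform(-limit, limit, size=shape)


class ToxicityModel:
    """Weights plus forward passes; training lives in :mod:`peptox.train`."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        self._build()

    # -- parameter construction ---------------------------------------------
    def _param(self, name, shape, init="glorot"):
        rng = self._rng
        if init == "glorot":
            data = _glorot(rng, shape)
        elif init == "zeros":
            data = np.zeros(shape)
        elif init == "ones":
            data = np.ones(shape)
        self.params[name] = Tensor(data, requires_grad=True)

    def _build_gvp(self, prefix, in_s, in_v, out_s, out_v, hidden_v=None):
        hv = hidden_v if hidden_v is not None else max(in_v, out_v, 1)
        self._param(f"{prefix}.Wh", (in_v, hv))
        self._param(f"{prefix}.Ws", (in_s + hv, out_s))
        self._param(f"{prefix}.bs", (out_s,), init="zeros")
        if out_v:
            self._param(f"{prefix}.Wv", (hv, out_v))
            self._param(f"{prefix}.Wg", (out_s, out_v))
            self._param(f"{prefix}.bg", (out_v,), init="zeros")

    def _build_ln(self, prefix, dim):
        self._param(f"{prefix}.gamma", (dim,), init="ones")
        self._param(f"{prefix}.beta", (dim,), init="zeros")

    def _build(self):
        c = self.config
        dh, nv = c.d_h, c.n_vector_channels
        # GNN branch
        self._build_gvp("gnn.embed", 6, 3, dh, nv)
        for l in range(c.n_gnn_layers):
            p = f"gnn.l{l}"
            self._build_gvp(f"{p}.msg0", dh + c.n_edge_scalars, nv + 1, dh, nv)
            self._build_gvp(f"{p}.msg1", dh, nv, dh, nv)
            for k in range(3):
                self._build_gvp(f"{p}.upd{k}", dh, nv, dh, nv)
            self._build_ln(f"{p}.ln_msg", dh)
            self._build_ln(f"{p}.ln_upd", dh)
        self._build_gvp("gnn.readout", dh, nv, dh, 0)
        self._build_ln("gnn.ln", dh)
        # GRU branch (d_h/2 per direction)
        d2 = c.d_h // 2
        for l in range(c.n_gru_layers):
            d_in = c.d_input if l == 0 else c.d_h
            for direction in ("fw", "bw"):
                # gates fused in [z | r | n] order for one matmul per step
                p = f"gru.l{l}.{direction}"
                self._param(f"{p}.W", (d_in, 3 * d2))
                self._param(f"{p}.U", (d2, 3 * d2))
                self._param(f"{p}.b", (3 * d2,), init="zeros")
        self._build_ln("gru.ln", c.d_h)
        # Attention fusion
        df = c.d_fused
        for name in ("Wq", "Wk", "Wv", "Wo"):
            self._param(f"attn.{name}", (df, df))
        self._param("attn.bo", (df,), init="zeros")
        self._build_ln("attn.ln", df)
        # Heads
        self._param("head.tox.W", (df + 1, 2))
        self._param("head.tox.b", (2,), init="zeros")
        self._param("head.ss.W", (df, c.n_ss_classes))
        self._param("head.ss.b", (c.n_ss_classes,), init="zeros")
        # Reverse-folding pre-training head (20 amino-acid classes)
        self._param("pretrain.aa.W", (dh, len(AA_ALPHABET)))
        self._param("pretrain.aa.b", (len(AA_ALPHABET),), init="zeros")

    # -- state --------------------------------------------------------------
    def get_state(self):
        return {k: p.data.copy() for k, p in self.params.items()}

    def set_state(self, state):
        for k, v in state.items():
            if k not in self.params:
                raise ShapeMismatch(f"unknown parameter {k}")
            if self.params[k].data.shape != v.shape:
                raise ShapeMismatch(f"shape mismatch for {k}")
            self.params[k].data = v.copy()

    def save(self, path):
        """Versioned checkpoint: arrays in .npz, config in a JSON sidecar."""
        path = str(path)
        np.savez(path if path.endswith(".npz") else path + ".npz",
                 **{k: p.data for k, p in self.params.items()})
        with open(path.removesuffix(".npz") + ".config.json", "w") as fh:
            json.dump({"format_version": 1, "config": asdict(self.config)},
                      fh, indent=2)

    @classmethod
    def load(cls, path):
        path = str(path).removesuffix(".npz")
        with open(path + ".config.json") as fh:
            meta = json.load(fh)
        model = cls(ModelConfig(**meta["config"]))
        data = np.load(path + ".npz")
        model.set_state({k: data[k] for k in data.files})
        return model

    def gnn_parameters(self):
        return {k: v for k, v in self.params.items() if k.startswith("gnn.")}

    # -- building blocks -----------------------------------------------------
    def _ln(self, prefix, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + 1e-5) ** -0.5)
        return xn * self.params[f"{prefix}.gamma"] + self.params[f"{prefix}.beta"]

    @staticmethod
    def _vector_ln(v):
        """Norm-rescaling of vector channels (no learned affine)."""
        sq = (v * v).sum(axis=-1)                  # (..., n_v)
        m = sq.mean(axis=-1, keepdims=True)        # (..., 1)
        scale = (m + 1e-8) ** -0.5
        return v * scale.reshape(*scale.shape, 1)

    def gvp_layer(self, prefix, s, v, activate=True):
        """One geometric vector perceptron.

        Scalars come out rotation-invariant, vectors equivariant: vector
        channels are linearly mixed, their norms join the scalar path, and
        output vectors are gated by a sigmoid of the scalar pre-activation.
        """
        P = self.params
        if s.shape[-1] != P[f"{prefix}.Ws"].shape[0] - P[f"{prefix}.Wh"].shape[1]:
            raise ShapeMismatch(f"scalar width mismatch at {prefix}")
        if v.shape[-2] != P[f"{prefix}.Wh"].shape[0]:
            raise ShapeMismatch(f"vector channel mismatch at {prefix}")
        vh = ad.matmul(v.swapaxes(-1, -2), P[f"{prefix}.Wh"]).swapaxes(-1, -2)
        norms = ad.vector_norm(vh, axis=-1)
        s_lin = ad.matmul(ad.concat([s, norms], axis=-1), P[f"{prefix}.Ws"]) \
            + P[f"{prefix}.bs"]
        s_out = ad.relu(s_lin) if activate else s_lin
        if f"{prefix}.Wv" not in P:
            return s_out, None
        vu = ad.matmul(vh.swapaxes(-1, -2), P[f"{prefix}.Wv"]).swapaxes(-1, -2)
        gate = ad.sigmoid(ad.matmul(s_lin, P[f"{prefix}.Wg"])
                          + P[f"{prefix}.bg"])
        v_out = vu * gate.reshape(*gate.shape, 1)
        return s_out, v_out

    # -- GNN branch ----------------------------------------------------------
    def gnn_forward(self, graphs):
        """Structural features for a batch of graphs (disjoint union).

        Returns a dense (B, L_max, d_h) block of rotation/translation
        invariant scalars, zero on padded rows, plus the flat per-node
        scalars for the pre-training head.
        """
        c = self.config
        B = len(graphs)
        sizes = [g.n_nodes for g in graphs]
        offsets = np.cumsum([0] + sizes)
        n_total = offsets[-1]
        s0 = np.concatenate([g.node_scalars for g in graphs], axis=0)
        v0 = np.concatenate([g.node_vectors for g in graphs], axis=0)
        edge_chunks, es_chunks, ev_chunks = [], [], []
        for g, off in zip(graphs, offsets[:-1]):
            if len(g.edge_index):
                edge_chunks.append(g.edge_index + off)
                es_chunks.append(g.edge_scalars)
                ev_chunks.append(g.edge_vectors)
        if edge_chunks:
            edges = np.concatenate(edge_chunks, axis=0)
            edge_s = Tensor(np.concatenate(es_chunks, axis=0))
            edge_v = Tensor(np.concatenate(ev_chunks, axis=0))
        else:
            edges = np.zeros((0, 2), dtype=int)
            edge_s = Tensor(np.zeros((0, c.n_edge_scalars)))
            edge_v = Tensor(np.zeros((0, 1, 3)))

        s, v = self.gvp_layer("gnn.embed", Tensor(s0), Tensor(v0))
        recv, send = edges[:, 0], edges[:, 1]
        deg = np.bincount(recv, minlength=n_total).astype(float)
        inv_deg = 1.0 / np.maximum(deg, 1.0)

        for l in range(c.n_gnn_layers):
            p = f"gnn.l{l}"
            if len(edges):
                ms = ad.concat([ad.gather_rows(s, send), edge_s], axis=-1)
                mv = ad.concat([ad.gather_rows(v, send), edge_v], axis=-2)
                ms, mv = self.gvp_layer(f"{p}.msg0", ms, mv)
                ms, mv = self.gvp_layer(f"{p}.msg1", ms, mv)
                agg_s = ad.scatter_add_rows(ms, recv, n_total) \
                    * inv_deg[:, None]
                agg_v = ad.scatter_add_rows(mv, recv, n_total) \
                    * inv_deg[:, None, None]
                m_s = self._ln(f"{p}.ln_msg", s + agg_s)
                m_v = self._vector_ln(v + agg_v)
            else:
                m_s = self._ln(f"{p}.ln_msg", s)
                m_v = self._vector_ln(v)
            us, uv = m_s, m_v
            for k in range(3):
                us, uv = self.gvp_layer(f"{p}.upd{k}", us, uv,
                                        activate=(k < 2))
            s = self._ln(f"{p}.ln_upd", s + us)
            v = self._vector_ln(v + uv)

        h_nodes, _ = self.gvp_layer("gnn.readout", s, v, activate=False)
        h_nodes = self._ln("gnn.ln", h_nodes)

        flat_idx = np.concatenate(
            [b * c.L_max + np.arange(n) for b, n in enumerate(sizes)]
        ).astype(int)
        dense = ad.scatter_add_rows(h_nodes, flat_idx, B * c.L_max)
        return dense.reshape(B, c.L_max, c.d_h), h_nodes

    # -- GRU branch ----------------------------------------------------------
    def gru_forward(self, X, lengths):
        """Bi-GRU over the true lengths of a padded batch.

        ``X``: (B, L_max, d_input) array; returns (B, L_max, d_h) with the
        forward and backward half-states concatenated and padded rows zero.
        """
        c = self.config
        X = np.asarray(X, dtype=float)
        B, L_pad, _ = X.shape
        lengths = np.asarray(lengths, dtype=int)
        T = int(lengths.max())
        mask = (np.arange(L_pad)[None, :] < lengths[:, None]).astype(float)
        layer_in = Tensor(X)
        for l in range(c.n_gru_layers):
            halves = []
            for direction in ("fw", "bw"):
                p = f"gru.l{l}.{direction}"
                W = self.params[f"{p}.W"]
                U = self.params[f"{p}.U"]
                b = self.params[f"{p}.b"]
                d2 = U.shape[0]
                # input projections for all timesteps in one matmul
                x_proj = ad.matmul(layer_in, W) + b
                h = Tensor(np.zeros((B, d2)))
                steps = range(T) if direction == "fw" else range(T - 1, -1, -1)
                outs = [None] * T
                for t in steps:
                    xp = x_proj[:, t, :]
                    hp = ad.matmul(h, U)
                    z = ad.sigmoid(xp[:, :d2] + hp[:, :d2])
                    r = ad.sigmoid(xp[:, d2:2 * d2] + hp[:, d2:2 * d2])
                    n = ad.tanh(xp[:, 2 * d2:] + r * hp[:, 2 * d2:])
                    h_new = (1.0 - z) * n + z * h
                    m_t = mask[:, t:t + 1]
                    h = h_new * m_t + h * (1.0 - m_t)
                    outs[t] = (h * m_t).reshape(B, 1, d2)
                half = ad.concat(outs, axis=1)
                if T < L_pad:
                    half = ad.concat(
                        [half, Tensor(np.zeros((B, L_pad - T, d2)))], axis=1
                    )
                halves.append(half)
            layer_in = ad.concat(halves, axis=-1)
        h_seq = self._ln("gru.ln", layer_in) * mask[:, :, None]
        return h_seq

    # -- fusion --------------------------------------------------------------
    def attention_fuse(self, h_seq, h_strct, lengths, dropout_on=False,
                       rng=None):
        """Channel dropout per modality, concatenation, masked multi-head
        self-attention over the fused representation."""
        c = self.config
        B, L_pad = h_seq.shape[0], h_seq.shape[1]
        lengths = np.asarray(lengths, dtype=int)
        mask = (np.arange(L_pad)[None, :] < lengths[:, None]).astype(float)
        if dropout_on:
            rng = rng if rng is not None else np.random.default_rng()
            keep = 1.0 - c.dropout_p
            for which in range(2):
                m = (rng.random((B, 1, c.d_h)) < keep) / keep
                if which == 0:
                    h_seq = h_seq * m
                else:
                    h_strct = h_strct * m
        h_pep = ad.concat([h_seq, h_strct], axis=-1)

        H, dk, df = c.n_heads, c.d_head, c.d_fused

        def split_heads(x):
            return x.reshape(B, L_pad, H, dk).transpose((0, 2, 1, 3))

        q = split_heads(ad.matmul(h_pep, self.params["attn.Wq"]))
        k = split_heads(ad.matmul(h_pep, self.params["attn.Wk"]))
        v = split_heads(ad.matmul(h_pep, self.params["attn.Wv"]))
        scores = ad.matmul(q, k.swapaxes(-1, -2))
        if c.attn_scale:
            scores = scores * (1.0 / np.sqrt(dk))
        scores = scores + ((1.0 - mask) * -1e9)[:, None, None, :]
        attn = ad.softmax(scores, axis=-1)
        attn = attn * mask[:, None, :, None]   # zero rows of padded queries
        ctx = ad.matmul(attn, v).transpose((0, 2, 1, 3)).reshape(B, L_pad, df)
        h_prime = ad.matmul(ctx, self.params["attn.Wo"]) + self.params["attn.bo"]
        h_prime = self._ln("attn.ln", h_prime) * mask[:, :, None]
        return FusedFeatures(
            h_seq=h_seq,
            h_strct=h_strct,
            h_pep=h_pep,
            h_prime=h_prime,
            attention=attn.data,
            lengths=lengths,
            mask=mask,
        )

    # -- heads ---------------------------------------------------------------
    def classify(self, fused: FusedFeatures, amidation, dropout_on=False,
                 rng=None):
        """Pool, append the amidation flag, and score toxicity.

        Returns (p_toxic Tensor (B,), labels array of 'toxic'/'nontoxic').
        """
        c = self.config
        amd = np.asarray(amidation, dtype=float).reshape(-1, 1)
        summed = fused.h_prime.sum(axis=1)
        denom = (np.full(len(amd), float(c.L_max)) if c.paper_pooling
                 else fused.lengths.astype(float))
        pooled = summed * (1.0 / denom)[:, None]
        if dropout_on:
            rng = rng if rng is not None else np.random.default_rng()
            keep = 1.0 - c.dropout_p
            pooled = pooled * ((rng.random(pooled.shape) < keep) / keep)
        z = ad.concat([pooled, Tensor(amd)], axis=-1)
        logits = ad.matmul(z, self.params["head.tox.W"]) \
            + self.params["head.tox.b"]
        probs = ad.softmax(logits, axis=-1)
        p_toxic = probs[:, 1]
        labels = np.where(p_toxic.data > 0.5, "toxic", "nontoxic")
        return p_toxic, labels

    def ss_head(self, fused: FusedFeatures):
        """Per-residue 8-class secondary-structure scores (B, L_max, 8)."""
        return ad.matmul(fused.h_prime, self.params["head.ss.W"]) \
            + self.params["head.ss.b"]

    # -- full passes ---------------------------------------------------------
    def forward(self, batch, dropout_on=False, rng=None):
        """Run the full network on a collated batch.

        ``batch`` is a dict with keys X (B, L_max, d_input), lengths (B,),
        graphs (list of ResidueGraph), amidation (B,), and optionally
        y (B,) and ss (B, L_max with -1 padding).
        """
        h_strct, h_nodes = self.gnn_forward(batch["graphs"])
        h_seq = self.gru_forward(batch["X"], batch["lengths"])
        fused = self.attention_fuse(h_seq, h_strct, batch["lengths"],
                                    dropout_on=dropout_on, rng=rng)
        p_toxic, labels = self.classify(fused, batch["amidation"],
                                        dropout_on=dropout_on, rng=rng)
        ss_scores = self.ss_head(fused)
        return {
            "fused": fused,
            "p_toxic": p_toxic,
            "labels": labels,
            "ss_scores": ss_scores,
            "h_nodes": h_nodes,
        }

    def predict_proba(self, embedded, graphs):
        """Per-structure toxicity probabilities for one peptide."""
        out = []
        for g in graphs:
            batch = {
                "X": embedded.X[None, :, :],
                "lengths": np.array([embedded.length]),
                "graphs": [g],
                "amidation": np.array([float(embedded.amidation)]),
            }
            res = self.forward(batch, dropout_on=False)
            out.append(float(res["p_toxic"].data[0]))
        return np.array(out)


def compute_loss(p_toxic, y, ss_scores=None, ss_labels=None, lambda_ss=0.0):
    """Combined objective (1 - lambda) * L_tox + lambda * L_ss.

    ``p_toxic``: Tensor (B,) of probabilities; ``y``: binary array.
    ``ss_labels``: int array (B, L_max) with -1 marking padded residues;
    they are excluded from the cross-entropy.  Probabilities are clipped to
    [eps, 1 - eps] with eps = 1e-7 before the logs.
    """
    y = np.asarray(y, dtype=float)
    p = ad.clip(p_toxic, EPS_PROB, 1.0 - EPS_PROB)
    ltx = -(ad.log(p) * y + ad.log(1.0 - p) * (1.0 - y)).mean()
    if lambda_ss == 0.0 or ss_scores is None or ss_labels is None:
        return ltx * (1.0 - lambda_ss)
    ss_labels = np.asarray(ss_labels)
    valid = ss_labels >= 0
    n_classes = ss_scores.shape[-1]
    onehot = np.zeros(ss_labels.shape + (n_classes,))
    rows = np.where(valid)
    onehot[rows[0], rows[1], ss_labels[valid]] = 1.0
    p_ss = ad.clip(ad.softmax(ss_scores, axis=-1), EPS_PROB, 1.0)
    nll = -(ad.log(p_ss) * onehot).sum(axis=-1)
    lss = (nll * valid).sum() * (1.0 / max(valid.sum(), 1))
    return ltx * (1.0 - lambda_ss) + lss * lambda_ss
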