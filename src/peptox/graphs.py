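"""Residue-graph featurization of peptide backbones.

A structure becomes a graph with one node per residue and an edge between
every pair of residues whose Cα atoms lie strictly closer than ``d_max``.
Node features split into rotation-invariant scalars (sine/cosine of ω, ψ,
φ) and rotation-equivariant unit vectors (forward Cα direction rᵢ,
backward Cα direction bᵢ, and the Cα→Cβ side-chain direction dᵢ).  Edge
scalars encode the Cα–Cα distance with 16 Gaussian radial basis functions
and the signed backbone offset j−i with a 16-wide sinusoidal code; the
single edge vector is the unit vector from Cαⱼ to Cαᵢ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .backbone import BackboneStructure, DihedralSet
from .errors import LengthMismatch, MalformedStructure

__all__ = [
    "ResidueGraph",
    "build_edges",
    "rbf_encode",
    "positional_encode",
    "featurize_graph",
    "save_graphs",
    "load_graphs",
]

N_RBF = 16
N_POS = 16


@dataclass
class ResidueGraph:
    id: str
    n_nodes: int
    edge_index: np.ndarray      # (E, 2) int, row (i, j): i receives from j
    node_scalars: np.ndarray    # (L, 6)
    node_vectors: np.ndarray    # (L, 3, 3)
    edge_scalars: np.ndarray    # (E, 32)
    edge_vectors: np.ndarray    # (E, 1, 3), unit(Cα_i − Cα_j)
    d_max: float

    def summary(self):
        return {
            "id": self.id,
            "n_nodes": int(self.n_nodes),
            "n_edges": int(len(self.edge_index)),
            "d_max": float(self.d_max),
            "node_scalar_dim": int(self.node_scalars.shape[1]),
            "edge_scalar_dim": int(self.edge_scalars.shape[1]),
        }


def build_edges(coords_CA, d_max):
    """All ordered residue pairs with Cα distance strictly below ``d_max``."""
    coords = np.asarray(coords_CA, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise LengthMismatch("need at least one residue")
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    close = dist < d_max
    np.fill_diagonal(close, False)
    i, j = np.nonzero(close)
    return np.stack([i, j], axis=1)


def rbf_encode(distance, n_centers=N_RBF, d_cut=12.0):
    """Gaussian radial basis expansion of a distance in Å.

    Centers are evenly spaced on [0, d_cut] and the width σ equals the
    center spacing, so each output lies in (0, 1] with a peak of exactly 1
    when the distance sits on a center.
    """
    d = np.asarray(distance, dtype=float)
    centers = np.linspace(0.0, d_cut, n_centers)
    sigma = centers[1] - centers[0]
    return np.exp(-(((d[..., None] - centers) / sigma) ** 2))


def positional_encode(offset, n_feats=N_POS):
    """Transformer-style sinusoidal encoding of the signed offset j−i."""
    off = np.asarray(offset, dtype=float)
    k = np.arange(n_feats // 2)
    freq = 10000.0 ** (-2.0 * k / n_feats)
    arg = off[..., None] * freq
    out = np.empty(off.shape + (n_feats,))
    out[..., 0::2] = np.sin(arg)
    out[..., 1::2] = np.cos(arg)
    return out


def _safe_unit(v):
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    return np.where(norm > 0, v / np.where(norm > 0, norm, 1.0), 0.0)


def featurize_graph(s: BackboneStructure, d: DihedralSet, d_max=12.0,
                    n_rbf=N_RBF, n_pos=N_POS) -> ResidueGraph:
    """Build the full residue graph for one backbone.

    Requires every residue to carry a Cβ (recorded or imputed).  Undefined
    terminal dihedrals contribute sin = cos = 0; the last forward vector
    r_L and the first backward vector b_1 are zero sentinels.
    """
    L = len(s)
    if len(d) != L:
        raise LengthMismatch("dihedral set length differs from structure")
    if not np.all(s.has_cb):
        raise MalformedStructure(
            "all residues need a Cβ; run impute_cbeta first"
        )

    sc = np.zeros((L, 6))
    for col, (ang, defined) in enumerate(
        [(d.omega, d.omega_defined), (d.psi, d.psi_defined),
         (d.phi, d.phi_defined)]
    ):
        sc[defined, 2 * col] = np.sin(ang[defined])
        sc[defined, 2 * col + 1] = np.cos(ang[defined])

    ca = s.coords_CA
    fwd = np.zeros((L, 3))
    bwd = np.zeros((L, 3))
    fwd[:-1] = _safe_unit(ca[1:] - ca[:-1])
    bwd[1:] = _safe_unit(ca[:-1] - ca[1:])
    side = _safe_unit(s.coords_CB - ca)
    node_vectors = np.stack([fwd, bwd, side], axis=1)

    edges = build_edges(ca, d_max)
    if len(edges):
        i, j = edges[:, 0], edges[:, 1]
        dist = np.linalg.norm(ca[i] - ca[j], axis=-1)
        edge_scalars = np.concatenate(
            [rbf_encode(dist, n_rbf, d_cut=d_max),
             positional_encode((j - i).astype(float), n_pos)],
            axis=1,
        )
        edge_vectors = _safe_unit(ca[i] - ca[j])[:, None, :]
    else:
        edge_scalars = np.zeros((0, n_rbf + n_pos))
        edge_vectors = np.zeros((0, 1, 3))

    return ResidueGraph(
        id=s.id,
        n_nodes=L,
        edge_index=edges,
        node_scalars=sc,
        node_vectors=node_vectors,
        edge_scalars=edge_scalars,
        edge_vectors=edge_vectors,
        d_max=float(d_max),
    )


def save_graphs(graphs, path, summary_path=None):
    """Serialize graphs to one ``.npz`` container (arrays keyed by id)."""
    payload = {}
    for g in graphs:
        for fld in ("edge_index", "node_scalars", "node_vectors",
                    "edge_scalars", "edge_vectors"):
            payload[f"{g.id}::{fld}"] = getattr(g, fld)
        payload[f"{g.id}::meta"] = np.array([g.n_nodes, g.d_max])
    np.savez(path, **payload)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump([g.summary() for g in graphs], fh, indent=2)


def load_graphs(path):
    data = np.load(path, allow_pickle=False)
    ids = sorted({k.split("::")[0] for k in data.files})
    out = []
    for gid in ids:
        n_nodes, d_max = data[f"{gid}::meta"]
        out.append(ResidueGraph(
            id=gid,
            n_nodes=int(n_nodes),
            edge_index=data[f"{gid}::edge_index"].astype(int),
            node_scalars=data[f"{gid}::node_scalars"],
            node_vectors=data[f"{gid}::node_vectors"],
            edge_scalars=data[f"{gid}::edge_scalars"],
            edge_vectors=data[f"{gid}::edge_vectors"],
            d_max=float(d_max),
        ))
    return out
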