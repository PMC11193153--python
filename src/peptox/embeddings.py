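"""Per-residue sequence embeddings, zero-padded to the model length.

Two kinds of backend provide the ``L_max x d_input`` matrix ``X``: an
optional external protein-language-model adapter (ESM2, if the ``esm``
package is installed) and a built-in deterministic synthetic embedder used
for testing and simulation.  Nothing downstream depends on which backend
produced the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .backbone import AA_ALPHABET
from .errors import (
    BackendUnavailable,
    EmptySequence,
    IllegalResidue,
    SequenceTooLong,
)

__all__ = [
    "EmbeddedPeptide",
    "embed_sequence",
    "synthetic_embed",
    "read_fasta",
    "write_fasta",
    "save_embeddings",
    "load_embeddings",
]

DEFAULT_L_MAX = 50
SYNTHETIC_D_INPUT = 64

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass
class EmbeddedPeptide:
    id: str
    sequence: str
    X: np.ndarray            # (L_max, d_input); rows beyond length are zero
    length: int
    amidation: bool = False
    label: str = "unknown"   # toxic | nontoxic | unknown

    @property
    def d_input(self):
        return self.X.shape[1]

    @property
    def L_max(self):
        return self.X.shape[0]


def _validate_sequence(seq, L_max):
    if len(seq) == 0:
        raise EmptySequence("sequence is empty")
    bad = set(seq) - set(AA_ALPHABET)
    if bad:
        raise IllegalResidue(f"non-natural residues {sorted(bad)} in {seq!r}")
    if L_max is not None and len(seq) > L_max:
        raise SequenceTooLong(f"length {len(seq)} exceeds L_max={L_max}")


# Per-(seed, d_input) base tables, built lazily.
_BASE_CACHE = {}


def _base_table(seed, d_input):
    key = (int(seed), int(d_input))
    if key not in _BASE_CACHE:
        rng = np.random.default_rng(np.random.SeedSequence([17, *key]))
        _BASE_CACHE[key] = rng.uniform(-0.8, 0.8, size=(20, d_input))
    return _BASE_CACHE[key]


def synthetic_embed(seq, d_input=SYNTHETIC_D_INPUT, seed=0):
    """Deterministic stand-in embedder for the external language model.

    Row i is a fixed random vector for the residue identity at position i
    plus a small sinusoidal positional component, so the value depends only
    on (residue, position, seed), stays within [-1, 1], and differs between
    residues at the same position.
    """
    if d_input < 8:
        raise ValueError("d_input must be at least 8")
    _validate_sequence(seq, L_max=None)
    base = _base_table(seed, d_input)
    idx = np.array([_AA_INDEX[a] for a in seq])
    pos = np.arange(len(seq), dtype=float)
    k = np.arange(d_input // 2)
    freq = 100.0 ** (-2.0 * k / d_input)
    arg = pos[:, None] * freq
    posenc = np.empty((len(seq), d_input))
    posenc[:, 0::2] = np.sin(arg)
    posenc[:, 1::2] = np.cos(arg)
    return base[idx] + 0.2 * posenc


def _esm_embed(seq, variant):
    try:
        import esm  # noqa: F401  (optional external dependency)
    except ImportError as exc:
        raise BackendUnavailable(
            "the 'esm' package with pretrained ESM2 weights is required for "
            f"the {variant} backend; install fair-esm or use the synthetic "
            "backend"
        ) from exc
    import torch

    loader = {
        "plm-small": esm.pretrained.esm2_t12_35M_UR50D,
        "plm-large": esm.pretrained.esm2_t33_650M_UR50D,
    }[variant]
    model, alphabet = loader()
    model.eval()
    batch_converter = alphabet.get_batch_converter()
    _, _, tokens = batch_converter([("query", seq)])
    layer = {"plm-small": 12, "plm-large": 33}[variant]
    with torch.no_grad():
        reps = model(tokens, repr_layers=[layer])["representations"][layer]
    return reps[0, 1:len(seq) + 1].numpy()


def embed_sequence(seq, backend="synthetic", L_max=DEFAULT_L_MAX,
                   d_input=None, seed=0, id=None, amidation=False,
                   label="unknown"):
    """Embed one peptide sequence and right-pad with zeros to ``L_max``."""
    _validate_sequence(seq, L_max)
    if backend == "synthetic":
        rows = synthetic_embed(seq, d_input or SYNTHETIC_D_INPUT, seed)
    elif backend in ("plm-small", "plm-large"):
        rows = _esm_embed(seq, backend)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    X = np.zeros((L_max, rows.shape[1]))
    X[:len(seq)] = rows
    return EmbeddedPeptide(
        id=id if id is not None else seq,
        sequence=seq,
        X=X,
        length=len(seq),
        amidation=bool(amidation),
        label=label,
    )


# ---------------------------------------------------------------------------
# FASTA and on-disk cache


def read_fasta(path):
    """Return [(id, sequence), ...] from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries, path):
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


def save_embeddings(peptides, path, backend="synthetic"):
    """Cache embedding matrices to one ``.npz``, keyed by (backend, id)."""
    payload = {f"{backend}::{p.id}": p.X for p in peptides}
    np.savez(path, **payload)


def load_embeddings(path, backend="synthetic"):
    data = np.load(path, allow_pickle=False)
    prefix = f"{backend}::"
    return {
        k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)
    }
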