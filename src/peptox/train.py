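"""Optimization: supervised training with early stopping, reverse-folding
pre-training of the structural branch, and ensemble prediction.

Each of a peptide's (up to five) predicted structures is a separate
training sample carrying the peptide's label — the augmentation used at
training time — while validation and test scoring average the per-structure
probabilities back to one value per peptide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Adam
from .backbone import AA_ALPHABET, assign_ss8, compute_dihedrals, impute_cbeta
from .embeddings import EmbeddedPeptide
from .errors import (
    EmptyEnsemble,
    EmptySplit,
    IllegalResidue,
    Leakage,
    LengthMismatch,
)
from .graphs import ResidueGraph, featurize_graph
from .model import ModelConfig, ToxicityModel, compute_loss
from .metrics import confusion_counts

__all__ = [
    "TrainConfig",
    "PeptideSample",
    "prepare_samples",
    "train_model",
    "pretrain_reverse_folding",
    "predict_ensemble",
    "ensemble_validation_f1",
]


@dataclass
class TrainConfig:
    lr: float = 4e-4
    weight_decay: float = 1e-7
    batch_size: int = 32
    patience: int = 20           # epochs without val-F1 improvement
    max_epochs: int = 500
    seed: int = 0
    lambda_ss: float = 0.2
    ensemble_validation: bool = True  # score val peptides on averaged p
    finetune_pretrained: bool = True  # fine-tune (vs freeze) GNN weights

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


@dataclass
class PeptideSample:
    """One (peptide, structure) training sample."""

    peptide_id: str
    embedded: EmbeddedPeptide
    graph: ResidueGraph
    ss_labels: np.ndarray    # (L,) int
    y: int                   # 1 = toxic


def prepare_samples(records, config: ModelConfig):
    """Featurize dataset records into per-structure samples.

    ``records`` iterate as objects with .id, .embedding (EmbeddedPeptide),
    .structures (list of BackboneStructure), .label, and optionally
    precomputed .ss_labels per structure.
    """
    samples = []
    for rec in records:
        ss_list = getattr(rec, "ss_labels", None)
        for k, structure in enumerate(rec.structures):
            s = impute_cbeta(structure)
            d = compute_dihedrals(s)
            g = featurize_graph(s, d, d_max=config.d_max)
            ss = (ss_list[k] if ss_list is not None else assign_ss8(s, d))
            samples.append(PeptideSample(
                peptide_id=rec.id,
                embedded=rec.embedding,
                graph=g,
                ss_labels=np.asarray(ss, dtype=int),
                y=int(rec.label == "toxic"),
            ))
    return samples


def collate(samples, L_max):
    B = len(samples)
    X = np.stack([s.embedded.X for s in samples])
    lengths = np.array([s.embedded.length for s in samples])
    ss = np.full((B, L_max), -1, dtype=int)
    for b, s in enumerate(samples):
        ss[b, :len(s.ss_labels)] = s.ss_labels
    return {
        "X": X,
        "lengths": lengths,
        "graphs": [s.graph for s in samples],
        "amidation": np.array([float(s.embedded.amidation) for s in samples]),
        "y": np.array([s.y for s in samples]),
        "ss": ss,
    }


def _f1_at_half(y_true, p):
    """F1 with 'toxic' positive at the strict 0.5 threshold."""
    pred = (np.asarray(p) > 0.5).astype(int)
    tp, fp, tn, fn = confusion_counts(y_true, pred)
    denom = tp + 0.5 * (fp + fn)
    return tp / denom if denom > 0 else 0.0


def ensemble_validation_f1(model, samples):
    """Validation F1 on per-peptide ensemble-averaged probabilities."""
    by_pep = {}
    for s in samples:
        by_pep.setdefault(s.peptide_id, []).append(s)
    y, p = [], []
    for pid, group in by_pep.items():
        batch = collate(group, model.config.L_max)
        res = model.forward(batch, dropout_on=False)
        y.append(group[0].y)
        p.append(float(res["p_toxic"].data.mean()))
    return _f1_at_half(np.array(y), np.array(p)), np.array(y), np.array(p)


def _per_structure_validation_f1(model, samples):
    batch_size = 64
    y, p = [], []
    for lo in range(0, len(samples), batch_size):
        chunk = samples[lo:lo + batch_size]
        res = model.forward(collate(chunk, model.config.L_max),
                            dropout_on=False)
        y.extend(s.y for s in chunk)
        p.extend(res["p_toxic"].data.tolist())
    return _f1_at_half(np.array(y), np.array(p)), np.array(y), np.array(p)


def train_model(train_records, val_records, mc: ModelConfig,
                tc: TrainConfig, pretrained_gnn=None, verbose=False):
    """Adam training of the combined loss with early stopping on val F1.

    Returns (model carrying the best-epoch weights, history list of dicts).
    """
    train_records, val_records = list(train_records), list(val_records)
    if not train_records or not val_records:
        raise EmptySplit("both train and validation sets must be non-empty")
    shared = {r.id for r in train_records} & {r.id for r in val_records}
    if shared:
        raise Leakage(f"ids in both splits: {sorted(shared)[:5]}")

    train_samples = prepare_samples(train_records, mc)
    val_samples = prepare_samples(val_records, mc)

    model = ToxicityModel(mc)
    if pretrained_gnn is not None:
        model.set_state({k: v for k, v in pretrained_gnn.items()
                         if k.startswith("gnn.")})
    params = dict(model.params)
    if pretrained_gnn is not None and not tc.finetune_pretrained:
        params = {k: v for k, v in params.items() if not k.startswith("gnn.")}
    opt = Adam(params, lr=tc.lr, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed)

    history = []
    best_f1, best_state, wait = -np.inf, model.get_state(), 0
    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(train_samples))
        losses = []
        for lo in range(0, len(order), tc.batch_size):
            batch_samples = [train_samples[i]
                             for i in order[lo:lo + tc.batch_size]]
            batch = collate(batch_samples, mc.L_max)
            out = model.forward(batch, dropout_on=True, rng=rng)
            loss = compute_loss(out["p_toxic"], batch["y"],
                                out["ss_scores"], batch["ss"],
                                lambda_ss=tc.lambda_ss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        if tc.ensemble_validation:
            val_f1, _, _ = ensemble_validation_f1(model, val_samples)
        else:
            val_f1, _, _ = _per_structure_validation_f1(model, val_samples)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_f1": float(val_f1)})
        if verbose:
            print(f"epoch {epoch:3d} loss {np.mean(losses):.4f} "
                  f"val_f1 {val_f1:.3f}")
        if val_f1 > best_f1:
            best_f1, best_state, wait = val_f1, model.get_state(), 0
        else:
            wait += 1
            if wait >= tc.patience:
                break
    model.set_state(best_state)
    return model, history


def pretrain_reverse_folding(graphs, sequences, mc: ModelConfig,
                             tc: TrainConfig, epochs=10):
    """Pre-train the GNN branch to predict residue identity from structure.

    Twenty-class per-node cross-entropy over the graph features alone; the
    returned dict of ``gnn.*`` arrays can seed :func:`train_model`.
    """
    graphs, sequences = list(graphs), list(sequences)
    if len(graphs) != len(sequences):
        raise LengthMismatch("one sequence per graph required")
    for g, seq in zip(graphs, sequences):
        if g.n_nodes != len(seq):
            raise LengthMismatch(f"graph/sequence length differ for {g.id}")
        bad = set(seq) - set(AA_ALPHABET)
        if bad:
            raise IllegalResidue(f"labels outside 20-letter alphabet: {bad}")
    labels = np.concatenate(
        [[AA_ALPHABET.index(a) for a in seq] for seq in sequences]
    ).astype(int)

    model = ToxicityModel(mc)
    params = {k: v for k, v in model.params.items()
              if k.startswith(("gnn.", "pretrain."))}
    opt = Adam(params, lr=tc.lr, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed)
    n = len(graphs)
    history = []
    onehot_eye = np.eye(len(AA_ALPHABET))
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, correct, total = [], 0, 0
        for lo in range(0, n, tc.batch_size):
            idx = order[lo:lo + tc.batch_size]
            batch_graphs = [graphs[i] for i in idx]
            y = np.concatenate(
                [[AA_ALPHABET.index(a) for a in sequences[i]] for i in idx]
            ).astype(int)
            _, h_nodes = model.gnn_forward(batch_graphs)
            logits = ad.matmul(h_nodes, model.params["pretrain.aa.W"]) \
                + model.params["pretrain.aa.b"]
            p = ad.clip(ad.softmax(logits, axis=-1), 1e-9, 1.0)
            loss = -(ad.log(p) * onehot_eye[y]).sum(axis=-1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=-1) == y).sum())
            total += len(y)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "node_accuracy": correct / total})
    weights = {k: v.data.copy() for k, v in model.gnn_parameters().items()}
    return weights, history


def predict_ensemble(model, embedded, structures_or_graphs):
    """Average per-structure probabilities into one call per peptide.

    Accepts raw backbones (featurized on the fly with the model's d_max)
    or prebuilt residue graphs.  Returns (p_final, label, per-structure p).
    """
    items = list(structures_or_graphs)
    if not items:
        raise EmptyEnsemble("need at least one structure")
    graphs = []
    for item in items:
        if isinstance(item, ResidueGraph):
            graphs.append(item)
        else:
            s = impute_cbeta(item)
            graphs.append(featurize_graph(s, compute_dihedrals(s),
                                          d_max=model.config.d_max))
    per_structure = model.predict_proba(embedded, graphs)
    p_final = float(per_structure.mean())
    label = "toxic" if p_final > 0.5 else "nontoxic"
    return p_final, label, per_structure
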