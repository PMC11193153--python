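"""Synthetic peptides: backbones from internal coordinates, structure
presets, and labeled datasets with a plantable toxicity signal.

Backbones are grown atom by atom (NeRF-style) from per-residue (φ, ψ, ω)
torsions with ideal bond lengths and angles, so the dihedral computation in
:mod:`peptox.backbone` can be verified as an exact inverse.  The labeled
dataset plants a logistic signal that couples a structural cue (helix
fraction) with a compositional cue (cationic-residue fraction), so neither
the sequence branch nor the structure branch of the model can separate the
classes alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .backbone import (
    AA_ALPHABET,
    BackboneStructure,
    assign_ss8,
    compute_dihedrals,
    virtual_cbeta,
    write_pdb,
    read_pdb,
)
from .embeddings import EmbeddedPeptide, embed_sequence, write_fasta
from .errors import InvalidAngles

__all__ = [
    "BOND_N_CA",
    "BOND_CA_C",
    "BOND_C_N",
    "BackboneSpec",
    "SyntheticDatasetSpec",
    "SyntheticPeptide",
    "build_backbone_from_dihedrals",
    "make_structure_preset",
    "generate_labeled_dataset",
    "synthetic_hc50_replicates",
    "write_dataset",
    "load_dataset",
]

# Ideal backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-119.0, 113.0)


@dataclass
class BackboneSpec:
    """Internal-coordinate description of one backbone.

    φ of the first and ψ/ω of the last residue are ignored during
    construction (they do not define any atom).  ``noise_sd`` adds
    isotropic Gaussian jitter (Å) to all atoms after placement.
    """

    sequence: str
    phi: np.ndarray     # degrees, per residue
    psi: np.ndarray
    omega: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0
    plddt: np.ndarray | None = None

    def __post_init__(self):
        L = len(self.sequence)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        for name in ("phi", "psi", "omega"):
            arr = getattr(self, name)
            if arr.shape != (L,):
                raise InvalidAngles(f"{name} must have one entry per residue")
            if np.any((arr <= -180.0) | (arr > 180.0)):
                raise InvalidAngles(f"{name} entries must lie in (-180, 180]")
        if self.noise_sd < 0:
            raise InvalidAngles("noise_sd must be non-negative")


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Next atom D from the three previous ones: |CD| = bond, angle BCD,
    torsion ABCD (same sign convention as :func:`peptox.backbone.dihedral`).
    """
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi),
         np.sin(theta) * np.sin(chi)]
    )
    return c + m @ d_local


def build_backbone_from_dihedrals(spec: BackboneSpec) -> BackboneStructure:
    """Sequential internal-coordinate construction of N/Cα/C (+Cβ) atoms.

    β-carbons are placed tetrahedrally for every residue except glycine
    (left absent, as in real backbone records); synthetic pLDDT defaults to
    Uniform(70, 95) per residue.
    """
    L = len(spec.sequence)
    rng = np.random.default_rng(spec.seed)
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.radians(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(L - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i], BOND_C_N,
                               ANGLE_CA_C_N, spec.psi[i])
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], BOND_N_CA,
                                ANGLE_C_N_CA, spec.omega[i])
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], BOND_CA_C,
                               ANGLE_N_CA_C, spec.phi[i + 1])
    if spec.noise_sd > 0:
        N = N + rng.normal(0.0, spec.noise_sd, N.shape)
        CA = CA + rng.normal(0.0, spec.noise_sd, CA.shape)
        C = C + rng.normal(0.0, spec.noise_sd, C.shape)
    CB = np.full((L, 3), np.nan)
    for i, aa in enumerate(spec.sequence):
        if aa != "G":
            CB[i] = virtual_cbeta(N[i], CA[i], C[i])
    plddt = (spec.plddt if spec.plddt is not None
             else rng.uniform(70.0, 95.0, L))
    return BackboneStructure(
        id=f"synthetic-{spec.seed}",
        sequence=spec.sequence,
        coords_N=N,
        coords_CA=CA,
        coords_C=C,
        coords_CB=CB,
        cb_imputed=np.zeros(L, dtype=bool),
        plddt=np.asarray(plddt, dtype=float),
    )


def _coil_dihedrals(rng, n):
    """Dihedrals far from the canonical helix/strand regions (positive φ)."""
    phi = rng.uniform(40.0, 140.0, n)
    psi = rng.uniform(-170.0, 170.0, n)
    return phi, psi


def make_structure_preset(kind, n, seed=0, noise_sd=0.0, sequence=None):
    """Canonical helix (φ=-57, ψ=-47), strand (φ=-119, ψ=113) or random
    coil backbone of ``n`` residues; deterministic for a fixed seed."""
    if n < 2:
        raise InvalidAngles("presets need at least 2 residues")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = "".join(rng.choice(list(AA_ALPHABET), n))
    if kind == "helix":
        phi = np.full(n, HELIX_PHI_PSI[0])
        psi = np.full(n, HELIX_PHI_PSI[1])
    elif kind == "strand":
        phi = np.full(n, STRAND_PHI_PSI[0])
        psi = np.full(n, STRAND_PHI_PSI[1])
    elif kind == "coil":
        phi, psi = _coil_dihedrals(rng, n)
    else:
        raise ValueError(f"unknown preset kind {kind!r}")
    omega = np.full(n, 180.0)
    spec = BackboneSpec(sequence=sequence, phi=phi, psi=psi, omega=omega,
                        noise_sd=noise_sd, seed=seed)
    s = build_backbone_from_dihedrals(spec)
    s.id = f"{kind}-{n}-{seed}"
    return s


# ---------------------------------------------------------------------------
# Labeled datasets


@dataclass
class SyntheticDatasetSpec:
    """Conditions of the simulated study.

    Labels follow a logistic model in the realized helix fraction hf (0-1)
    and cationic-residue (K/R) fraction cf (0-0.6):
    P(toxic) = sigmoid(bias + coef_helix * hf + coef_cationic * cf).
    ``signal_scale`` multiplies all three coefficients (``inf`` degrades
    the logistic to exact thresholding); ``min_margin`` excludes peptides
    whose raw linear score falls within that distance of the decision
    boundary, making the classes cleanly separable.  Each peptide gets
    ``n_structures`` jittered backbones, emulating an ensemble of
    predictor outputs.
    """

    n_peptides: int = 200
    length_range: tuple = (5, 50)
    class_balance: float = 0.5
    bias: float = -8.0
    coef_helix: float = 8.0
    coef_cationic: float = 16.0
    signal_scale: float = 1.0
    min_margin: float = 0.0
    label_noise: float = 0.0
    n_structures: int = 5
    structure_noise_sd: float = 0.15
    amidation_rate: float = 0.25
    embed_dim: int = 64
    L_max: int = 50
    seed: int = 0


@dataclass
class SyntheticPeptide:
    id: str
    sequence: str
    amidation: bool
    label: str
    helix_fraction: float
    cationic_fraction: float
    planted_score: float
    structures: list
    ss_labels: list
    embedding: EmbeddedPeptide


def _sigmoid(z):
    # numerically stable for arbitrarily large |z| (incl. +-inf)
    z = np.asarray(z, dtype=float)
    out = np.where(z >= 0,
                   1.0 / (1.0 + np.exp(-np.abs(z))),
                   np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    return float(out) if out.ndim == 0 else out


def planted_probability(spec: SyntheticDatasetSpec, helix_fraction,
                        cationic_fraction):
    """The generative P(toxic) — reusable as an independent oracle.

    ``signal_scale=inf`` degenerates to exact thresholding of the raw
    linear score at zero (deterministic labels).
    """
    raw = (spec.bias
           + spec.coef_helix * helix_fraction
           + spec.coef_cationic * cationic_fraction)
    if np.isinf(spec.signal_scale):
        return (1.0 if raw > 0 else 0.0), raw
    z = spec.signal_scale * raw
    return _sigmoid(z), z


_CATIONIC = "KR"
_NEUTRAL = "".join(a for a in AA_ALPHABET if a not in _CATIONIC)


def _sample_peptide(spec, rng, pep_index, y):
    lo, hi = spec.length_range
    for _ in range(1000):
        L = int(rng.integers(lo, hi + 1))
        hf = rng.uniform(0.0, 1.0)
        cf = rng.uniform(0.0, 0.6)
        n_helix = int(round(hf * L))
        n_cat = min(int(round(cf * L)), L)
        hf_real = n_helix / L
        cf_real = n_cat / L
        p, z = planted_probability(spec, hf_real, cf_real)
        if spec.min_margin > 0:
            raw = (spec.bias + spec.coef_helix * hf_real
                   + spec.coef_cationic * cf_real)
            if abs(raw) < spec.min_margin:
                continue
        accept = p if y else (1.0 - p)
        if rng.random() < accept:
            return L, n_helix, n_cat, hf_real, cf_real, z
    raise RuntimeError("rejection sampling failed; coefficients too extreme "
                       "for the requested class")


def generate_labeled_dataset(spec: SyntheticDatasetSpec):
    """Deterministic labeled corpus of peptides with structures, secondary
    structure labels, and synthetic embeddings attached."""
    rng = np.random.default_rng(spec.seed)
    peptides = []
    for idx in range(spec.n_peptides):
        y = int(rng.random() < spec.class_balance)
        L, n_helix, n_cat, hf, cf, z = _sample_peptide(spec, rng, idx, y)
        positions = rng.permutation(L)[:n_cat]
        seq = [str(rng.choice(list(_NEUTRAL))) for _ in range(L)]
        for pos in positions:
            seq[pos] = str(rng.choice(list(_CATIONIC)))
        seq = "".join(seq)
        label = y
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            label = 1 - label
        amidation = bool(rng.random() < spec.amidation_rate)

        structures, ss_labels = [], []
        coil_phi, coil_psi = _coil_dihedrals(rng, L)
        phi = coil_phi.copy()
        psi = coil_psi.copy()
        phi[:n_helix] = HELIX_PHI_PSI[0]
        psi[:n_helix] = HELIX_PHI_PSI[1]
        for k in range(spec.n_structures):
            bspec = BackboneSpec(
                sequence=seq,
                phi=phi,
                psi=psi,
                omega=np.full(L, 180.0),
                noise_sd=spec.structure_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            s = build_backbone_from_dihedrals(bspec)
            s.id = f"pep{idx:04d}_s{k}"
            structures.append(s)
            ss_labels.append(assign_ss8(s, compute_dihedrals(s)))
        emb = embed_sequence(
            seq, backend="synthetic", L_max=spec.L_max,
            d_input=spec.embed_dim, seed=spec.seed,
            id=f"pep{idx:04d}", amidation=amidation,
            label="toxic" if label else "nontoxic",
        )
        peptides.append(SyntheticPeptide(
            id=f"pep{idx:04d}",
            sequence=seq,
            amidation=amidation,
            label="toxic" if label else "nontoxic",
            helix_fraction=hf,
            cationic_fraction=cf,
            planted_score=z,
            structures=structures,
            ss_labels=ss_labels,
            embedding=emb,
        ))
    return peptides


def synthetic_hc50_replicates(n_toxic=56, n_nontoxic=284, n_replicates=3,
                              seed=0):
    """Synthetic stand-in for a replicate HC50 assay table.

    Generates ``n_toxic`` peptides whose replicate values put them at or
    below 128 µg/mL in at least two of ``n_replicates`` experiments, and
    ``n_nontoxic`` peptides that fail that rule, mimicking the composition
    of an in-house hemolysis test set.  Returns a tidy DataFrame with
    columns id, sequence, hc50_1..hc50_k.
    """
    rng = np.random.default_rng(seed)
    rows = []

    def sample_seq():
        L = int(rng.integers(8, 40))
        return "".join(rng.choice(list(AA_ALPHABET), L))

    for i in range(n_toxic):
        n_low = int(rng.integers(2, n_replicates + 1))
        lows = rng.uniform(5.0, 128.0, n_low)
        highs = rng.uniform(140.0, 1280.0, n_replicates - n_low)
        reps = rng.permutation(np.concatenate([lows, highs]))
        rows.append(("tox%04d" % i, sample_seq(), *np.round(reps, 1)))
    for i in range(n_nontoxic):
        n_low = int(rng.integers(0, 2))  # at most one replicate <= 128
        lows = rng.uniform(5.0, 128.0, n_low)
        highs = rng.uniform(140.0, 1280.0, n_replicates - n_low)
        reps = rng.permutation(np.concatenate([lows, highs]))
        rows.append(("non%04d" % i, sample_seq(), *np.round(reps, 1)))
    cols = ["id", "sequence"] + [f"hc50_{k+1}" for k in range(n_replicates)]
    df = pd.DataFrame(rows, columns=cols)
    return df.sample(frac=1.0, random_state=seed).reset_index(drop=True)


# ---------------------------------------------------------------------------
# On-disk layout


def write_dataset(peptides, out_dir, spec: SyntheticDatasetSpec = None):
    """Write PDBs (pLDDT in B-factor), FASTA, and a manifest CSV."""
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    rows = []
    for pep in peptides:
        for s in pep.structures:
            write_pdb(s, out / "structures" / f"{s.id}.pdb")
        rows.append({
            "id": pep.id,
            "sequence": pep.sequence,
            "amidation": int(pep.amidation),
            "label": pep.label,
            "n_structures": len(pep.structures),
            "helix_fraction": pep.helix_fraction,
            "cationic_fraction": pep.cationic_fraction,
        })
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    write_fasta([(p.id, p.sequence) for p in peptides], out / "peptides.fasta")
    meta = {"embed_dim": peptides[0].embedding.d_input,
            "L_max": peptides[0].embedding.L_max,
            "embed_seed": spec.seed if spec is not None else 0}
    with open(out / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_dataset(data_dir):
    """Reload a dataset directory written by :func:`write_dataset`."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    with open(data_dir / "meta.json") as fh:
        meta = json.load(fh)
    peptides = []
    for _, row in manifest.iterrows():
        structures = []
        for k in range(int(row["n_structures"])):
            s = read_pdb(data_dir / "structures" / f"{row['id']}_s{k}.pdb")
            s.id = f"{row['id']}_s{k}"
            structures.append(s)
        emb = embed_sequence(
            row["sequence"], backend="synthetic", L_max=meta["L_max"],
            d_input=meta["embed_dim"], seed=meta["embed_seed"],
            id=row["id"], amidation=bool(row["amidation"]),
            label=row["label"],
        )
        peptides.append(SyntheticPeptide(
            id=row["id"],
            sequence=row["sequence"],
            amidation=bool(row["amidation"]),
            label=row["label"],
            helix_fraction=float(row["helix_fraction"]),
            cationic_fraction=float(row["cationic_fraction"]),
            planted_score=np.nan,
            structures=structures,
            ss_labels=None,
            embedding=emb,
        ))
    return peptides
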