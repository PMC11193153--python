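"""Backbone geometry: PDB I/O, dihedrals, virtual Cβ, secondary structure.

Structures are reduced to the four backbone atoms the downstream graph
featurization needs (N, Cα, C, plus a recorded or virtual Cβ) together with
the per-residue pLDDT confidence that structure predictors write into the
PDB B-factor column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import (
    ChainNotFound,
    DegenerateGeometry,
    EmptyEnsemble,
    LengthMismatch,
    MalformedStructure,
)

__all__ = [
    "AA_ALPHABET",
    "SS8_ALPHABET",
    "BackboneStructure",
    "DihedralSet",
    "read_pdb",
    "write_pdb",
    "impute_cbeta",
    "virtual_cbeta",
    "dihedral",
    "compute_dihedrals",
    "assign_ss8",
    "ss8_from_string",
    "read_ss8_table",
    "rank_by_plddt",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_AA_3TO1 = {v: k for k, v in _AA_1TO3.items()}

# 8-state secondary-structure alphabet; the built-in assigner only emits
# H (alpha helix), E (extended strand) and C (coil), but external label
# files may use the full alphabet.
SS8_ALPHABET = "HGIEBTSC"

CB_BOND_LENGTH = 1.522  # Å, Cα–Cβ
_TETRAHEDRAL = np.arccos(-1.0 / 3.0)


@dataclass
class BackboneStructure:
    """Per-residue backbone record.

    ``coords_CB`` rows are NaN where no β-carbon is recorded (glycine, or
    absent from the file) until :func:`impute_cbeta` fills them in.
    """

    id: str
    sequence: str
    coords_N: np.ndarray
    coords_CA: np.ndarray
    coords_C: np.ndarray
    coords_CB: np.ndarray
    cb_imputed: np.ndarray
    plddt: np.ndarray
    chain_id: str = "A"

    def __post_init__(self):
        for name in ("coords_N", "coords_CA", "coords_C", "coords_CB"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.cb_imputed = np.asarray(self.cb_imputed, dtype=bool)
        self.plddt = np.asarray(self.plddt, dtype=float)
        self.validate()

    def __len__(self):
        return len(self.sequence)

    def validate(self):
        n = len(self.sequence)
        for name in ("coords_N", "coords_CA", "coords_C", "coords_CB"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise LengthMismatch(
                    f"{name} has shape {arr.shape}, expected ({n}, 3)"
                )
        for name in ("coords_N", "coords_CA", "coords_C"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise MalformedStructure(f"non-finite coordinates in {name}")
        if self.plddt.shape != (n,) or self.cb_imputed.shape != (n,):
            raise LengthMismatch("per-residue annotation length mismatch")
        if np.any((self.plddt < 0) | (self.plddt > 100)):
            raise MalformedStructure("pLDDT outside [0, 100]")

    @property
    def has_cb(self):
        return np.all(np.isfinite(self.coords_CB), axis=1)

    @property
    def mean_plddt(self):
        return float(self.plddt.mean())

    def transformed(self, rotation=None, translation=None):
        """Apply a rigid motion; used by invariance checks."""
        R = np.eye(3) if rotation is None else np.asarray(rotation)
        t = np.zeros(3) if translation is None else np.asarray(translation)
        out = replace(self)
        for name in ("coords_N", "coords_CA", "coords_C", "coords_CB"):
            setattr(out, name, getattr(self, name) @ R.T + t)
        return out


@dataclass
class DihedralSet:
    """φ/ψ/ω in radians with per-angle defined masks.

    φ is undefined at the first residue; ψ and ω at the last.  ω_i
    describes the peptide bond between residues i and i+1.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    phi_defined: np.ndarray
    psi_defined: np.ndarray
    omega_defined: np.ndarray

    def __len__(self):
        return len(self.phi)


# ---------------------------------------------------------------------------
# PDB I/O


def read_pdb(path, chain=None):
    """Read a backbone from a PDB file.

    The B-factor of each Cα atom is stored as the residue's pLDDT, following
    the AlphaFold2/ColabFold convention.  For multi-model files only MODEL 1
    is used; alternate locations keep conformer 'A' (or blank).
    """
    try:
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(
            model=1, extra_fields=["b_factor"], altloc="first"
        )
    except Exception as exc:
        raise MalformedStructure(f"cannot parse {path}: {exc}") from exc
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise MalformedStructure(f"no ATOM records in {path}")

    chains = list(dict.fromkeys(atoms.chain_id))
    if chain is None:
        chain = chains[0]
    elif chain not in chains:
        raise ChainNotFound(f"chain {chain!r} not in {chains}")
    atoms = atoms[atoms.chain_id == chain]

    res_ids = np.unique(atoms.res_id)
    n = len(res_ids)
    coords = {k: np.full((n, 3), np.nan) for k in ("N", "CA", "C", "CB")}
    plddt = np.zeros(n)
    seq = []
    for r, rid in enumerate(res_ids):
        res = atoms[atoms.res_id == rid]
        seq.append(_AA_3TO1.get(res.res_name[0], "X"))
        for atom_name in ("N", "CA", "C", "CB"):
            hit = res[res.atom_name == atom_name]
            if hit.array_length():
                coords[atom_name][r] = hit.coord[0]
        ca = res[res.atom_name == "CA"]
        if ca.array_length():
            plddt[r] = ca.b_factor[0]
        for atom_name in ("N", "CA", "C"):
            if not np.all(np.isfinite(coords[atom_name][r])):
                raise MalformedStructure(
                    f"residue {rid} is missing backbone atom {atom_name}"
                )
    return BackboneStructure(
        id=str(path),
        sequence="".join(seq),
        coords_N=coords["N"],
        coords_CA=coords["CA"],
        coords_C=coords["C"],
        coords_CB=coords["CB"],
        cb_imputed=np.zeros(n, dtype=bool),
        plddt=np.clip(plddt, 0.0, 100.0),
        chain_id=str(chain),
    )


def write_pdb(s: BackboneStructure, path):
    """Write backbone atoms as fixed-width ATOM records, pLDDT in B-factor."""
    names, elements, rows, res_idx = [], [], [], []
    for i, aa in enumerate(s.sequence):
        per_res = [("N", "N", s.coords_N[i]), ("CA", "C", s.coords_CA[i]),
                   ("C", "C", s.coords_C[i])]
        if np.all(np.isfinite(s.coords_CB[i])):
            per_res.append(("CB", "C", s.coords_CB[i]))
        for nm, el, xyz in per_res:
            names.append(nm)
            elements.append(el)
            rows.append(xyz)
            res_idx.append(i)
    n_atoms = len(rows)
    arr = struc.AtomArray(n_atoms)
    arr.coord = np.asarray(rows)
    arr.chain_id = np.full(n_atoms, s.chain_id)
    arr.res_id = np.asarray(res_idx) + 1
    arr.res_name = np.asarray(
        [_AA_1TO3.get(s.sequence[i], "UNK") for i in res_idx]
    )
    arr.atom_name = np.asarray(names)
    arr.element = np.asarray(elements)
    arr.hetero = np.zeros(n_atoms, dtype=bool)
    arr.set_annotation("b_factor", s.plddt[np.asarray(res_idx)])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Virtual Cβ


def virtual_cbeta(n, ca, c, bond_length=CB_BOND_LENGTH):
    """Place an ideal tetrahedral Cβ from backbone N, Cα, C.

    The direction makes the tetrahedral angle arccos(-1/3) with both the
    Cα→N and Cα→C unit vectors, on the side giving L-amino-acid chirality.
    """
    n1 = n - ca
    n1 = n1 / np.linalg.norm(n1)
    n2 = c - ca
    n2 = n2 / np.linalg.norm(n2)
    cos12 = float(np.dot(n1, n2))
    alpha = np.cos(_TETRAHEDRAL) / (1.0 + cos12)
    perp = np.cross(n1, n2)
    perp_sq = float(np.dot(perp, perp))
    beta_sq = (1.0 - alpha**2 * 2.0 * (1.0 + cos12)) / perp_sq
    beta = np.sqrt(max(beta_sq, 0.0))
    direction = alpha * (n1 + n2) + beta * perp
    return ca + bond_length * direction / np.linalg.norm(direction)


def impute_cbeta(s: BackboneStructure) -> BackboneStructure:
    """Fill missing β-carbons with the ideal tetrahedral construction.

    Residues with a recorded Cβ are untouched; the operation is idempotent.
    """
    cb = s.coords_CB.copy()
    imputed = s.cb_imputed.copy()
    for i in np.where(~s.has_cb)[0]:
        cb[i] = virtual_cbeta(s.coords_N[i], s.coords_CA[i], s.coords_C[i])
        imputed[i] = True
    return replace(s, coords_CB=cb, cb_imputed=imputed)


# ---------------------------------------------------------------------------
# Dihedrals


def dihedral(p0, p1, p2, p3, tol=1e-8):
    """Torsion angle of four points, IUPAC sign convention, radians.

    Raises :class:`DegenerateGeometry` when three consecutive points are
    collinear within ``tol``.
    """
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale1 = np.linalg.norm(b1) * np.linalg.norm(b2)
    scale2 = np.linalg.norm(b2) * np.linalg.norm(b3)
    if np.linalg.norm(n1) <= tol * max(scale1, tol) or \
            np.linalg.norm(n2) <= tol * max(scale2, tol):
        raise DegenerateGeometry("collinear atoms in dihedral definition")
    u2 = b2 / np.linalg.norm(b2)
    return float(np.arctan2(np.dot(np.cross(n1, n2), u2), np.dot(n1, n2)))


def compute_dihedrals(s: BackboneStructure) -> DihedralSet:
    """φᵢ, ψᵢ, ωᵢ for every residue, with terminal angles masked.

    φᵢ = C(i−1)–N(i)–Cα(i)–C(i); ψᵢ = N(i)–Cα(i)–C(i)–N(i+1);
    ωᵢ = Cα(i)–C(i)–N(i+1)–Cα(i+1).
    """
    L = len(s)
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    omega = np.full(L, np.nan)
    N, CA, C = s.coords_N, s.coords_CA, s.coords_C
    for i in range(L):
        if i > 0:
            phi[i] = dihedral(C[i - 1], N[i], CA[i], C[i])
        if i < L - 1:
            psi[i] = dihedral(N[i], CA[i], C[i], N[i + 1])
            omega[i] = dihedral(CA[i], C[i], N[i + 1], CA[i + 1])
    return DihedralSet(
        phi=phi,
        psi=psi,
        omega=omega,
        phi_defined=~np.isnan(phi),
        psi_defined=~np.isnan(psi),
        omega_defined=~np.isnan(omega),
    )


# ---------------------------------------------------------------------------
# Secondary structure

# Broad Ramachandran regions for the built-in assigner (degrees).
_HELIX_PHI = (-100.0, -30.0)
_HELIX_PSI = (-80.0, -5.0)
_STRAND_PHI = (-170.0, -70.0)
_STRAND_PSI = (80.0, 180.0)


def _in_region(value, lo_hi):
    lo, hi = lo_hi
    return lo < value < hi


def assign_ss8(s: BackboneStructure, d: DihedralSet) -> np.ndarray:
    """Per-residue 8-state class indices from backbone dihedrals.

    This is a deliberately simple dihedral-region stand-in for DSSP: runs of
    at least four consecutive helical (φ, ψ) pairs become H, runs of at
    least three strand pairs become E, and everything else is C.  Externally
    computed 8-state labels can be supplied instead via
    :func:`ss8_from_string`.
    """
    L = len(s)
    if len(d) != L:
        raise LengthMismatch("dihedral set length differs from structure")
    phi_deg = np.degrees(d.phi)
    psi_deg = np.degrees(d.psi)
    helix = np.zeros(L, dtype=bool)
    strand = np.zeros(L, dtype=bool)
    for i in range(L):
        if not (d.phi_defined[i] and d.psi_defined[i]):
            continue
        helix[i] = _in_region(phi_deg[i], _HELIX_PHI) and _in_region(
            psi_deg[i], _HELIX_PSI
        )
        strand[i] = _in_region(phi_deg[i], _STRAND_PHI) and _in_region(
            psi_deg[i], _STRAND_PSI
        )
    labels = np.full(L, SS8_ALPHABET.index("C"), dtype=int)
    _mark_runs(helix, min_run=4, code=SS8_ALPHABET.index("H"), out=labels)
    _mark_runs(strand, min_run=3, code=SS8_ALPHABET.index("E"), out=labels)
    return labels


def _mark_runs(flags, min_run, code, out):
    i, L = 0, len(flags)
    while i < L:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j < L and flags[j]:
            j += 1
        if j - i >= min_run:
            out[i:j] = code
        i = j


def ss8_from_string(ss: str) -> np.ndarray:
    """Convert an 8-state label string (e.g. from DSSP) to class indices."""
    try:
        return np.array([SS8_ALPHABET.index(c) for c in ss], dtype=int)
    except ValueError as exc:
        raise ValueError(f"illegal SS8 letter in {ss!r}") from exc


def read_ss8_table(path):
    """Read a two-column TSV of (id, SS8 string) external labels."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, ss = line.split("\t")[:2]
            out[key] = ss8_from_string(ss)
    return out


# ---------------------------------------------------------------------------
# Ensembles


def rank_by_plddt(structures):
    """Order an ensemble by descending mean pLDDT (stable on ties)."""
    structures = list(structures)
    if not structures:
        raise EmptyEnsemble("no structures to rank")
    return sorted(structures, key=lambda s: -s.mean_plddt)
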