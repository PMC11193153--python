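"""Dataset construction: hemolysis labeling, HC50 replicate labeling,
sequence filters, and identity-constrained train/validation splitting.

The hemolysis criteria form two ladders over (activity %, concentration
µg/mL) pairs: a measurement showing high lysis at low concentration marks a
peptide hemolytic, low lysis at high concentration marks it nonhemolytic,
and peptides whose measurements satisfy neither ladder are excluded.  A
peptide assayed in HC50 replicates is toxic when at least two replicates
fall at or below 128 µg/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .backbone import AA_ALPHABET
from .errors import InsufficientData, NoMeasurements

__all__ = [
    "HemolysisMeasurement",
    "PeptideRecord",
    "HEMOLYTIC_CRITERIA",
    "NONHEMOLYTIC_CRITERIA",
    "HC50_THRESHOLD",
    "label_hemolysis_record",
    "label_hc50_replicates",
    "filter_sequences",
    "sequence_identity",
    "cluster_by_identity",
    "split_by_identity",
    "read_hemolysis_table",
    "read_hc50_table",
]


@dataclass
class HemolysisMeasurement:
    activity: float       # percent lysis, 0-100
    concentration: float  # µg/mL, > 0


@dataclass
class PeptideRecord:
    id: str
    sequence: str
    amidation: bool = False
    measurements: list = field(default_factory=list)
    hc50_replicates: list = field(default_factory=list)
    label: str = "unknown"   # toxic | nontoxic | excluded | unknown


# (minimum activity %, maximum concentration µg/mL); the 100% row is an
# exact-activity requirement.
HEMOLYTIC_CRITERIA = [
    (40.0, 200.0),
    (50.0, 250.0),
    (60.0, 300.0),
    (70.0, 350.0),
    (80.0, 400.0),
    (90.0, 450.0),
    (100.0, 500.0),
]

# (maximum activity %, strict minimum concentration µg/mL)
NONHEMOLYTIC_CRITERIA = [
    (50.0, 250.0),
    (40.0, 200.0),
    (30.0, 150.0),
    (20.0, 100.0),
    (10.0, 50.0),
]

HC50_THRESHOLD = 128.0  # µg/mL
HC50_MIN_REPLICATES = 2


def _is_hemolytic(m: HemolysisMeasurement):
    for min_act, max_conc in HEMOLYTIC_CRITERIA:
        ok_act = (m.activity == 100.0 if min_act == 100.0
                  else m.activity >= min_act)
        if ok_act and m.concentration <= max_conc:
            return True
    return False


def _is_nonhemolytic(m: HemolysisMeasurement):
    return any(
        m.activity <= max_act and m.concentration > min_conc
        for max_act, min_conc in NONHEMOLYTIC_CRITERIA
    )


def label_hemolysis_record(measurements):
    """Label a peptide from its activity/concentration measurements.

    Toxic if any measurement satisfies a hemolytic row, else nontoxic if
    any satisfies a nonhemolytic row, else excluded.  Toxic takes
    precedence when different measurements of one peptide hit both ladders
    (conservative for a safety screen).  Order-independent by construction.
    """
    measurements = list(measurements)
    if not measurements:
        raise NoMeasurements("peptide has no hemolysis measurements")
    if any(_is_hemolytic(m) for m in measurements):
        return "toxic"
    if any(_is_nonhemolytic(m) for m in measurements):
        return "nontoxic"
    return "excluded"


def label_hc50_replicates(values):
    """Toxic iff at least two replicate HC50 values are <= 128 µg/mL."""
    values = np.asarray(list(values), dtype=float)
    return ("toxic"
            if int((values <= HC50_THRESHOLD).sum()) >= HC50_MIN_REPLICATES
            else "nontoxic")


def filter_sequences(records, min_len=5, max_len=50):
    """Length window, natural-residue alphabet, exact-duplicate removal."""
    seen, out = set(), []
    for rec in records:
        seq = rec.sequence
        if not (min_len <= len(seq) <= max_len):
            continue
        if set(seq) - set(AA_ALPHABET):
            continue
        if seq in seen:
            continue
        seen.add(seq)
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Identity clustering and splitting (CD-HIT stand-in)

_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 2.0
        a.mismatch_score = -1.0
        a.open_gap_score = -2.0
        a.extend_gap_score = -0.5
        _ALIGNER = a
    return _ALIGNER


def sequence_identity(a, b):
    """Identity = identical columns / alignment length, global alignment."""
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_by_identity(sequences, max_identity=0.80):
    """Greedy clustering: each sequence joins the first cluster whose
    representative it matches at >= max_identity, longest sequences first."""
    order = sorted(range(len(sequences)), key=lambda i: -len(sequences[i]))
    reps, clusters = [], []
    assignment = [None] * len(sequences)
    for i in order:
        seq = sequences[i]
        for c, rep in enumerate(reps):
            if sequence_identity(seq, rep) >= max_identity:
                clusters[c].append(i)
                assignment[i] = c
                break
        else:
            reps.append(seq)
            clusters.append([i])
            assignment[i] = len(reps) - 1
    return clusters


def split_by_identity(records, val_fraction=0.2, max_identity=0.80, seed=0):
    """4:1 train/validation split with whole identity clusters on one side.

    No validation sequence may share >= max_identity global-alignment
    identity with any training sequence; offending clusters are reassigned
    to the training side until the audit passes.
    """
    records = list(records)
    clusters = cluster_by_identity([r.sequence for r in records],
                                   max_identity)
    labels = {r.label for r in records}
    for lab in labels:
        n_clusters = sum(
            1 for cl in clusters if any(records[i].label == lab for i in cl)
        )
        if n_clusters < 2:
            raise InsufficientData(f"class {lab!r} has {n_clusters} cluster(s)")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    class_total = {lab: sum(r.label == lab for r in records)
                   for lab in labels}
    val_target = {lab: val_fraction * n for lab, n in class_total.items()}
    val_count = {lab: 0 for lab in labels}
    val_clusters = set()
    for c in order:
        members = clusters[c]
        counts = {}
        for i in members:
            counts[records[i].label] = counts.get(records[i].label, 0) + 1
        major = max(counts, key=counts.get)
        if val_count[major] < val_target[major]:
            val_clusters.add(c)
            for lab, k in counts.items():
                val_count[lab] += k

    # audit: pull any validation cluster too similar to the training side
    changed = True
    while changed:
        changed = False
        train_seqs = [records[i].sequence
                      for c, cl in enumerate(clusters)
                      if c not in val_clusters for i in cl]
        for c in sorted(val_clusters):
            for i in clusters[c]:
                if any(sequence_identity(records[i].sequence, t)
                       >= max_identity for t in train_seqs):
                    val_clusters.discard(c)
                    changed = True
                    break
            if changed:
                break

    train, val = [], []
    for c, cl in enumerate(clusters):
        side = val if c in val_clusters else train
        side.extend(records[i] for i in cl)
    return train, val


def export_split_fasta(train, val, out_dir):
    """Write train.fasta / val.fasta for a finished split."""
    from pathlib import Path

    from .embeddings import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.id, r.sequence) for r in train], out / "train.fasta")
    write_fasta([(r.id, r.sequence) for r in val], out / "val.fasta")
    return out / "train.fasta", out / "val.fasta"


# ---------------------------------------------------------------------------
# Tabular readers


def read_hemolysis_table(path):
    """Read a CSV/TSV of hemolysis measurements into labeled records.

    Expected columns: id, sequence, amidation, activity, concentration;
    several rows per id accumulate as measurements of one peptide.
    """
    df = _read_table(path)
    records = {}
    for _, row in df.iterrows():
        rid = str(row["id"])
        rec = records.setdefault(rid, PeptideRecord(
            id=rid,
            sequence=str(row["sequence"]),
            amidation=bool(row.get("amidation", False)),
        ))
        rec.measurements.append(HemolysisMeasurement(
            activity=float(row["activity"]),
            concentration=float(row["concentration"]),
        ))
    out = list(records.values())
    for rec in out:
        rec.label = label_hemolysis_record(rec.measurements)
    return out


def read_hc50_table(path):
    """Read a CSV/TSV with replicate HC50 columns (hc50_1, hc50_2, ...)."""
    df = _read_table(path)
    hc_cols = [c for c in df.columns if c.lower().startswith("hc50")]
    out = []
    for _, row in df.iterrows():
        reps = [float(row[c]) for c in hc_cols if pd.notna(row[c])]
        rec = PeptideRecord(
            id=str(row["id"]),
            sequence=str(row["sequence"]),
            amidation=bool(row.get("amidation", False)),
            hc50_replicates=reps,
        )
        rec.label = label_hc50_replicates(reps)
        out.append(rec)
    return out


def _read_table(path):
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)
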