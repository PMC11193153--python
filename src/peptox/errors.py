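"""Exception types raised across the package."""


class PeptoxError(Exception):
    """Base class for all package-specific errors."""


class MalformedStructure(PeptoxError):
    """PDB file has no parsable residues or a residue lacks N/CA/C."""


class ChainNotFound(PeptoxError):
    """Requested chain id absent from the structure file."""


class DegenerateGeometry(PeptoxError):
    """Three consecutive dihedral-defining atoms are collinear."""


class LengthMismatch(PeptoxError):
    """Per-residue arrays disagree in length."""


class EmptyEnsemble(PeptoxError):
    """An operation over structure ensembles received no structures."""


class EmptySequence(PeptoxError):
    """Empty amino-acid sequence where at least one residue is required."""


class IllegalResidue(PeptoxError):
    """Sequence contains a character outside the 20 natural amino acids."""


class BackendUnavailable(PeptoxError):
    """The requested external embedding backend is not installed."""


class SequenceTooLong(PeptoxError):
    """Sequence exceeds the configured maximum model length."""


class ShapeMismatch(PeptoxError):
    """Tensor channel counts disagree with the model configuration."""


class NoMeasurements(PeptoxError):
    """A peptide record carries no hemolysis measurements to label."""


class InsufficientData(PeptoxError):
    """A class has too few identity clusters to split."""


class EmptySplit(PeptoxError):
    """Training or validation set is empty."""


class Leakage(PeptoxError):
    """The same peptide id appears in both train and validation splits."""


class InvalidAngles(PeptoxError):
    """Backbone specification contains out-of-range torsion angles."""
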