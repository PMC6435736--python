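"""Exception hierarchy for disorderbench."""


class DisorderBenchError(Exception):
    """Base class for all package errors."""


class FormatError(DisorderBenchError):
    """A file does not conform to its expected text format."""


class InconsistencyError(DisorderBenchError):
    """Conformers of an ensemble disagree on their residue content."""


class PairingError(DisorderBenchError):
    """Two per-residue profiles share no residue numbers."""


class EnsembleTooSmallError(DisorderBenchError):
    """An operation requires more conformers than the ensemble has."""


class BinningMismatchError(DisorderBenchError):
    """Two discrete distributions do not share a binning."""


class EmptyClassError(DisorderBenchError):
    """A conditional distribution has no members on one side."""
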