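"""Exception types raised across the pipeline."""


class TirpolyError(Exception):
    """Base class for all package errors."""


class FormatError(TirpolyError):
    """Malformed input record (FASTA header, table row, ...)."""


class ClassificationError(TirpolyError):
    """A TE library record carries a superfamily code outside the
    TIR-order Class II scope."""


class DuplicateFamilyError(TirpolyError):
    """Two library records share a family name."""


class EmptyLibraryError(TirpolyError):
    """A TE library file contained no records."""


class ParameterError(TirpolyError):
    """A configuration value violates its documented range."""


class PlacementError(TirpolyError):
    """A simulated event cannot be placed (no target-site motif nearby,
    or gaps cannot be drawn disjoint)."""


class ContractError(TirpolyError):
    """A caller violated an operation precondition."""
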