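"""Exception hierarchy shared across the package."""


class PepNBError(Exception):
    """Base class for all package-specific errors."""


class PeptideError(PepNBError, ValueError):
    """Invalid peptide input."""


class PeptideAlphabetError(PeptideError):
    """A character is not one of the 20 canonical amino-acid letters."""


class PeptideLengthError(PeptideError):
    """Peptide length is outside the presentable 8-13 range."""


class DegenerateDataError(PepNBError, ValueError):
    """Input data carry no usable variation (e.g. identical peptides)."""


class ExhaustionError(PepNBError, RuntimeError):
    """A sampler cannot supply the requested number of eligible items."""


class ModelSchemaError(PepNBError, ValueError):
    """A serialized model file is malformed or has an unknown version."""


class InputFormatError(PepNBError, ValueError):
    """A peptide list or FASTA file violates its format contract."""
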