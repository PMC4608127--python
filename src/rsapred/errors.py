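"""Exception hierarchy shared across the pipeline."""


class RsaPredError(Exception):
    """Base class for all package errors."""


class FormatError(RsaPredError):
    """A file does not conform to its declared dialect."""


class LengthMismatchError(FormatError):
    """A per-residue file's row count disagrees with the declared chain length."""


class MissingInputError(RsaPredError):
    """A required profile (PSSM, secondary structure, disorder) is absent."""


class ConfigurationError(RsaPredError):
    """Inconsistent options, mismatched shapes or invalid parameter values."""


class InsufficientDataError(RsaPredError):
    """Not enough residues/chains to perform the requested fit."""


class SingularFitError(RsaPredError):
    """The regression design matrix is rank deficient."""


class UndefinedCorrelationError(RsaPredError):
    """Pearson correlation requested for a constant vector."""
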