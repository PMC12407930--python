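"""Exception hierarchy.

Exit-code mapping used by the CLI: 2 for input/parse errors, 3 for
parameter errors, 4 for empty-result conditions.
"""


class OmegasimError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputFormatError(OmegasimError):
    """Malformed or inconsistent input data (FASTA/VCF/BED)."""

    exit_code = 2


class MissingContigError(InputFormatError):
    """A contig named in the VCF is absent from the reference FASTA."""


class InvalidRegionError(InputFormatError):
    """A BED interval with start >= end or malformed columns."""


class InvalidBaseError(InputFormatError):
    """A base outside {T, C, A, G} where an unambiguous base is required."""


class StopCodonError(InputFormatError):
    """A stop codon supplied where a sense codon is required."""


class ParameterError(OmegasimError):
    """Missing or invalid model/run parameters."""

    exit_code = 3


class UnsupportedModelError(ParameterError):
    """Unknown substitution-model name."""


class EmptyResultError(OmegasimError):
    """A run whose result set is empty."""

    exit_code = 4


class EmptyInputError(EmptyResultError):
    """No usable records in an input file."""


class NoStartCodonError(EmptyResultError):
    """No ATG found in a sequence to be scanned."""


class EmptyScanError(EmptyResultError):
    """A scan that covers zero sense codons."""


class AllDegenerateError(EmptyResultError):
    """Every replicate of a null distribution had an undefined omega."""


# Control-flow signals for context-mode per-variant skips; these are not
# OmegasimError because callers tally them rather than abort.
class ContextSkip(Exception):
    category = "other"


class FlankOutOfBounds(ContextSkip):
    category = "out_of_bounds"


class AmbiguousFlank(ContextSkip):
    category = "ambiguous_flank"


class StopContext(ContextSkip):
    category = "stop_codon_context"
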