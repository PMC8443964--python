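"""Exception types shared across the pipeline."""


class PleioccaError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(PleioccaError, ValueError):
    """A configuration value is outside its domain."""


class FormatError(PleioccaError, ValueError):
    """An input file does not match the expected dialect."""


class NoSharedSnpsError(PleioccaError, ValueError):
    """Two studies have no SNP in common after harmonization."""


class OrderingError(PleioccaError, ValueError):
    """SNPs were not supplied in genomic (chromosome, position) order."""


class DomainError(PleioccaError, ValueError):
    """A numeric argument violates a mathematical precondition."""


class DegenerateMatrixError(PleioccaError, ValueError):
    """A matrix cannot be regularized to positive definiteness."""


class ConsistencyError(PleioccaError, ValueError):
    """Cross-referenced inputs disagree (e.g. unknown SNP or gene IDs)."""


class PipelineError(PleioccaError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
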