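"""Exception hierarchy shared across the package."""


class SilacDiffError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SilacDiffError):
    """A column mapping, threshold set, or run configuration is invalid."""


class InputError(SilacDiffError):
    """An input table or gene-set file violates its contract."""


class DegeneratePopulationError(SilacDiffError):
    """The log2-ratio population has zero spread; z-scores are undefined."""


class NoQuantifiableProteinsError(SilacDiffError):
    """Quality filtering removed every record."""


class PipelineError(SilacDiffError):
    """A pipeline stage failed; the message names the stage."""
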