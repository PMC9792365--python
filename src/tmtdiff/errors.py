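"""Exception hierarchy shared across the pipeline."""


class TmtdiffError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(TmtdiffError):
    """A configuration value violates its invariant."""


class DesignError(TmtdiffError):
    """The experimental design of the input cannot support the operation."""


class InputError(TmtdiffError):
    """Malformed or inconsistent input data."""


class TransformError(TmtdiffError):
    """A numerical transform is undefined for the given values."""


class StateError(TmtdiffError):
    """Pipeline stages called out of their required order."""
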