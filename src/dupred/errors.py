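"""Exception hierarchy shared across the package."""


class DupredError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DupredError, ValueError):
    """Invalid configuration (bad probability, empty tree, missing path...)."""


class ValidationError(DupredError, ValueError):
    """Invalid input data (frame violation, missing label, bad table...)."""


class NewickError(DupredError, ValueError):
    """Malformed or semantically invalid Newick input."""


class PipelineError(DupredError, RuntimeError):
    """A pipeline stage could not run on the supplied data."""
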