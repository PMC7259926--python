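"""Exception hierarchy shared by all pipeline stages."""


class EcoprovError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EcoprovError):
    """Invalid inputs, malformed files, or violated preconditions (CLI exit code 2)."""


class SelectionError(ValidationError):
    """A parameter-selection scan did not contain a qualifying region."""


class NumericalError(EcoprovError):
    """A numerical procedure failed to converge or produced non-finite values (CLI exit code 3)."""
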