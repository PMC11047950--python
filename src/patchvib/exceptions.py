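"""Exception hierarchy for the patchvib toolkit.

Errors are split by who is at fault: a :class:`ConfigurationError` means the
caller wired incompatible settings together; an :class:`InputError` means the
data handed to an operation is malformed; a :class:`NumericalError` means a
computation left the realm of finite numbers and cannot sensibly continue.
"""


class PatchVibError(Exception):
    """Base class for all errors raised by patchvib."""


class ConfigurationError(PatchVibError):
    """Incompatible or invalid configuration (bad layer wiring, unknown names)."""


class InputError(PatchVibError):
    """Malformed input data (non-finite values, out-of-range probabilities)."""


class ShapeError(InputError):
    """Array shapes do not agree with each other or with the configuration."""


class NumericalError(PatchVibError):
    """A computation produced non-finite values or failed to converge."""
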