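"""Package-level exception types.

``InputError`` covers malformed or inconsistent user input (bad files,
misannotated sites, invalid parameter combinations); ``IncompatibilityError``
covers mismatches between a saved model and the encoder/feature space it is
applied to.  The CLI maps them to exit codes 2 and 3 respectively.
"""


class InputError(ValueError):
    """Malformed or inconsistent input data or parameters."""


class IncompatibilityError(RuntimeError):
    """Model and feature space (dimension, layout, property table) disagree."""
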