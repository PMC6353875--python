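"""Exception hierarchy.

``InputError`` covers anything the user can fix (bad files, invalid
configs, violated preconditions) and maps to CLI exit code 1; any other
``CSPFitError`` (or unexpected exception) maps to exit code 2.
"""


class CSPFitError(Exception):
    """Base class for all cspfit errors."""


class InputError(CSPFitError):
    """Invalid user input: malformed file, inconsistent config, bad precondition."""


class FitError(CSPFitError):
    """Numerical failure inside a fitting routine."""
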