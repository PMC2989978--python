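"""Exception hierarchy. User-facing CLI maps DlwError to exit code 1."""


class DlwError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DlwError):
    """A value violates a physical or statistical precondition."""


class SchemaError(DlwError):
    """An input file does not match the expected tabular schema."""


class KineticsError(DlwError):
    """Isotope kinetics could not be simulated or fitted in a physiological range."""
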