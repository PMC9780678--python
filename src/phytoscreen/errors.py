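"""Exception hierarchy shared across the screening pipeline.

``ConfigurationError`` marks problems a user can fix in a config file or
on the command line; ``DataError`` marks problems in the input data
itself.  The CLI maps these onto distinct exit codes.
"""


class ScreeningError(Exception):
    """Base class for all errors raised by phytoscreen."""


class ConfigurationError(ScreeningError):
    """Invalid configuration: unknown keys, missing columns, bad rule specs."""


class DataError(ScreeningError):
    """Invalid input data: duplicate ids, out-of-range values, empty files."""


class StructureParseError(DataError):
    """A structure string could not be parsed into a molecule."""

    def __init__(self, structure: str, detail: str = ""):
        self.structure = structure
        msg = f"could not parse structure {structure!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
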