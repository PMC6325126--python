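"""Exception hierarchy shared across the package."""


class NickscanError(Exception):
    """Base class for all package errors."""


class InputError(NickscanError):
    """A required input is missing, empty, or semantically invalid."""


class ParseError(NickscanError):
    """A record in an input file could not be parsed."""


class ConfigurationError(NickscanError):
    """A parameter set or file header violates its contract."""


class CoordinateError(NickscanError):
    """A read or site lies outside its chromosome."""


class PlacementError(NickscanError):
    """Planted sites could not be placed without overlap."""
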