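"""Exception hierarchy shared across docknet modules."""


class DocknetError(Exception):
    """Base class for all docknet errors."""


class ParseError(DocknetError, ValueError):
    """A malformed record in an input file; the message names the line."""


class EmptyInputError(DocknetError, ValueError):
    """An input that must be non-empty was empty."""


class DegenerateScoreError(DocknetError, ValueError):
    """Decoy score distribution has zero spread; z is undefined."""


class DegenerateGeometryError(DocknetError, ValueError):
    """Point set too small or rank-deficient for superposition."""


class GridSizeError(DocknetError, ValueError):
    """Structures exceed the configured docking grid."""
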