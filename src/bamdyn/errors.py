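"""Exception hierarchy shared across the package."""


class BamdynError(Exception):
    """Base class for all package errors."""


class FormatError(BamdynError):
    """A file could not be parsed under the requested dialect."""


class EmptyInputError(BamdynError):
    """An input resolved to nothing (empty model, empty series, ...)."""


class CongruenceError(BamdynError):
    """Trajectory frames do not match the topology atom count."""


class SelectionError(BamdynError):
    """A residue-range/chain selection resolved to no atoms."""


class FrameError(BamdynError):
    """The membrane frame could not be constructed (degenerate geometry)."""


class PairingError(BamdynError):
    """Atom pairing between two structures failed or is under-determined."""


class ParameterError(BamdynError):
    """An operation parameter is out of its allowed range."""


class LookupResidueError(BamdynError):
    """A residue or atom named in a query is absent from the structure."""
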