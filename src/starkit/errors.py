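"""Exception hierarchy for starkit.

Every error raised by the library derives from :class:`StarkitError`, so
callers (and the CLI) can catch one base class.  Subclasses distinguish the
contract that was violated.
"""


class StarkitError(Exception):
    """Base class for all starkit errors."""


class AlphabetError(StarkitError, ValueError):
    """A sequence contains a symbol outside {A, C, G, U} after normalization."""


class InputError(StarkitError, ValueError):
    """An argument violates an operation's precondition (e.g. empty sequence)."""


class SizeError(StarkitError, ValueError):
    """An input exceeds a declared size guard (e.g. exhaustive enumeration)."""


class ModelError(StarkitError, ValueError):
    """An energy model parameter is invalid (e.g. non-positive kT)."""


class ScaffoldError(StarkitError, ValueError):
    """A terminator scaffold violates its invariants."""


class ConfigError(StarkitError, ValueError):
    """A configuration file contains an unknown key, bad type, or bad bound."""


class FormatError(StarkitError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ContractError(StarkitError, ValueError):
    """An internal data-structure invariant was violated by a caller."""


class DesignFailureError(StarkitError, RuntimeError):
    """Sequence design exhausted its attempt budget without satisfying the
    acceptance constraints.  The message names the binding constraint."""
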