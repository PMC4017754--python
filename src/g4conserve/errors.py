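"""Exception hierarchy.

All user-facing failures derive from :class:`G4ConserveError` so callers can
catch one base class; the subclasses distinguish bad input data, bad
coordinates, resource-limit refusals and malformed fixture specs.
"""


class G4ConserveError(Exception):
    """Base class for all errors raised by this package."""


class InputError(G4ConserveError, ValueError):
    """Invalid user input (empty sequence, illegal alphabet, missing id)."""


class CoordinateError(G4ConserveError, IndexError):
    """A position or interval falls outside the sequence/alignment it refers to."""


class ResourceLimitError(G4ConserveError, RuntimeError):
    """An input exceeds a configured safety limit (e.g. alignment length)."""


class FixtureSpecError(G4ConserveError, ValueError):
    """A synthetic-fixture specification is internally inconsistent."""
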