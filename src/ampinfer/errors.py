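"""Exception hierarchy.

Everything user-facing raises an :class:`AmpinferError` subclass so the CLI
can turn any expected failure into a one-line message and a nonzero exit.
"""

from __future__ import annotations

from collections.abc import Sequence


class AmpinferError(Exception):
    """Base class for all expected failures."""


class CoordinateLoadError(AmpinferError):
    """A gene-coordinate file could not be parsed or violates an invariant."""


class PanelError(AmpinferError):
    """A panel definition is empty, unreadable, or names an unknown built-in."""


class QueryError(AmpinferError):
    """The amplified-gene query is empty or unparseable."""


class UnknownGeneError(AmpinferError):
    """Query symbols that do not exist in the genome index.

    The offending tokens are kept on :attr:`symbols` so callers can report
    or, with the skip-unknown escape hatch, discard them.
    """

    def __init__(self, symbols: Sequence[str]):
        self.symbols = tuple(symbols)
        super().__init__(
            "unknown gene name(s) not present in the genome index: "
            + ", ".join(self.symbols)
        )


class CensusError(AmpinferError):
    """A cancer gene census file is empty or malformed."""


class RenderError(AmpinferError):
    """An unknown output format was requested."""


class SimulationError(AmpinferError):
    """Simulation parameters are infeasible (e.g. amplicons do not fit)."""
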