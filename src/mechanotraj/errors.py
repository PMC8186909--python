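"""Exception hierarchy for mechanotraj."""


class MechanotrajError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MechanotrajError, ValueError):
    """A structure or trajectory file could not be parsed."""


class SelectionError(MechanotrajError, ValueError):
    """A named domain selection could not be resolved to atoms."""


class UnitError(MechanotrajError, ValueError):
    """An unknown or incompatible physical unit was requested."""


class AnalysisError(MechanotrajError, ValueError):
    """An analysis precondition was violated (degenerate input, no signal...)."""


class SimulationUnstableError(MechanotrajError, RuntimeError):
    """The toy integrator blew up (bond extension beyond the sanity bound)."""
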