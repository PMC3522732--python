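"""Exception hierarchy.

Everything raised deliberately by the package derives from
:class:`FluxcompareError`, so callers (and the CLI) can separate data
problems from genuine bugs.
"""


class FluxcompareError(Exception):
    """Base class for all errors raised by fluxcompare."""


class StructuralError(FluxcompareError):
    """A model violates a structural invariant (duplicate ids, dangling
    metabolite references, zero stoichiometric coefficients, inverted
    bounds)."""


class FormatError(FluxcompareError):
    """An input file could not be parsed; carries file/line context in the
    message."""


class MediumError(FluxcompareError):
    """A medium names a metabolite that is not external in any member of the
    collection it is applied to."""


class ObjectiveNotFoundError(FluxcompareError, KeyError):
    """The requested objective reaction id does not exist in the model."""


class SolverError(FluxcompareError):
    """The LP backend failed for a reason other than infeasibility or
    unboundedness; the backend status is carried in the message."""


class FrontError(FluxcompareError):
    """The base model of a Pareto sweep is infeasible."""


class StateError(FluxcompareError):
    """An operation was applied to a result in the wrong state (e.g. binding
    constraint diagnostics on a non-optimal solve)."""


class StatisticsError(FluxcompareError):
    """A statistic was requested on too few observations to be meaningful."""
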