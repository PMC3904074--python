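"""Exception hierarchy shared across cablekit."""


class CablekitError(Exception):
    """Base class for all cablekit errors."""


class UnitParseError(CablekitError, ValueError):
    """A quantity or unit string could not be parsed."""


class DimensionError(CablekitError, ValueError):
    """Operation between dimensionally incompatible quantities."""


class DomainError(CablekitError, ValueError):
    """A value is outside the physically meaningful domain (e.g. negative area)."""


class MorphologyError(CablekitError, ValueError):
    """Invalid morphology structure or SWC content."""


class AmbiguityError(CablekitError, ValueError):
    """Two equal-priority channel applications claim the same section."""


class ValidationError(CablekitError, ValueError):
    """A simulation object graph failed validation before running."""


class ReferenceError_(CablekitError, LookupError):
    """A recording or connection refers to an object not in the simulation."""


class DiscretizationError(CablekitError, ValueError):
    """A morphology cannot be spatially discretized."""


class NumericError(CablekitError, ArithmeticError):
    """Numerical failure during integration or rate evaluation."""


class StateError(CablekitError, ValueError):
    """Channel/solver state outside its allowed range."""


class QueryParseError(CablekitError, ValueError):
    """A tag-selection query string could not be parsed."""


class WindowError(CablekitError, ValueError):
    """An empty or inverted time window was requested."""


class ScenarioError(CablekitError, ValueError):
    """A scenario file is malformed or internally inconsistent."""


class ComparisonError(CablekitError, ValueError):
    """Cross-backend comparison on mismatched recording sets."""
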