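"""Exception hierarchy for clonaldyn."""


class ClonaldynError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ClonaldynError):
    """Invalid parameters, initial conditions, controls or config files."""


class NumericalError(ClonaldynError):
    """Integrator failure (step-size collapse, overflow) with context echoed."""


class BracketError(ClonaldynError):
    """A bisection bracket whose endpoints do not straddle the threshold."""


class AnalyticLimitError(ClonaldynError):
    """A closed-form solution was requested outside its regime of validity."""
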