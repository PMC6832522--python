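"""Exception hierarchy shared across the package."""


class TregSwitchError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TregSwitchError, ValueError):
    """Invalid user-supplied parameter (negative rate, bad fraction, ...)."""


class SchemaError(TregSwitchError, KeyError):
    """Required channel, gene, or group is missing from the input."""


class NumericalError(TregSwitchError, RuntimeError):
    """Integrator or optimizer failure; carries diagnostics in args."""


class FitError(NumericalError):
    """All optimizer starts failed for a model fit."""


class SelectionError(TregSwitchError, RuntimeError):
    """Fewer than two candidate models could be fitted."""


class UndefinedSteadyStateError(TregSwitchError, ZeroDivisionError):
    """Steady-state fraction requested with all exchange rates zero."""


class UndefinedFoldError(TregSwitchError, ZeroDivisionError):
    """Fold conversion requested with a zero control fraction."""


class DegenerateThresholdError(TregSwitchError, ValueError):
    """Automatic thresholding attempted on a constant image."""


class EmptyForegroundError(TregSwitchError, ValueError):
    """Box-counting metrics requested for an image without foreground."""


class InsufficientScalesError(TregSwitchError, ValueError):
    """Too few usable scales for the log-log regression."""


class ConfigError(TregSwitchError, ValueError):
    """Pipeline configuration failed validation; args[0] lists all violations."""
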