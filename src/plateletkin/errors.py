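"""Exception hierarchy shared by all plateletkin modules."""


class PlateletKinError(Exception):
    """Base class for all package-specific errors."""


class ProtocolError(PlateletKinError, ValueError):
    """Invalid stimulation protocol (event ordering, times, concentrations)."""


class ConfigurationError(PlateletKinError, KeyError):
    """Missing or inconsistent entries in a parameter table or run config."""


class UnitError(PlateletKinError, ValueError):
    """Unknown or inconsistent concentration unit."""


class IntegrationError(PlateletKinError, RuntimeError):
    """ODE solver failure; carries the last valid state reached."""

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class DegenerateFitError(PlateletKinError, ValueError):
    """Signal too flat (below the noise floor) for a meaningful fit."""


class FitError(PlateletKinError, RuntimeError):
    """Nonlinear fit failed to converge; message carries diagnostics."""


class ModelMismatchError(PlateletKinError, ValueError):
    """Data shape contradicts the assumed model (e.g. rising decay curve)."""


class TraceRangeError(PlateletKinError, ValueError):
    """Requested evaluation window falls outside the recorded trace."""
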