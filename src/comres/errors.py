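"""Exception hierarchy shared across the package."""


class ComresError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ComresError, ValueError):
    """A parameter set violates a model invariant (e.g. |alpha| >= 1)."""


class ConfigError(ComresError, ValueError):
    """A configuration file is malformed or holds unknown keys."""


class SingularDenominatorError(ComresError, ZeroDivisionError):
    """1 - alpha_pc * alpha_cp is numerically zero (unreachable under |alpha| < 1)."""


class NotApplicableError(ComresError, ValueError):
    """A coexistence-branch quantity was requested outside the coexistence regime."""


class ThresholdUndefinedError(ComresError, ValueError):
    """Competitive release is impossible (alpha_pc <= 0), so f* is undefined."""


class NoStableEquilibriumError(ComresError, RuntimeError):
    """No feasible stable fixed point found; indicates a tolerance problem."""


class IntegrationError(ComresError, RuntimeError):
    """The ODE/PDE solver failed; the message carries solver diagnostics."""


class InstabilityError(IntegrationError):
    """A spatial field diverged (non-finite or exploding norm)."""
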