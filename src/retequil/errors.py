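"""Exception hierarchy shared across the package."""


class RetequilError(Exception):
    """Base class for all package errors."""


class ConfigError(RetequilError, ValueError):
    """Invalid configuration input (unknown key, bad value, bad file)."""


class ChainBreakdownError(RetequilError, ArithmeticError):
    """The stepwise approximation chain produced a non-physical value.

    Carries the name of the failing step in ``step``.
    """

    def __init__(self, message: str, step: str):
        super().__init__(message)
        self.step = step


class ConvergenceError(RetequilError, RuntimeError):
    """Equilibrium solver failed to converge; carries the best iterate."""

    def __init__(self, message: str, state=None):
        super().__init__(message)
        self.state = state


class UnitError(RetequilError, ValueError):
    """Quantity supplied with incompatible units."""
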