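"""Exception hierarchy shared across the package."""


class MsceError(Exception):
    """Base class for all package errors."""


class InputError(MsceError, ValueError):
    """Invalid user-supplied argument (grids, labels, ranges, tables)."""


class ConfigError(MsceError, ValueError):
    """Invalid or inconsistent configuration."""


class SchemaError(InputError):
    """A table failed schema validation; message names the column/row."""


class NumericalError(MsceError, ArithmeticError):
    """Solver failure, underflow below a configured floor, or an
    out-of-range survival probability; message names the offending
    component."""


class FitError(MsceError, RuntimeError):
    """Calibration failed to converge after all restarts."""


class SimulationError(MsceError, RuntimeError):
    """Stochastic simulation exceeded its event-count safety cap."""
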