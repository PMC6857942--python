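"""Exception hierarchy shared across the package."""


class CardiofitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CardiofitError):
    """Invalid configuration, unknown name, or malformed input."""


class SimulationError(CardiofitError):
    """Integration failed (non-finite state).  Carries the failing time."""

    def __init__(self, message: str, time_ms: float | None = None):
        super().__init__(message)
        self.time_ms = time_ms


class NotReachableError(CardiofitError):
    """A requested voltage is never attained within the requested segment."""


class ContractError(CardiofitError):
    """Two objects that must share a grid or an objective mask do not."""
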