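"""Exception types shared across quiflux."""


class QuifluxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(QuifluxError):
    """A network/run configuration is malformed or inconsistent."""


class InfeasibleFluxError(QuifluxError):
    """Steady-state balance forces a negative flux.

    Parameters
    ----------
    node : str
        The metabolite node (or derived arc) whose balance is violated.
    value : float
        The offending (negative) flux value.
    """

    def __init__(self, node: str, value: float, message: str | None = None):
        self.node = node
        self.value = value
        super().__init__(
            message or f"steady-state balance forces negative flux at {node!r}: {value:.4g}"
        )


class SolverError(QuifluxError):
    """ODE integration or steady-state search failed."""
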