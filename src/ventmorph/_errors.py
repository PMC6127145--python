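"""Exception hierarchy shared by all pipeline stages.

Exit-code mapping used by the CLI: config errors exit 2, data/topology
errors exit 3, convergence failures exit 4.
"""


class VentmorphError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(VentmorphError):
    """Invalid configuration or precondition on user-supplied parameters."""

    exit_code = 2


class DataError(VentmorphError):
    """Malformed, inconsistent or contract-violating input data."""

    exit_code = 3


class TopologyError(DataError):
    """Mesh is not closed / not manifold / wrong genus or mixed topologies."""


class DegeneracyError(DataError):
    """Numerically degenerate input (collinear points, singular design...)."""


class ConvergenceError(VentmorphError):
    """An iterative procedure failed to reach its stopping contract."""

    exit_code = 4
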