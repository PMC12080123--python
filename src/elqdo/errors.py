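"""Exception types shared across the package."""


class ElQdoError(Exception):
    """Base class for package errors."""


class DomainError(ElQdoError, ValueError):
    """An argument is outside its mathematical domain (negative distance, ...)."""


class ConfigurationError(ElQdoError, ValueError):
    """Inconsistent or unknown configuration (unknown damping kind, shape mismatch, ...)."""


class GeometryError(ElQdoError, ValueError):
    """Degenerate molecular geometry (collinear water, oxygen on the cage center, ...)."""


class ParameterError(ElQdoError, ValueError):
    """Invalid variational parameters (non-SPD quadratic form, non-positive exponent, ...)."""


class NodeError(ElQdoError, ArithmeticError):
    """The wave function vanishes at the requested configuration."""


class RunError(ElQdoError, RuntimeError):
    """A Monte Carlo run failed (population collapse, all walkers on nodes, ...)."""


class PolarizationCatastropheError(ElQdoError, ArithmeticError):
    """The coupled-dipole Hamiltonian has a non-positive normal mode: the
    oscillators are closer than the dipole approximation allows."""


class ResolutionError(ElQdoError, RuntimeError):
    """A grid eigensolve did not converge under refinement."""
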