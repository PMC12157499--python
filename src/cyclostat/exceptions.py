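"""Exception types used across the package."""


class ParameterError(ValueError):
    """Invalid model or kinetic parameters."""


class UnsupportedOperationError(RuntimeError):
    """Operation not defined for this model family (e.g. density of a point mass)."""


class QuadratureError(RuntimeError):
    """Numerical integration failed to converge to the requested tolerance."""


class ConvergenceError(RuntimeError):
    """A series summation did not stabilize (direct and Borel routes exhausted)."""


class InternalConsistencyError(RuntimeError):
    """Two independent computation routes disagree beyond tolerance."""
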