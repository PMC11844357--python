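"""Exception types shared across the identification pipeline."""


class LeakageError(ValueError):
    """A record length does not hold an integer number of cycles of the probed
    frequency, so a single-frequency DFT would suffer spectral leakage."""


class CoverageError(RuntimeError):
    """A grid frequency is missing from a required channel role (reference or
    disturbance) on some axis, so the pooled FRF cannot be estimated there."""


class NearSingularError(ArithmeticError):
    """A frequency-response value is too close to zero to invert safely."""


class LoopInstabilityError(ArithmeticError):
    """The closed loop 1 + PB is (numerically) singular at some frequency."""


class OptimizationError(RuntimeError):
    """No restart of the derivative-free fit converged."""
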