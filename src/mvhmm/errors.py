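"""Exception hierarchy for mvhmm."""


class MVHMMError(Exception):
    """Base class for all mvhmm errors."""


class DimensionError(MVHMMError, ValueError):
    """Shapes of observations and parameters do not agree."""


class NotPositiveDefiniteError(MVHMMError, ValueError):
    """A covariance matrix is not symmetric positive definite.

    The message names the offending matrix (Sigma or Psi).
    """


class DegenerateStateError(MVHMMError, RuntimeError):
    """A hidden state received (numerically) zero total responsibility."""

    def __init__(self, state: int, weight: float = 0.0):
        self.state = state
        self.weight = weight
        super().__init__(
            f"state {state} is degenerate (total responsibility {weight:.3e})"
        )


class UnderflowError(MVHMMError, RuntimeError):
    """Numerical collapse (all-zero scaled column) in the forward recursion."""

    def __init__(self, unit: int, time: int):
        self.unit = unit
        self.time = time
        super().__init__(f"forward recursion underflowed at unit {unit}, time {time}")


class InitializationError(MVHMMError, RuntimeError):
    """All short-EM starts failed."""


class IterationLimitError(MVHMMError, RuntimeError):
    """An inner iterative routine (e.g. the MM rotation loop) did not converge."""


class FitFailedError(MVHMMError, RuntimeError):
    """All restarts of the ECM driver failed."""


class BalanceError(MVHMMError, ValueError):
    """Long-format input does not describe a balanced four-way panel."""
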