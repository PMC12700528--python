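"""Exception hierarchy shared across the package."""


class BrainInvError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BrainInvError):
    """Input fails a structural or numerical validity check."""


class ShapeError(ValidationError):
    """Array has the wrong shape (e.g. non-square connectome)."""


class DegenerateInputError(ValidationError):
    """Input is structurally valid but degenerate (all-zero matrix, constant signal)."""


class PreconditionError(BrainInvError):
    """A documented operation precondition is not met."""


class ConfigurationError(BrainInvError):
    """Run configuration is inconsistent (e.g. dt larger than the smallest delay)."""


class DivergenceError(BrainInvError):
    """Numerical integration produced a non-finite or out-of-range state.

    Carries the step index at which the failure occurred when known.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class IntegratorStepError(DivergenceError):
    """A state constraint (e.g. r > 0) was violated even after step refinement."""


class DatasetQualityError(BrainInvError):
    """Too many simulations in a batch produced unusable features."""


class TrainingFailureError(BrainInvError):
    """Density-estimator training produced a non-finite loss."""


class DegeneratePosteriorError(BrainInvError):
    """Posterior draws are degenerate (zero variance / constant column)."""


class LeakageError(BrainInvError):
    """Nearly all posterior mass lies outside the prior support."""


class RecipeError(BrainInvError):
    """Feature recipe does not match the data it is applied to."""


class CorruptionError(BrainInvError):
    """Stored dataset failed its checksum on load."""


class CapabilityError(BrainInvError):
    """A requested capability (e.g. density gradients) is unavailable."""
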