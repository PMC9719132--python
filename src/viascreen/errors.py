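"""Exception types shared across the pipeline."""


class ViaScreenError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(ViaScreenError, ValueError):
    """A configuration field failed validation; the message names the field."""


class RoiConvergenceError(ViaScreenError, RuntimeError):
    """The ROI mixture model failed to converge; carries the iteration count."""

    def __init__(self, n_iter: int, message: str | None = None):
        self.n_iter = n_iter
        super().__init__(message or f"GMM did not converge after {n_iter} iterations")


class EmptyMaskError(ViaScreenError, ValueError):
    """An operation that requires a non-empty ROI mask received an empty one.

    Callers may fall back to a whole-image mask.
    """
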