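"""Exception hierarchy for the tensile-analysis pipeline."""


class OculomechError(Exception):
    """Base class for all package errors."""


class DomainError(OculomechError, ValueError):
    """An argument is outside the physically meaningful domain."""


class GeometryError(OculomechError, ValueError):
    """Specimen geometry is missing, over-specified, or non-positive."""


class UnusableSpecimenError(OculomechError):
    """A raw record cannot be referenced to the preload state."""


class StructureError(OculomechError):
    """A record does not have the expected preconditioning/ramp structure."""

    def __init__(self, message, detected_cycles=None):
        super().__init__(message)
        self.detected_cycles = detected_cycles


class FitError(OculomechError):
    """Model fitting failed or produced no admissible model."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class WindowCoverageError(OculomechError):
    """A curve does not span the requested tangent-modulus window."""


class ConfigError(OculomechError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(OculomechError):
    """Input validation failed; carries an itemized list of problems."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
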