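"""Exception hierarchy for partglm."""


class PartGLMError(Exception):
    """Base class for all partglm errors."""


class UnsupportedDesignError(PartGLMError):
    """The design falls outside the supported family (single random unit
    factor crossed with the within-subject factors, optionally nested in
    the between-subjects factors)."""


class QuasiFRequiredError(PartGLMError):
    """No single error stratum has an expected mean square matching the
    effect's EMS minus its own component; an exact F-ratio does not exist
    and a quasi-F (Satterthwaite pooling) would be required.

    Quasi-F construction is deliberately not implemented; the error names
    the variance components that could not be matched.
    """

    def __init__(self, effect, unmatched):
        self.effect = effect
        self.unmatched = tuple(unmatched)
        super().__init__(
            f"No exact denominator exists for effect '{effect}': the "
            f"components {sorted(map(str, self.unmatched))} appear in its EMS "
            "but in no single error stratum. A quasi-F ratio would be "
            "required, which this package does not construct."
        )


class AmbiguousErrorTermError(PartGLMError):
    """More than one error stratum matches the effect's EMS remainder."""


class DegenerateDesignError(PartGLMError):
    """A degrees-of-freedom computation produced a non-positive value."""


class IncompleteDataError(PartGLMError):
    """A subject is missing one or more within-subject cells."""


class NonEstimableError(PartGLMError):
    """A contrast row lies outside the row space of the design matrix."""


class InvalidErrorTermError(PartGLMError):
    """A contrast with surviving subject-effect weights was tested against a
    residual error term, which would inflate the F statistic."""


class CollinearCovariateError(PartGLMError):
    """A covariate column is aliased with existing design columns."""


class DegenerateFitError(PartGLMError):
    """A sub-model has no residual degrees of freedom."""


class SingularCovarianceError(PartGLMError):
    """Too few subjects to estimate the within-subject covariance."""
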