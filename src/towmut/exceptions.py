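"""Exception types raised across the package."""


class TowmutError(ValueError):
    """Base class for all input-contract violations."""


class CollinearTraitsError(TowmutError):
    """The trait matrix has linearly dependent columns, so Y'Y is singular."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        if message is None:
            message = (
                "trait matrix is rank deficient; offending column(s): "
                f"{self.columns}"
            )
        super().__init__(message)


class CollinearCovariatesError(TowmutError):
    """The augmented covariate design [1 | Z] is rank deficient."""


class DegenerateFitError(TowmutError):
    """A model fit produced a degenerate (singular or non-positive) result."""
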