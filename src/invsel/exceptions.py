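"""Exception types raised across the package."""


class InvalidConfigError(ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(ValueError):
    """Input data violates a precondition (e.g. non-binary labels)."""


class DegenerateDesignError(ValueError):
    """A model design is degenerate, e.g. a constant classification."""


class UndefinedCVError(RuntimeError):
    """Cross-validation could not be computed on any fold."""


class UndefinedAUCError(ValueError):
    """AUC is undefined, e.g. fewer than two classes in the truth."""
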